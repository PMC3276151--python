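"""Map estimation, genotype HMM, imputation, IM/CIM, permutations."""

import numpy as np
import pytest

from conftest import population_from_genotypes
from lobeqtl.core import MISSING, GeneticMap, haldane_r
from lobeqtl.scan import (
    PermutationConfig,
    _anova_lod,
    _combine_lod,
    _permuted_matrix,
    _transition,
    composite_interval_mapping,
    estimate_map,
    genotype_probabilities,
    impute_genotypes,
    interval_mapping,
    permutation_threshold,
)
from lobeqtl.simulate import (
    CrossDesign,
    QTLArchitecture,
    assign_phenotypes,
    simulate_cross,
)


# ---------------------------------------------------------------------------
# map estimation
# ---------------------------------------------------------------------------


class TestEstimateMap:
    def test_duplicated_marker_columns_give_zero_distance(self, toy_map, f2_toy):
        geno = f2_toy.genotypes.copy()
        geno[:, 1] = geno[:, 0]
        pop = population_from_genotypes(toy_map, geno)
        est = estimate_map(pop)
        assert est.pos[1] - est.pos[0] == pytest.approx(0.0, abs=1e-6)

    def test_f2_recombination_fraction_recovered(self):
        # markers 25.54 female-cM apart: female r = 0.20, males transmit
        # intact chromosomes, so the intercross estimate is the per-gamete
        # average 0.10 and the sex-averaged distance -50*ln(0.8) = 11.157
        gmap = GeneticMap(names=["a", "b"], chrom=["2", "2"], pos=[0.0, 25.54])
        pop = simulate_cross(CrossDesign(t=2, n_phenotyped=2000, census=400), gmap, seed=21)
        est = estimate_map(pop)
        d = est.pos[1] - est.pos[0]
        r_hat = 0.5 * (1 - np.exp(-2 * d / 100))
        assert r_hat == pytest.approx(0.10, abs=0.02)
        assert d == pytest.approx(11.157, abs=2.0)

    def test_ail_map_expansion_single_arm(self):
        gmap = GeneticMap(
            names=[f"m{i}" for i in range(11)], chrom=["2"] * 11,
            pos=np.linspace(0, 50, 11),
        )
        f2 = simulate_cross(CrossDesign(t=2, n_phenotyped=400, census=300), gmap, seed=22)
        f17 = simulate_cross(CrossDesign(t=17, n_phenotyped=400, census=300), gmap, seed=23)
        l2 = estimate_map(f2).chrom_length("2")
        l17 = estimate_map(f17).chrom_length("2")
        assert l17 / l2 >= 7.0

    def test_x_map_from_hemizygous_males(self):
        gmap = GeneticMap(names=["x1", "x2"], chrom=["X", "X"], pos=[0.0, 30.0])
        pop = simulate_cross(CrossDesign(t=2, n_phenotyped=3000, census=400), gmap, seed=24)
        est = estimate_map(pop)
        # sons get a recombinant maternal X: r = Haldane(30) directly
        expect = float(haldane_r(30.0))
        d = est.pos[1]
        r_hat = 0.5 * (1 - np.exp(-2 * d / 100))
        assert r_hat == pytest.approx(expect, abs=0.03)

    def test_unlinked_capped_with_warning(self, toy_map):
        rng = np.random.default_rng(0)
        geno = rng.integers(0, 3, size=(400, 3)).astype(np.int8)
        pop = population_from_genotypes(toy_map, geno)
        with pytest.warns(UserWarning, match="capped"):
            est = estimate_map(pop)
        assert np.all(np.diff(est.pos) <= -50 * np.log(1 - 2 * 0.49) + 1e-6)


# ---------------------------------------------------------------------------
# genotype probabilities
# ---------------------------------------------------------------------------


class TestGenotypeProbabilities:
    def test_typed_marker_posterior_is_certain(self, f2_toy):
        probs = genotype_probabilities(f2_toy, step=None, epsilon=0.0)
        for j, col in enumerate(probs.grid.marker_col):
            g = f2_toy.genotypes[:, col]
            assert np.allclose(probs.probs[np.arange(len(g)), j, g], 1.0)

    def test_probabilities_sum_to_one(self, f2_toy):
        probs = genotype_probabilities(f2_toy, step=2.0, epsilon=1e-3)
        assert np.allclose(probs.probs.sum(axis=2), 1.0, atol=1e-9)

    def test_grid_contains_all_markers(self, f2_toy):
        probs = genotype_probabilities(f2_toy, step=7.0)
        grid = probs.grid
        for j, (c, p) in enumerate(zip(f2_toy.gmap.chrom, f2_toy.gmap.pos)):
            k = grid.locate(c, p)
            assert grid.pos[k] == pytest.approx(p)
            assert grid.marker_col[k] == j
        assert np.sum(grid.marker_col >= 0) == len(f2_toy.gmap)

    def test_middle_marker_matches_exhaustive_enumeration(self, toy_map):
        """Flanks AA and BB at 20 cM, middle missing: the posterior equals a
        brute-force sum over all flank-compatible genotype paths."""
        pop = population_from_genotypes(toy_map, np.array([[0, MISSING, 2]]))
        probs = genotype_probabilities(pop, step=None, epsilon=0.0)
        r = float(haldane_r(20.0))
        T = _transition(r, two_state=False)
        enum = np.array([T[0, g] * T[g, 2] for g in range(3)])
        enum /= enum.sum()
        mid = probs.grid.locate("2", 20.0)
        assert np.allclose(probs.probs[0, mid], enum, atol=1e-9)

    def test_enumeration_with_genotyping_error(self, toy_map):
        """Observed middle marker with error rate: posterior equals the
        emission-weighted enumeration."""
        eps = 0.02
        pop = population_from_genotypes(toy_map, np.array([[0, 0, 2]]))
        probs = genotype_probabilities(pop, step=None, epsilon=eps)
        r = float(haldane_r(20.0))
        T = _transition(r, two_state=False)
        joint = np.zeros(3)
        for g0 in range(3):
            for g1 in range(3):
                for g2 in range(3):
                    prior = np.array([0.25, 0.5, 0.25])[g0] * T[g0, g1] * T[g1, g2]
                    e = 1.0
                    for g, obs in ((g0, 0), (g1, 0), (g2, 2)):
                        e *= (1 - eps) if g == obs else eps / 2
                    joint[g1] += prior * e
        joint /= joint.sum()
        mid = probs.grid.locate("2", 20.0)
        assert np.allclose(probs.probs[0, mid], joint, atol=1e-9)

    def test_fully_missing_individual_keeps_prior(self, toy_map):
        pop = population_from_genotypes(toy_map, np.full((1, 3), MISSING))
        probs = genotype_probabilities(pop, step=None)
        assert np.allclose(probs.probs[0], [0.25, 0.5, 0.25], atol=1e-12)

    def test_male_x_never_heterozygous(self, panel):
        pop = simulate_cross(CrossDesign(t=2, n_phenotyped=100, census=100), panel, seed=25)
        probs = genotype_probabilities(pop, step=2.0, epsilon=1e-3)
        x = probs.grid.is_x
        assert np.all(probs.probs[:, x, 1] == 0.0)
        imps = impute_genotypes(probs, 4, seed=1)
        assert set(np.unique(imps.geno[:, x, :])) <= {0, 2}

    def test_epsilon_validated(self, f2_toy):
        with pytest.raises(ValueError, match="error rate"):
            genotype_probabilities(f2_toy, epsilon=0.7)


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------


class TestImputation:
    def test_fully_typed_imputations_identical(self, f2_toy):
        probs = genotype_probabilities(f2_toy, step=None, epsilon=0.0)
        imps = impute_genotypes(probs, 8, seed=2)
        assert np.all(imps.geno == imps.geno[:, :, :1])
        assert np.array_equal(imps.geno[:, :, 0], f2_toy.genotypes[:, probs.grid.marker_col])

    def test_imputed_frequency_matches_posterior(self, toy_map):
        pop = population_from_genotypes(toy_map, np.array([[0, MISSING, 2]] * 1))
        probs = genotype_probabilities(pop, step=None, epsilon=0.0)
        M = 256
        imps = impute_genotypes(probs, M, seed=3)
        mid = probs.grid.locate("2", 20.0)
        for g in range(3):
            p = probs.probs[0, mid, g]
            freq = np.mean(imps.geno[0, mid] == g)
            assert abs(freq - p) <= 3 * np.sqrt(p * (1 - p) / M) + 1e-12

    def test_seed_reproducible(self, f2_toy):
        probs = genotype_probabilities(f2_toy, step=5.0, epsilon=1e-3)
        a = impute_genotypes(probs, 4, seed=9)
        b = impute_genotypes(probs, 4, seed=9)
        c = impute_genotypes(probs, 4, seed=10)
        assert a.geno.tobytes() == b.geno.tobytes()
        assert a.geno.tobytes() != c.geno.tobytes()

    def test_imputed_paths_are_coherent_mosaics(self, toy_map):
        """Joint draws: between fully informative identical flanks with a
        tight map, imputed middles rarely double-switch (cf. independent
        per-position draws, which would ignore linkage)."""
        tight = GeneticMap(names=["a", "b", "c"], chrom=["2", "2", "2"], pos=[0.0, 1.0, 2.0])
        pop = population_from_genotypes(tight, np.array([[0, MISSING, 0]] * 200))
        probs = genotype_probabilities(pop, step=None, epsilon=0.0)
        imps = impute_genotypes(probs, 16, seed=4)
        mid = probs.grid.locate("2", 1.0)
        assert np.mean(imps.geno[:, mid, :] != 0) < 0.05


# ---------------------------------------------------------------------------
# interval mapping
# ---------------------------------------------------------------------------


class TestIntervalMapping:
    def test_lod_matches_closed_form_regression(self, f2_toy):
        rng = np.random.default_rng(5)
        n = len(f2_toy)
        g = f2_toy.genotypes[:, 1]
        y = 0.7 * (g - 1.0) + rng.normal(0, 1, n)
        probs = genotype_probabilities(f2_toy, step=None, epsilon=0.0)
        imps = impute_genotypes(probs, 8, seed=6)
        prof = interval_mapping(imps, y)
        X = np.column_stack([np.ones(n), g - 1.0, (g == 1).astype(float)])
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        rss1 = np.sum((y - X @ beta) ** 2)
        rss0 = np.sum((y - y.mean()) ** 2)
        lod_cf = n / 2 * np.log10(rss0 / rss1)
        j = prof.grid.locate("2", 20.0)
        assert prof.lod[j] == pytest.approx(lod_cf, abs=1e-6)

    def test_affine_phenotype_invariance(self, f2_toy):
        rng = np.random.default_rng(7)
        y = rng.normal(size=len(f2_toy))
        probs = genotype_probabilities(f2_toy, step=5.0, epsilon=1e-4)
        imps = impute_genotypes(probs, 4, seed=8)
        a = interval_mapping(imps, y)
        b = interval_mapping(imps, -2.5 * y + 11.0)
        assert np.allclose(a.lod, b.lod, atol=1e-9)

    def test_null_scans_stay_below_threshold(self, panel):
        """Pure-noise phenotypes: the genome-max LOD should fall below its
        own 5% permutation threshold in at least 90% of replicates."""
        below = 0
        reps = 50
        for rep in range(reps):
            pop = simulate_cross(CrossDesign(t=2, n_phenotyped=200, census=200),
                                 panel, seed=3000 + rep)
            rng = np.random.default_rng(4000 + rep)
            y = rng.normal(size=200)
            probs = genotype_probabilities(pop, step=None, epsilon=1e-4)
            imps = impute_genotypes(probs, 2, seed=5000 + rep)
            prof = interval_mapping(imps, y)
            cfg = PermutationConfig(P=100, alpha=0.05, seed=6000 + rep)
            thr = permutation_threshold(imps, y, cfg, "autosome")
            aut = ~prof.grid.is_x
            below += prof.lod[aut].max() <= thr
        assert below >= 0.9 * reps

    def test_qtl_peak_found_near_true_locus(self, panel):
        arch = QTLArchitecture(loci=(("2", 60.0, 1.0, 0.0),), residual_sd=1.0)
        hits = 0
        for rep in range(10):
            pop = simulate_cross(CrossDesign(t=2, n_phenotyped=367, census=250),
                                 panel, seed=7000 + rep, extra_loci=arch.positions())
            pop = assign_phenotypes(pop, arch, seed=7100 + rep)
            probs = genotype_probabilities(pop, step=2.0, epsilon=1e-4)
            imps = impute_genotypes(probs, 8, seed=7200 + rep)
            prof = interval_mapping(imps, pop.phenotype("score"))
            chrom, pos, _lod = prof.max("2")
            hits += abs(pos - 60.0) <= 10.0
        assert hits >= 9

    def test_monotone_information_on_unmasking(self, panel):
        """Revealing masked genotypes does not decrease the expected peak
        LOD at a true QTL."""
        arch = QTLArchitecture(loci=(("2", 60.0, 0.7, 0.0),), residual_sd=1.0)
        full_lods, masked_lods = [], []
        for rep in range(20):
            pop = simulate_cross(CrossDesign(t=2, n_phenotyped=150, census=150),
                                 panel, seed=8000 + rep, extra_loci=arch.positions())
            pop = assign_phenotypes(pop, arch, seed=8100 + rep)
            y = pop.phenotype("score")
            masked = pop.genotypes.copy()
            masked[75:] = MISSING
            for geno, sink in ((pop.genotypes, full_lods), (masked, masked_lods)):
                p2 = population_from_genotypes(panel, geno)
                probs = genotype_probabilities(p2, step=None, epsilon=1e-4)
                imps = impute_genotypes(probs, 8, seed=8200 + rep)
                prof = interval_mapping(imps, y)
                sink.append(prof.max("2")[2])
        assert np.mean(full_lods) >= np.mean(masked_lods)

    def test_zero_variance_phenotype_rejected(self, f2_toy):
        probs = genotype_probabilities(f2_toy, step=None)
        imps = impute_genotypes(probs, 2, seed=1)
        with pytest.raises(ValueError, match="variance"):
            interval_mapping(imps, np.ones(len(f2_toy)))


# ---------------------------------------------------------------------------
# composite interval mapping
# ---------------------------------------------------------------------------


class TestCIM:
    def test_no_covariates_reduces_to_im(self, f2_toy):
        rng = np.random.default_rng(9)
        y = rng.normal(size=len(f2_toy))
        probs = genotype_probabilities(f2_toy, step=5.0, epsilon=1e-4)
        imps = impute_genotypes(probs, 4, seed=11)
        im = interval_mapping(imps, y)
        cim = composite_interval_mapping(imps, y, window=10.0, n_covariates=0)
        assert np.allclose(im.lod, cim.lod, atol=1e-9)

    def test_covariates_dropped_within_window(self, f2_toy):
        rng = np.random.default_rng(10)
        y = rng.normal(size=len(f2_toy))
        probs = genotype_probabilities(f2_toy, step=None, epsilon=1e-4)
        imps = impute_genotypes(probs, 2, seed=12)
        cim = composite_interval_mapping(imps, y, window=10.0, n_covariates=2)
        grid = cim.grid
        for k, (c, p) in enumerate(cim.info["covariates"]):
            at_cov = grid.locate(c, p)
            assert k in cim.info["dropped_by_position"][at_cov]
            far = [j for j in range(len(grid))
                   if grid.chrom[j] != c or abs(grid.pos[j] - p) >= 5.0]
            for j in far[:5]:
                assert k not in cim.info["dropped_by_position"][j]

    def test_too_many_covariates_rejected(self, f2_toy):
        probs = genotype_probabilities(f2_toy, step=None)
        imps = impute_genotypes(probs, 2, seed=13)
        with pytest.raises(ValueError, match="covariates"):
            composite_interval_mapping(imps, np.arange(len(f2_toy)), n_covariates=3)

    def test_cim_lowers_interpeak_valley(self):
        """Two linked QTL 30 cM apart: conditioning on marker covariates
        deflates the single-QTL ridge between the peaks (replicate median)."""
        gmap = GeneticMap(
            names=[f"m{i}" for i in range(13)], chrom=["2"] * 13,
            pos=np.linspace(0, 60, 13),
        )
        arch = QTLArchitecture(
            loci=(("2", 15.0, 1.0, 0.0), ("2", 45.0, 1.0, 0.0)), residual_sd=1.0
        )
        diffs = []
        for rep in range(20):
            pop = simulate_cross(CrossDesign(t=2, n_phenotyped=300, census=250),
                                 gmap, seed=9000 + rep, extra_loci=arch.positions())
            pop = assign_phenotypes(pop, arch, seed=9100 + rep)
            y = pop.phenotype("score")
            probs = genotype_probabilities(pop, step=None, epsilon=1e-4)
            imps = impute_genotypes(probs, 4, seed=9200 + rep)
            mid = probs.grid.locate("2", 30.0)
            im = interval_mapping(imps, y)
            cim = composite_interval_mapping(imps, y, window=10.0, n_covariates=4)
            diffs.append(im.lod[mid] - cim.lod[mid])
        assert np.median(diffs) > 0


# ---------------------------------------------------------------------------
# permutation thresholds
# ---------------------------------------------------------------------------


class TestPermutations:
    def test_degenerate_strata_give_observed_maximum(self, f2_toy):
        """With singleton strata every permutation is the identity, so all
        maxima equal the observed max and the threshold equals it."""
        rng = np.random.default_rng(14)
        y = rng.normal(size=len(f2_toy))
        probs = genotype_probabilities(f2_toy, step=None, epsilon=1e-4)
        imps = impute_genotypes(probs, 2, seed=15)
        prof = interval_mapping(imps, y)
        cfg = PermutationConfig(P=10, alpha=0.05, strata=np.arange(len(f2_toy)), seed=16)
        with pytest.warns(UserWarning, match="maximum"):
            thr = permutation_threshold(imps, y, cfg, "all")
        assert thr == pytest.approx(prof.lod.max(), abs=1e-9)

    def test_stratified_permutation_preserves_stratum_multisets(self):
        rng = np.random.default_rng(17)
        y = rng.normal(size=30)
        strata = np.array(["g"] * 10 + ["u"] * 20)
        cfg = PermutationConfig(P=25, alpha=0.2, strata=strata, seed=18)
        Y = _permuted_matrix(y, cfg)
        for p in range(25):
            for s in ("g", "u"):
                assert np.allclose(np.sort(Y[strata == s, p]), np.sort(y[strata == s]))

    def test_threshold_order_statistic_convention(self, f2_toy):
        rng = np.random.default_rng(19)
        y = rng.normal(size=len(f2_toy))
        probs = genotype_probabilities(f2_toy, step=None, epsilon=1e-4)
        imps = impute_genotypes(probs, 2, seed=20)
        cfg = PermutationConfig(P=40, alpha=0.05, seed=21)
        thr, null = permutation_threshold(imps, y, cfg, "all", return_null=True)
        k = int(np.ceil(0.95 * 40))
        assert thr == pytest.approx(np.sort(null)[k - 1])

    def test_x_and_autosome_scopes_disjoint(self, panel):
        pop = simulate_cross(CrossDesign(t=2, n_phenotyped=100, census=120), panel, seed=26)
        rng = np.random.default_rng(22)
        y = rng.normal(size=100)
        probs = genotype_probabilities(pop, step=None, epsilon=1e-4)
        imps = impute_genotypes(probs, 2, seed=23)
        cfg = PermutationConfig(P=30, alpha=0.1, seed=24)
        ta = permutation_threshold(imps, y, cfg, "autosome")
        tx = permutation_threshold(imps, y, cfg, "X")
        assert ta != tx  # different position sets, same permutations
        with pytest.raises(ValueError, match="scope"):
            permutation_threshold(imps, y, cfg, "Y")


def test_combine_lod_is_log_mean_lr():
    lod_pm = np.array([[1.0, 2.0, 3.0]])
    expect = np.log10(np.mean(10.0 ** lod_pm[0]))
    assert _combine_lod(lod_pm)[0] == pytest.approx(expect, abs=1e-12)


def test_anova_lod_handles_empty_classes():
    G = np.zeros((10, 1, 1), dtype=np.int8)  # all one class: no signal
    y = np.random.default_rng(0).normal(size=10)
    lod = _anova_lod(G, y)
    assert lod[0, 0, 0] == pytest.approx(0.0, abs=1e-9)
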