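"""End-to-end driver: simulate, measure, scan, fit, test.

The pipeline reproduces the study's analysis chain on synthetic data:

1. simulate the F2 and F17 crosses under the three-QTL + Q1xQ2
   architecture and render one lobe outline per fly (plus parental
   reference outlines);
2. measure every outline (standardize, elliptic Fourier descriptors,
   size metrics), run the mapping-set PCA and attach the first shape
   component (the mapped trait) to the populations;
3. select the F17 phenotypic tails for genotyping, re-estimate both
   genetic maps, and scan: IM and CIM with X/autosome permutation
   thresholds in the F2, selective-genotyping IM with stratified
   permutations in the F17;
4. fit the multi-QTL model at the three strongest F17 peaks (with an
   interaction between the two lead QTL, the published model structure)
   and report effects, percent variance and 2-LOD intervals;
5. run the candidate-locus LOD-sum resampling test.

Every output table carries the config hash; rerunning with the manifest's
config and seed reproduces the outputs exactly.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import interpolate_position
from .enrichment import CandidateSet, candidate_resampling_test
from .io import write_candidates, write_cross, write_outlines
from .model import fit_qtl_model, lod_support_interval
from .morphometrics import efa_coefficients, shape_pca, size_metrics, standardize_outline
from .scan import (
    PermutationConfig,
    composite_interval_mapping,
    estimate_map,
    genotype_probabilities,
    impute_genotypes,
    interval_mapping,
    permutation_threshold,
)
from .simulate import (
    assign_phenotypes,
    f2_design,
    f17_design,
    mid_template,
    render_lobe_outline,
    score_shape_map,
    select_tails,
    simulate_cross,
    study_architecture,
    study_marker_panel,
)

__all__ = ["run_pipeline", "synthetic_candidates", "measure_outlines", "find_peaks"]

log = logging.getLogger("lobeqtl")


def synthetic_candidates(seed=20110331):
    """A synthetic stand-in for the 22-gene candidate list.

    The real candidate positions are not printed in any table we ship, so
    this fixture fabricates 22 named loci (18 autosomal + 4 X-linked,
    matching the published split) spread over the genome with a cluster
    near each mapped QTL.  It exists so the enrichment test has a default
    input; any real list can be supplied as a candidate file instead.
    """
    rng = np.random.default_rng(seed)
    names = [f"cand{i + 1:02d}" for i in range(22)]
    chrom, pos = [], []
    for c, p in (("2", 28.0), ("3", 30.0), ("3", 47.5)):  # near the generative QTL
        for _ in range(3):
            chrom.append(c)
            pos.append(round(float(np.clip(p + rng.normal(0, 4.0), 0, 105)), 1))
    spread = [("2", 9), ("2", 45), ("2", 63), ("2", 88), ("3", 8),
              ("3", 70), ("3", 85), ("3", 99), ("2", 99)]
    for c, p in spread:
        chrom.append(c)
        pos.append(float(p))
    for p in (5.0, 22.0, 40.0, 60.0):
        chrom.append("X")
        pos.append(p)
    return CandidateSet(names=tuple(names), chrom=tuple(chrom), pos=tuple(pos))


def measure_outlines(outlines, n_harmonics=25):
    """Standardize and measure a list of raw outlines.

    Returns (size/shape table, descriptor matrix): one row per outline,
    descriptors are the 4n Fourier coefficients.
    """
    rows, desc = [], []
    for raw in outlines:
        std = standardize_outline(raw)
        met = size_metrics(std)
        coef = efa_coefficients(std, n_harmonics)
        desc.append(coef.descriptor())
        rows.append(
            {
                "outline_id": std.outline_id,
                "side": std.side,
                "area": met.area,
                "height": met.height,
                "width": met.width,
                "hw": met.hw,
                "flagged": std.flagged,
            }
        )
    return pd.DataFrame(rows), np.array(desc)


def find_peaks(profile, threshold=None, min_sep=20.0, k=None, scope="autosome"):
    """Greedy peak picking on a LOD profile.

    Returns (chrom, pos, lod) tuples in decreasing LOD order, keeping
    peaks separated by at least ``min_sep`` cM on a chromosome and above
    ``threshold`` (if given); ``k`` caps the count.
    """
    grid = profile.grid
    if scope == "autosome":
        cand = np.flatnonzero(~grid.is_x)
    elif scope == "X":
        cand = np.flatnonzero(grid.is_x)
    else:
        cand = np.arange(len(grid))
    order = cand[np.argsort(profile.lod[cand])[::-1]]
    peaks = []
    for j in order:
        if threshold is not None and profile.lod[j] < threshold:
            break
        if any(grid.chrom[j] == c and abs(grid.pos[j] - p) < min_sep for c, p, _l in peaks):
            continue
        peaks.append((grid.chrom[j], float(grid.pos[j]), float(profile.lod[j])))
        if k is not None and len(peaks) == k:
            break
    return peaks


def _stage(name, t0):
    log.info("stage %-18s done in %6.1f s", name, time.perf_counter() - t0)


def run_pipeline(config, outdir, candidates=None):
    """Run the full analysis chain; returns a dict of in-memory results.

    ``outdir`` receives cross files, outline and shape tables, scan
    profiles, the fitted-model table, the candidate-test result and a
    manifest with the config, its hash and package/library versions.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not logging.getLogger().handlers:
        logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(outdir / "log.txt", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    results = {}
    try:
        rng = np.random.default_rng(config.seed)
        seeds = {
            name: int(rng.integers(2**31))
            for name in ("f2", "f17", "pheno_f2", "pheno_f17", "outlines", "imp_f2",
                         "imp_f17", "perm_f2", "perm_f17", "candidates")
        }
        panel = study_marker_panel()
        arch = study_architecture(heritability=config.heritability,
                                  paired_corr=config.paired_corr)

        # --- simulate ---------------------------------------------------
        t0 = time.perf_counter()
        f2 = simulate_cross(f2_design(config.n_f2, config.census), panel, seeds["f2"],
                            extra_loci=arch.positions())
        f17 = simulate_cross(f17_design(config.n_f17, config.census, config.tail_count),
                             panel, seeds["f17"], extra_loci=arch.positions())
        f2 = assign_phenotypes(f2, arch, seeds["pheno_f2"])
        f17 = assign_phenotypes(f17, arch, seeds["pheno_f17"])
        _stage("simulate", t0)

        # --- render + measure outlines -----------------------------------
        t0 = time.perf_counter()
        template = mid_template()
        smap = score_shape_map(arch, template)
        orng = np.random.default_rng(seeds["outlines"])
        outlines, owners = [], []
        for label, pop in (("F2", f2), ("F17", f17)):
            for i in range(len(pop)):
                outlines.append(
                    render_lobe_outline(
                        pop.phenotype("score")[i], template, smap,
                        jitter_sd=config.jitter_sd,
                        n_points=config.n_outline_points,
                        seed=int(orng.integers(2**31)),
                        outline_id=str(pop.ids[i]),
                        side=str(pop.phenotypes["side_used"].iloc[i]),
                    )
                )
                owners.append((label, i))
        # parental reference outlines (trait-locus genotypes fixed)
        for pname, code in (("parentA", 0), ("parentB", 2)):
            gval = _uniform_genetic_value(arch, code)
            for rep in range(25):
                outlines.append(
                    render_lobe_outline(
                        gval, template, smap, jitter_sd=config.jitter_sd,
                        n_points=config.n_outline_points,
                        seed=int(orng.integers(2**31)),
                        outline_id=f"{pname}_{rep + 1:02d}",
                    )
                )
                owners.append((pname, rep))
        shape_tab, desc = measure_outlines(outlines, config.n_harmonics)
        # sign reference: a parent-B (Sam-like) outline scores nonnegative
        ref = next(i for i, (lab, _j) in enumerate(owners) if lab == "parentB")
        space = shape_pca(desc, sign_reference=ref, prefix="m")
        n_show = min(6, space.n_components)
        for ci in range(n_show):
            shape_tab[space.component_names()[ci]] = space.scores[:, ci]
        mpc1 = {lab: {} for lab in ("F2", "F17", "parentA", "parentB")}
        for row, (lab, i) in enumerate(owners):
            mpc1[lab][i] = space.scores[row, 0]
        for label, pop in (("F2", f2), ("F17", f17)):
            extra = shape_tab.iloc[[r for r, (lab, _i) in enumerate(owners) if lab == label]]
            frame = pd.DataFrame(
                {
                    "mPC1": [mpc1[label][i] for i in range(len(pop))],
                    "hw": extra["hw"].to_numpy(),
                    "area": extra["area"].to_numpy(),
                }
            )
            if label == "F2":
                f2 = f2.with_phenotypes(frame)
            else:
                f17 = f17.with_phenotypes(frame)
        _stage("morphometrics", t0)

        # --- selective genotyping and maps --------------------------------
        t0 = time.perf_counter()
        f17 = select_tails(f17, config.tail_count, trait="mPC1")
        map_f2 = estimate_map(f2)
        map_f17 = estimate_map(f17)
        _stage("maps", t0)

        # --- scans --------------------------------------------------------
        t0 = time.perf_counter()
        y2 = f2.phenotype("mPC1")
        probs2 = genotype_probabilities(f2, map_f2, step=config.step, epsilon=config.epsilon)
        imps2 = impute_genotypes(probs2, config.n_imputations, seeds["imp_f2"])
        im2 = interval_mapping(imps2, y2)
        cim2 = composite_interval_mapping(imps2, y2, config.cim_window, config.cim_covariates)
        pcfg2 = PermutationConfig(P=config.n_permutations, alpha=config.alpha,
                                  seed=seeds["perm_f2"])
        im2.thresholds = {
            "autosome": permutation_threshold(imps2, y2, pcfg2, "autosome"),
            "X": permutation_threshold(imps2, y2, pcfg2, "X"),
            "alpha": config.alpha,
        }

        y17 = f17.phenotype("mPC1")
        probs17 = genotype_probabilities(f17, map_f17, step=config.step,
                                         epsilon=config.epsilon)
        imps17 = impute_genotypes(probs17, config.n_imputations, seeds["imp_f17"])
        im17 = interval_mapping(imps17, y17)
        strata = np.where(f17.genotyped, "genotyped", "ungenotyped")
        pcfg17 = PermutationConfig(P=config.n_permutations, alpha=config.alpha,
                                   strata=strata, seed=seeds["perm_f17"])
        im17.thresholds = {
            "autosome": permutation_threshold(imps17, y17, pcfg17, "autosome"),
            "X": permutation_threshold(imps17, y17, pcfg17, "X"),
            "alpha": config.alpha,
        }
        _stage("scans", t0)

        # --- multi-QTL model ----------------------------------------------
        t0 = time.perf_counter()
        peaks = find_peaks(im17, min_sep=40.0, k=3, scope="autosome")
        peaks = sorted(peaks, key=lambda t: (t[0], t[1]))
        loci = [(c, p) for c, p, _l in peaks]
        interactions = [(0, 1)] if len(loci) >= 2 else []
        fitted = fit_qtl_model(imps17, y17, loci, interactions)
        intervals = [
            lod_support_interval(im17, c, p, drop=2.0) for c, p, _l in peaks
        ]
        _stage("fit", t0)

        # --- candidate test -------------------------------------------------
        t0 = time.perf_counter()
        cands = candidates if candidates is not None else synthetic_candidates()
        ctest = candidate_resampling_test(
            im17, cands, n_resamples=config.n_resamples, seed=seeds["candidates"]
        )
        _stage("candidates", t0)

        # --- outputs --------------------------------------------------------
        t0 = time.perf_counter()
        digest = config.digest
        write_cross(f2, outdir / "f2_cross.csv")
        write_cross(f17, outdir / "f17_cross.csv")
        write_outlines(outlines, outdir / "outlines.csv")
        shape_tab.to_csv(outdir / "shape_results.csv", index=False)
        coef_cols = [
            f"h{h + 1}{t}" for h in range(config.n_harmonics) for t in ("a", "b", "c", "d")
        ]
        coef_tab = pd.DataFrame(desc, columns=coef_cols)
        coef_tab.insert(0, "outline_id", shape_tab["outline_id"])
        coef_tab.to_csv(outdir / "shape_coefficients.csv", index=False)
        maps = pd.concat(
            [
                panel.to_frame().assign(map="reference"),
                map_f2.to_frame().assign(map="F2_estimated"),
                map_f17.to_frame().assign(map="F17_estimated"),
            ]
        )
        maps.to_csv(outdir / "maps.csv", index=False)
        scan2 = im2.to_frame().rename(columns={"lod": "lod_im"})
        scan2["lod_cim"] = cim2.lod
        scan2.to_csv(outdir / "f2_scan.csv", index=False)
        im17.to_frame().rename(columns={"lod": "lod_im"}).to_csv(
            outdir / "f17_scan.csv", index=False
        )
        fit_tab = fitted.terms.copy()
        fit_tab.to_csv(outdir / "model_terms.csv", index=False)
        iv_tab = pd.DataFrame(
            [
                {
                    "term": f"Q{i + 1}",
                    "chrom": iv.chrom,
                    "peak_expanded": iv.peak,
                    "lower_expanded": iv.lower,
                    "upper_expanded": iv.upper,
                    "lower_reference": interpolate_position(map_f17, panel, iv.chrom, iv.lower),
                    "upper_reference": interpolate_position(map_f17, panel, iv.chrom, iv.upper),
                    "whole_chromosome": iv.whole_chromosome,
                }
                for i, iv in enumerate(intervals)
            ]
        )
        iv_tab.to_csv(outdir / "model_intervals.csv", index=False)
        write_candidates(cands, outdir / "candidates.csv")
        manifest = {
            "config": config.to_dict(),
            "config_hash": digest,
            "stage_seeds": seeds,
            "versions": {"lobeqtl": __version__, "numpy": np.__version__,
                         "pandas": pd.__version__},
            "thresholds": {"f2": im2.thresholds, "f17": im17.thresholds},
            "model": {
                "loci": loci,
                "interactions": interactions,
                "total_pct_var": fitted.total_pct_var,
                "lod": fitted.lod,
            },
            "candidate_test": {
                "observed": ctest.observed,
                "null_mean": ctest.null_mean,
                "null_sd": ctest.null_sd,
                "p_value": ctest.p_value,
                "k": ctest.k,
                "n_resamples": ctest.n_resamples,
            },
        }
        with open(outdir / "manifest.json", "w") as mf:
            json.dump(manifest, mf, indent=2, default=str)
        for tab in ("shape_results", "f2_scan", "f17_scan", "model_terms",
                    "model_intervals", "maps"):
            # stamp the config hash as a trailing comment line
            with open(outdir / f"{tab}.csv", "a") as tf:
                tf.write(f"# config_hash,{digest}\n")
        _stage("write", t0)

        results.update(
            f2=f2, f17=f17, shape_table=shape_tab, shape_space=space,
            map_f2=map_f2, map_f17=map_f17, im_f2=im2, cim_f2=cim2, im_f17=im17,
            model=fitted, intervals=intervals, candidate_test=ctest,
            manifest=manifest,
        )
        return results
    except Exception:
        log.exception("pipeline stage failed; partial outputs are in %s", outdir)
        raise
    finally:
        log.removeHandler(fh)
        fh.close()


def _uniform_genetic_value(arch, code):
    """Genetic value of a genotype uniform across all trait loci."""
    x = float(code) - 1.0
    z = 1.0 if code == 1 else 0.0
    g = sum(a * x + d * z for _c, _p, a, d in arch.loci)
    for _i, _j, (aa, ad, da, dd) in arch.interactions:
        g += aa * x * x + ad * x * z + da * z * x + dd * z * z
    return g
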