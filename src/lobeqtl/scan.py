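"""Genome scans for an intercross by multiple imputation.

The chain is: estimate the genetic map from marker genotypes
(:func:`estimate_map`), compute hidden-Markov genotype posteriors on a cM
grid (:func:`genotype_probabilities`), draw whole-chromosome imputations
(:func:`impute_genotypes`), then scan by single-locus regression within
each imputation, combining likelihood ratios across imputations as
``LOD = log10(mean LR)`` (:func:`interval_mapping`,
:func:`composite_interval_mapping`).  Significance comes from permutation
(:func:`permutation_threshold`), with X- and autosome-specific thresholds
and an optional stratified variant for selectively genotyped populations
(phenotypes permuted separately within the genotyped and ungenotyped
subsets).

All phenotyped individuals are male, so the X is handled with two
hemizygous genotype classes (codes 0/2) everywhere: the HMM never assigns
heterozygote probability on the male X, and X regressions drop the
dominance term.  An F17 advanced intercross is analyzed with the same
intercross machinery on its own re-estimated (expanded) map; this is the
approximation the original analysis used and is documented in
docs/methods.md.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import GENO_AB, MISSING, GeneticMap, haldane_cm, haldane_r

__all__ = [
    "ScanGrid",
    "GenotypeProbabilities",
    "ImputationSet",
    "LODProfile",
    "PermutationConfig",
    "estimate_map",
    "genotype_probabilities",
    "impute_genotypes",
    "interval_mapping",
    "composite_interval_mapping",
    "permutation_threshold",
]


# ---------------------------------------------------------------------------
# map estimation
# ---------------------------------------------------------------------------

# ordered maternal x paternal gamete pairs for two linked loci; each gamete is
# (allele at locus 1, allele at locus 2), recombinant if the alleles differ
_GAMETES = [(0, 0), (1, 1), (0, 1), (1, 0)]


def _pair_tables():
    cls, nrec = [], []
    for m1, m2 in _GAMETES:
        for p1, p2 in _GAMETES:
            cls.append((m1 + p1) * 3 + (m2 + p2))
            nrec.append(int(m1 != m2) + int(p1 != p2))
    return np.array(cls), np.array(nrec)


_CLS16, _NREC16 = _pair_tables()


def _em_rf_intercross(g1, g2, tol=1e-10, max_iter=500):
    """ML recombination fraction between two autosomal intercross markers.

    EM over the unobserved gamete pair (the double heterozygote mixes the
    coupling and repulsion phases); individuals missing either genotype
    are dropped, which marginalizes them out of the pairwise likelihood.
    """
    ok = (g1 != MISSING) & (g2 != MISSING)
    g1, g2 = g1[ok], g2[ok]
    n = len(g1)
    if n == 0:
        return np.nan
    counts = np.bincount(3 * g1.astype(int) + g2, minlength=9).astype(float)
    r = 0.2
    for _ in range(max_iter):
        pair_p = 0.25 * (1.0 - r) ** (2 - _NREC16) * r**_NREC16
        class_p = np.bincount(_CLS16, weights=pair_p, minlength=9)
        class_rec = np.bincount(_CLS16, weights=pair_p * _NREC16, minlength=9)
        with np.errstate(invalid="ignore", divide="ignore"):
            e_rec = np.where(class_p > 0, class_rec / class_p, 0.0)
        r_new = float(np.sum(counts * e_rec) / (2.0 * n))
        r_new = min(max(r_new, 1e-12), 0.5)
        if abs(r_new - r) < tol:
            r = r_new
            break
        r = r_new
    return r


def _rf_hemizygous(g1, g2):
    """Direct ML recombination fraction between two male-X markers."""
    ok = (g1 != MISSING) & (g2 != MISSING)
    if not ok.any():
        return np.nan
    return float(np.mean(g1[ok] != g2[ok]))


def estimate_map(pop, gmap=None):
    """Re-estimate marker positions from the genotypes of a population.

    Marker order is taken from the input map (no reordering).  Adjacent
    recombination fractions are estimated by EM for autosomes and by
    direct counting on the hemizygous male X, then converted to cM with
    the inverse Haldane function; per-chromosome positions start at 0.
    Adjacent fractions of 0.5 or more are capped at 0.49 with a warning.
    """
    gmap = pop.gmap if gmap is None else gmap
    G = pop.genotypes
    new_pos = np.zeros(len(gmap))
    for c in gmap.chromosomes():
        idx = gmap.index_on(c)
        pos = 0.0
        new_pos[idx[0]] = 0.0
        for a, b in zip(idx[:-1], idx[1:]):
            if c == "X":
                r = _rf_hemizygous(G[:, a], G[:, b])
            else:
                r = _em_rf_intercross(G[:, a], G[:, b])
            if np.isnan(r):
                warnings.warn(
                    f"no informative pairs for {gmap.names[a]}-{gmap.names[b]}; using 0.49",
                    stacklevel=2,
                )
                r = 0.49
            if r >= 0.5 - 1e-9:
                warnings.warn(
                    f"adjacent recombination fraction >= 0.5 between {gmap.names[a]} and "
                    f"{gmap.names[b]}; capped at 0.49",
                    stacklevel=2,
                )
                r = 0.49
            pos += float(haldane_cm(r))
            new_pos[b] = pos
    return GeneticMap(names=gmap.names, chrom=gmap.chrom, pos=new_pos, arm=gmap.arm)


# ---------------------------------------------------------------------------
# scan grid and genotype HMM
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScanGrid:
    """Positions scanned: every marker plus pseudomarkers every ``step`` cM."""

    chrom: np.ndarray
    pos: np.ndarray
    is_marker: np.ndarray
    marker_col: np.ndarray  # column in the population's genotype matrix, -1 off markers
    step: float

    def __len__(self):
        return len(self.pos)

    @property
    def is_x(self):
        return self.chrom == "X"

    def index_on(self, chrom):
        return np.flatnonzero(self.chrom == chrom)

    def chromosomes(self):
        seen = []
        for c in self.chrom:
            if c not in seen:
                seen.append(c)
        return seen

    def locate(self, chrom, pos):
        """Index of the grid point nearest (chrom, pos)."""
        idx = self.index_on(chrom)
        if len(idx) == 0:
            raise KeyError(f"chromosome {chrom!r} is not on the scan grid")
        return int(idx[np.argmin(np.abs(self.pos[idx] - pos))])


def build_grid(gmap, step=1.0):
    if step is not None and step <= 0:
        raise ValueError("grid step must be positive (or None for markers only)")
    chroms, pos, ism, mcol = [], [], [], []
    for c in gmap.chromosomes():
        idx = gmap.index_on(c)
        mpos = gmap.pos[idx]
        if step is None:
            grid = np.unique(mpos)
        else:
            lo, hi = mpos[0], mpos[-1]
            grid = np.unique(np.concatenate([np.arange(lo, hi, step), [hi], mpos]))
        for p in grid:
            j = np.flatnonzero(np.abs(mpos - p) < 1e-9)
            chroms.append(c)
            pos.append(float(p))
            ism.append(len(j) > 0)
            mcol.append(int(idx[j[0]]) if len(j) else -1)
    return ScanGrid(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(pos),
        is_marker=np.array(ism),
        marker_col=np.array(mcol),
        step=float(step) if step is not None else float("nan"),
    )


def _transition(r, two_state):
    if two_state:
        return np.array([[1 - r, r], [r, 1 - r]])
    rr = r * r
    s = r * (1 - r)
    nn = (1 - r) ** 2
    return np.array([[nn, 2 * s, rr], [s, nn + rr, s], [rr, 2 * s, nn]])


@dataclass
class GenotypeProbabilities:
    """HMM genotype posteriors on a scan grid.

    ``probs`` is (individuals, grid positions, 3) over genotype codes
    0/1/2; on the (male) X the heterozygote column is identically zero.
    ``obs`` keeps the grid-aligned observed genotypes so that imputation
    can rerun the forward pass without the population object.
    """

    grid: ScanGrid
    probs: np.ndarray
    obs: np.ndarray
    epsilon: float

    @property
    def n_individuals(self):
        return self.probs.shape[0]


def _chrom_hmm_arrays(grid, c, obs_c, epsilon, two_state):
    """Emission (n, L, k) and transition (L-1, k, k) arrays for one chromosome."""
    n, L = obs_c.shape
    k = 2 if two_state else 3
    e = np.ones((n, L, k))
    if two_state:
        for code, state in ((0, 0), (2, 1)):
            m = obs_c == code
            e[m] = epsilon
            e[m, state] = 1.0 - epsilon
    else:
        for code in (0, 1, 2):
            m = obs_c == code
            e[m] = epsilon / 2.0
            e[m, code] = 1.0 - epsilon
    idx = grid.index_on(c)
    d = np.diff(grid.pos[idx])
    T = np.stack([_transition(float(haldane_r(dd)), two_state) for dd in d]) if len(d) else \
        np.zeros((0, k, k))
    init = np.full(k, 0.5) if two_state else np.array([0.25, 0.5, 0.25])
    return e, T, init


def _forward(e, T, init):
    n, L, k = e.shape
    alpha = np.empty((L, n, k))
    a = init[None, :] * e[:, 0, :]
    a /= a.sum(axis=1, keepdims=True)
    alpha[0] = a
    for j in range(1, L):
        a = (a @ T[j - 1]) * e[:, j, :]
        a /= a.sum(axis=1, keepdims=True)
        alpha[j] = a
    return alpha


def genotype_probabilities(pop, gmap=None, step=1.0, epsilon=1e-4):
    """Forward–backward genotype posteriors for every individual.

    Transitions use the Haldane map function on the supplied map (default:
    the population's own).  Emissions allow a symmetric genotyping-error
    rate ``epsilon``; missing genotypes (and pseudomarkers) emit uniformly,
    so a fully ungenotyped individual keeps the population prior.
    """
    if not 0.0 <= epsilon < 0.5:
        raise ValueError("genotyping error rate must be in [0, 0.5)")
    gmap = pop.gmap if gmap is None else gmap
    if tuple(gmap.names) != tuple(pop.gmap.names):
        raise ValueError("map markers do not match the population's markers")
    grid = build_grid(gmap, step)
    n = len(pop)
    obs = np.full((n, len(grid)), MISSING, dtype=np.int8)
    on_marker = grid.marker_col >= 0
    obs[:, on_marker] = pop.genotypes[:, grid.marker_col[on_marker]]
    probs = np.zeros((n, len(grid), 3))
    for c in grid.chromosomes():
        idx = grid.index_on(c)
        two_state = c == "X"
        e, T, init = _chrom_hmm_arrays(grid, c, obs[:, idx], epsilon, two_state)
        L = len(idx)
        alpha = _forward(e, T, init)
        beta = np.ones((n, e.shape[2]))
        post = np.empty((L, n, e.shape[2]))
        post[L - 1] = alpha[L - 1]
        for j in range(L - 2, -1, -1):
            beta = (beta * e[:, j + 1, :]) @ T[j].T
            beta /= beta.sum(axis=1, keepdims=True)
            p = alpha[j] * beta
            post[j] = p / p.sum(axis=1, keepdims=True)
        if two_state:
            probs[:, idx, 0] = post.transpose(1, 0, 2)[:, :, 0]
            probs[:, idx, 2] = post.transpose(1, 0, 2)[:, :, 1]
        else:
            probs[:, idx, :] = post.transpose(1, 0, 2)
    return GenotypeProbabilities(grid=grid, probs=probs, obs=obs, epsilon=float(epsilon))


# ---------------------------------------------------------------------------
# multiple imputation
# ---------------------------------------------------------------------------


@dataclass
class ImputationSet:
    """M joint draws of complete grid genotypes from the HMM posterior."""

    grid: ScanGrid
    geno: np.ndarray  # (individuals, positions, M) int8, codes 0/1/2 (0/2 on X)
    M: int
    seed: int

    @property
    def n_individuals(self):
        return self.geno.shape[0]


def impute_genotypes(probs, M, seed):
    """Sample M whole-chromosome genotype paths per individual (FFBS).

    Joint forward-filtering backward-sampling draws, not independent
    per-position draws, so imputed chromosomes are valid recombinant
    mosaics.  Fixed seed gives identical output.
    """
    if M < 1:
        raise ValueError("need at least one imputation")
    rng = np.random.default_rng(seed)
    grid, obs, eps = probs.grid, probs.obs, probs.epsilon
    n = obs.shape[0]
    geno = np.empty((n, len(grid), M), dtype=np.int8)
    for c in grid.chromosomes():
        idx = grid.index_on(c)
        two_state = c == "X"
        e, T, init = _chrom_hmm_arrays(grid, c, obs[:, idx], eps, two_state)
        k = e.shape[2]
        L = len(idx)
        alpha = _forward(e, T, init)
        # sample the last position, then walk backwards
        state = _sample_cat(alpha[L - 1][:, None, :].repeat(M, axis=1), rng)
        states = np.empty((L, n, M), dtype=np.int8)
        states[L - 1] = state
        for j in range(L - 2, -1, -1):
            w = alpha[j][:, None, :] * T[j].T[state]  # (n, M, k)
            state = _sample_cat(w, rng)
            states[j] = state
        out = states.transpose(1, 0, 2)
        geno[:, idx, :] = (out * 2).astype(np.int8) if two_state else out.astype(np.int8)
    return ImputationSet(grid=grid, geno=geno, M=int(M), seed=int(seed))


def _sample_cat(w, rng):
    """Categorical draws along the last axis of a nonnegative weight array."""
    cdf = np.cumsum(w, axis=-1)
    u = rng.random(w.shape[:-1]) * cdf[..., -1]
    return (u[..., None] > cdf[..., :-1]).sum(axis=-1).astype(np.int8)


# ---------------------------------------------------------------------------
# LOD profiles
# ---------------------------------------------------------------------------


@dataclass
class LODProfile:
    """Per-position LOD values over a scan grid."""

    grid: ScanGrid
    lod: np.ndarray
    method: str = "im"
    info: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self):
        lod = np.asarray(self.lod, dtype=float)
        if np.any(~np.isfinite(lod)):
            raise ValueError("LOD profile contains non-finite values")
        if np.any(lod < -1e-9):
            raise ValueError("LOD values must be nonnegative")
        self.lod = np.maximum(lod, 0.0)

    def max(self, chrom=None):
        idx = np.arange(len(self.grid)) if chrom is None else self.grid.index_on(chrom)
        j = idx[np.argmax(self.lod[idx])]
        return self.grid.chrom[j], float(self.grid.pos[j]), float(self.lod[j])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"chrom": self.grid.chrom, "pos": self.grid.pos, "lod": self.lod})


@dataclass(frozen=True)
class PermutationConfig:
    """Permutation-test settings; ``strata`` (if given) partitions the
    individuals, and phenotypes are shuffled within each stratum only."""

    P: int = 1000
    alpha: float = 0.05
    strata: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        if self.P < 1:
            raise ValueError("need at least one permutation")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


def _combine_lod(lod_pm):
    """log10 of the arithmetic mean likelihood ratio across imputations."""
    M = lod_pm.shape[-1]
    mx = lod_pm.max(axis=-1, keepdims=True)
    return (mx[..., 0] + np.log10(np.mean(10.0 ** (lod_pm - mx), axis=-1)))


def _anova_lod(G, Y, positions=None):
    """Single-locus regression LOD for every position/imputation/phenotype.

    ``G`` is the (n, P, M) imputed genotype tensor, ``Y`` an (n, R) matrix
    of phenotype columns.  The additive+dominance single-locus regression
    is exactly the genotype-class-means model, so RSS comes from class
    sums; on the male X only two classes occur and the model reduces to
    additive-only automatically.  Returns an (R, P', M) LOD array.
    """
    n = G.shape[0]
    if positions is not None:
        G = G[:, positions, :]
    P, M = G.shape[1], G.shape[2]
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    R = Y.shape[1]
    sy = Y.sum(axis=0)
    syy = (Y * Y).sum(axis=0)
    rss0 = syy - sy * sy / n
    if np.any(rss0 <= 0):
        raise ValueError("phenotype has zero variance")
    flat = G.reshape(n, P * M)
    rss1 = np.broadcast_to(syy[:, None], (R, P * M)).copy()
    for code in (0, 1, 2):
        mask = (flat == code)
        nc = mask.sum(axis=0)
        has = nc > 0
        s_c = Y.T @ mask  # (R, P*M)
        rss1[:, has] -= s_c[:, has] ** 2 / nc[has]
    rss1 = np.maximum(rss1, 1e-300)
    lod = (n / 2.0) * np.log10(rss0[:, None] / rss1)
    return np.maximum(lod, 0.0).reshape(R, P, M)


def interval_mapping(imps, phenotype):
    """Single-QTL genome scan (IM) from an imputation set.

    Every phenotyped individual enters; those without genotypes are
    represented through their imputations, which default to the
    population genotype expectations.  Per-imputation likelihood ratios
    are combined as LOD = log10(mean LR).
    """
    y = np.asarray(phenotype, dtype=float)
    lod_pm = _anova_lod(imps.geno, y)[0]
    return LODProfile(grid=imps.grid, lod=_combine_lod(lod_pm), method="im",
                      info={"M": imps.M})


# ---------------------------------------------------------------------------
# composite interval mapping
# ---------------------------------------------------------------------------


def _marker_dosages(imps):
    """Posterior-mean additive/dominance dosages at marker positions."""
    mk = np.flatnonzero(imps.grid.is_marker)
    g = imps.geno[:, mk, :].astype(float)
    x = g.mean(axis=2) - 1.0
    z = (imps.geno[:, mk, :] == GENO_AB).mean(axis=2)
    return mk, x, z


def _forward_select(y, cols_per_marker, n_cov):
    """Greedy RSS-minimizing forward selection of marker covariates."""
    n = len(y)
    chosen = []
    base = np.ones((n, 1))
    for _ in range(n_cov):
        q, _ = np.linalg.qr(base)
        yr = y - q @ (q.T @ y)
        best, best_rss = None, np.inf
        for j, cols in enumerate(cols_per_marker):
            if j in chosen:
                continue
            cr = cols - q @ (q.T @ cols)
            bb, rss, _rank, _sv = np.linalg.lstsq(cr, yr, rcond=None)
            rss = float(rss[0]) if len(rss) else float(np.sum((yr - cr @ bb) ** 2))
            if rss < best_rss:
                best, best_rss = j, rss
        chosen.append(best)
        base = np.hstack([base, cols_per_marker[best]])
    return chosen


def _two_var_rss(yr, xr, zr, syy):
    """RSS of yr ~ xr + zr (no intercept; all inputs pre-residualized),
    vectorized over the trailing axis.  Falls back to the additive-only
    model when the dominance column is (numerically) degenerate."""
    sxx = np.sum(xr * xr, axis=0)
    szz = np.sum(zr * zr, axis=0)
    sxz = np.sum(xr * zr, axis=0)
    sxy = xr.T @ yr if yr.ndim == 1 else np.sum(xr * yr, axis=0)
    szy = zr.T @ yr if yr.ndim == 1 else np.sum(zr * yr, axis=0)
    det = sxx * szz - sxz * sxz
    scale = np.maximum(sxx * szz, 1e-30)
    ok = det > 1e-10 * scale
    expl = np.zeros_like(sxx)
    # full 2x2 solve where well-conditioned
    expl[ok] = (szz[ok] * sxy[ok] ** 2 - 2 * sxz[ok] * sxy[ok] * szy[ok]
                + sxx[ok] * szy[ok] ** 2) / det[ok]
    only_x = (~ok) & (sxx > 1e-12)
    expl[only_x] = sxy[only_x] ** 2 / sxx[only_x]
    return np.maximum(syy - expl, 1e-300)


def composite_interval_mapping(imps, phenotype, window=10.0, n_covariates=4):
    """CIM: interval mapping with marker covariates outside a window.

    Covariate markers are picked once by forward selection on
    posterior-mean marker dosages; at each test position, covariates
    within ``window/2`` cM on the same chromosome are dropped from both
    the null and the full model.  ``n_covariates=0`` reduces exactly to
    :func:`interval_mapping`.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    grid = imps.grid
    y = np.asarray(phenotype, dtype=float)
    n = len(y)
    mk, xbar, zbar = _marker_dosages(imps)
    n_markers = xbar.shape[1]
    if n_covariates >= n_markers:
        raise ValueError(f"cannot select {n_covariates} covariates from {n_markers} markers")
    if n_covariates < 0:
        raise ValueError("covariate count must be nonnegative")
    cols = []
    for j in range(n_markers):
        gi = mk[j]
        if grid.is_x[gi]:
            cols.append(xbar[:, [j]])
        else:
            cols.append(np.column_stack([xbar[:, j], zbar[:, j]]))
    chosen = _forward_select(y, cols, n_covariates)
    cov_pos = [(grid.chrom[mk[j]], grid.pos[mk[j]]) for j in chosen]

    # group positions by their active covariate subset
    active_sets = []
    dropped_record = []
    for p in range(len(grid)):
        act = tuple(
            k for k, j in enumerate(chosen)
            if not (grid.chrom[mk[j]] == grid.chrom[p]
                    and abs(grid.pos[mk[j]] - grid.pos[p]) < window / 2.0)
        )
        active_sets.append(act)
        dropped_record.append(tuple(k for k in range(len(chosen)) if k not in act))

    lod_pm = np.empty((len(grid), imps.M))
    cache = {}
    xg = imps.geno.astype(float) - 1.0
    zg = (imps.geno == GENO_AB).astype(float)
    for act in set(active_sets):
        if act not in cache:
            C = np.hstack([np.ones((n, 1))] + [cols[chosen[k]] for k in act])
            q, _ = np.linalg.qr(C)
            yr = y - q @ (q.T @ y)
            cache[act] = (q, yr, float(np.sum(yr * yr)))
    for p in range(len(grid)):
        q, yr, rss0 = cache[active_sets[p]]
        xr = xg[:, p, :] - q @ (q.T @ xg[:, p, :])
        zr = zg[:, p, :] - q @ (q.T @ zg[:, p, :])
        rss1 = _two_var_rss(yr, xr, zr, rss0)
        lod_pm[p] = (n / 2.0) * np.log10(rss0 / rss1)
    return LODProfile(
        grid=grid,
        lod=_combine_lod(np.maximum(lod_pm, 0.0)),
        method="cim",
        info={
            "M": imps.M,
            "window": window,
            "covariates": cov_pos,
            "dropped_by_position": dropped_record,
        },
    )


# ---------------------------------------------------------------------------
# permutation thresholds
# ---------------------------------------------------------------------------


def _permuted_matrix(y, config):
    """(n, P) matrix of permuted phenotypes, within strata when given."""
    rng = np.random.default_rng(config.seed)
    n = len(y)
    Y = np.empty((n, config.P))
    if config.strata is None:
        groups = [np.arange(n)]
    else:
        strata = np.asarray(config.strata)
        if len(strata) != n:
            raise ValueError("strata labels must cover every individual")
        groups = [np.flatnonzero(strata == s) for s in np.unique(strata)]
    for p in range(config.P):
        col = np.empty(n)
        for g in groups:
            col[g] = y[g[rng.permutation(len(g))]]
        Y[:, p] = col
    return Y


def permutation_threshold(imps, phenotype, config, scope="autosome",
                          return_null=False, chunk=64):
    """Genome-wide LOD threshold from permutations, for one scope.

    ``scope`` restricts the scan to ``"autosome"``, ``"X"`` or ``"all"``
    chromosomes (X- and autosome-specific thresholds are obtained by two
    calls).  The threshold is the ceil((1-alpha)·P)-th order statistic of
    the per-permutation maximum LODs.
    """
    y = np.asarray(phenotype, dtype=float)
    grid = imps.grid
    if scope == "autosome":
        positions = np.flatnonzero(~grid.is_x)
    elif scope == "X":
        positions = np.flatnonzero(grid.is_x)
    elif scope == "all":
        positions = np.arange(len(grid))
    else:
        raise ValueError(f"unknown scope {scope!r}")
    if len(positions) == 0:
        raise ValueError(f"no scan positions in scope {scope!r}")
    if config.P * config.alpha < 1:
        warnings.warn(
            "P*alpha < 1: the threshold is the maximum permutation LOD", stacklevel=2
        )
    Y = _permuted_matrix(y, config)
    maxima = np.empty(config.P)
    for start in range(0, config.P, chunk):
        block = slice(start, min(start + chunk, config.P))
        lod = _combine_lod(_anova_lod(imps.geno, Y[:, block], positions=positions))
        maxima[block] = lod.max(axis=1)
    k = max(int(math.ceil((1.0 - config.alpha) * config.P)), 1)
    thr = float(np.sort(maxima)[k - 1])
    return (thr, maxima) if return_null else thr
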