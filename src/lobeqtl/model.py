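"""Multiple-QTL model fitting with epistasis, on imputed genotypes.

A model is a set of grid positions plus interaction pairs.  Each locus
contributes an additive column x (-1/0/+1) and, off the male X, a
dominance column z (0/1/0); an interaction contributes the cross products
of its two loci's columns (four terms for two autosomal loci).  Within
each imputation the model is an ordinary least-squares fit; per-term and
total variance explained come from drop-one residual-sum-of-squares
comparisons, and results are combined across imputations weighted by the
imputation's model likelihood.  LODs combine as log10(mean LR), matching
the genome-scan convention.

Also here: one-QTL scans conditional on a base model
(:func:`scan_additional`), two-dimensional epistasis scans
(:func:`scan_two`), and LOD-drop support intervals
(:func:`lod_support_interval`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GENO_AB
from .scan import LODProfile, _combine_lod, _two_var_rss

__all__ = [
    "FittedQTLModel",
    "SupportInterval",
    "ScanTwoResult",
    "fit_qtl_model",
    "scan_additional",
    "scan_two",
    "profile_qtl",
    "refine_positions",
    "lod_support_interval",
]


# ---------------------------------------------------------------------------
# model design construction
# ---------------------------------------------------------------------------


def _model_positions(grid, loci):
    idx = [grid.locate(c, p) for c, p in loci]
    if len(set(idx)) != len(idx):
        dup = [loci[i] for i in range(len(idx)) if idx.count(idx[i]) > 1]
        raise ValueError(f"coincident model loci (collinear design): {dup}")
    return idx


class _ModelDesign:
    """Column layout of one multi-QTL model (shared across imputations)."""

    def __init__(self, grid, loci, interactions):
        self.grid = grid
        self.loci = [(str(c), float(p)) for c, p in loci]
        self.interactions = [(int(i), int(j)) for i, j in interactions]
        for i, j in self.interactions:
            if not (0 <= i < len(self.loci) and 0 <= j < len(self.loci)) or i == j:
                raise ValueError("interaction pairs must index two distinct model loci")
        self.pos_idx = _model_positions(grid, self.loci)
        self.is_x = [bool(grid.is_x[k]) for k in self.pos_idx]
        # column bookkeeping: 0 is the intercept
        self.col_names = ["intercept"]
        self.locus_cols = []
        for l, x in enumerate(self.is_x):
            cols = [len(self.col_names)]
            self.col_names.append(f"Q{l + 1}.a")
            if not x:
                cols.append(len(self.col_names))
                self.col_names.append(f"Q{l + 1}.d")
            self.locus_cols.append(cols)
        self.int_cols = []
        for i, j in self.interactions:
            cols = []
            for pi, si in enumerate(("a", "d") if not self.is_x[i] else ("a",)):
                for pj, sj in enumerate(("a", "d") if not self.is_x[j] else ("a",)):
                    cols.append(len(self.col_names))
                    self.col_names.append(f"Q{i + 1}{si}:Q{j + 1}{sj}")
            self.int_cols.append(cols)

    def matrix(self, geno_m):
        """Design matrix for one imputation's (n, positions) genotype slice."""
        n = geno_m.shape[0]
        cols = [np.ones(n)]
        xs, zs = [], []
        for l, k in enumerate(self.pos_idx):
            g = geno_m[:, k].astype(float)
            x = g - 1.0
            z = (geno_m[:, k] == GENO_AB).astype(float)
            xs.append(x)
            zs.append(z)
            cols.append(x)
            if not self.is_x[l]:
                cols.append(z)
        for i, j in self.interactions:
            ti = [xs[i]] + ([zs[i]] if not self.is_x[i] else [])
            tj = [xs[j]] + ([zs[j]] if not self.is_x[j] else [])
            for ci in ti:
                for cj in tj:
                    cols.append(ci * cj)
        return np.column_stack(cols)

    def term_drops(self):
        """(term name, columns removed) for each drop-one comparison.

        Dropping a locus also drops every interaction that contains it,
        the convention of a fitqtl-style analysis.
        """
        drops = []
        for l, cols in enumerate(self.locus_cols):
            extra = [c for t, icols in enumerate(self.int_cols)
                     if l in self.interactions[t] for c in icols]
            drops.append((f"Q{l + 1}", sorted(cols + extra)))
        for t, icols in enumerate(self.int_cols):
            i, j = self.interactions[t]
            drops.append((f"Q{i + 1}:Q{j + 1}", list(icols)))
        return drops


def _rss(X, y):
    beta, res, rank, _sv = np.linalg.lstsq(X, y, rcond=None)
    if len(res) and rank == X.shape[1]:
        return float(res[0]), beta
    r = y - X @ beta
    return float(r @ r), beta


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass
class FittedQTLModel:
    """Joint fit of several QTL (and interactions) to one phenotype.

    ``terms`` has one row per locus and per interaction: effect estimates
    (additive ``a``, dominance ``d``; interaction coefficients reported as
    their additive-by-additive component), drop-one percent variance, and
    per-term LOD.  ``total_pct_var`` is 100·(1 − RSS_full/TSS) combined
    across imputations; ``lod`` is the whole-model LOD against the
    intercept-only null.  Percent variance attributed to linked terms can
    legitimately sum to more than the total; nothing is renormalized.
    """

    terms: pd.DataFrame
    total_pct_var: float
    lod: float
    n: int
    loci: list
    interactions: list
    info: dict = field(default_factory=dict)

    def __repr__(self):
        return (
            f"<FittedQTLModel {len(self.loci)} QTL, {len(self.interactions)} interaction(s): "
            f"total %var {self.total_pct_var:.1f}, LOD {self.lod:.1f}, n={self.n}>"
        )


def fit_qtl_model(imps, phenotype, loci, interactions=()):
    """Fit a multiple-QTL model by imputation.

    Parameters
    ----------
    imps : ImputationSet
    phenotype : array of length n (no missing values)
    loci : list of (chrom, pos) on the scan grid (snapped to the nearest
        grid point)
    interactions : list of (i, j) index pairs into ``loci``
    """
    y = np.asarray(phenotype, dtype=float)
    n = len(y)
    design = _ModelDesign(imps.grid, loci, interactions)
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss <= 0:
        raise ValueError("phenotype has zero variance")
    M = imps.M
    drops = design.term_drops()
    rss_full = np.empty(M)
    rss_drop = np.empty((len(drops), M))
    betas = np.empty((M, len(design.col_names)))
    for m in range(M):
        X = design.matrix(imps.geno[:, :, m])
        rss_full[m], betas[m] = _rss(X, y)
        for t, (_name, cols) in enumerate(drops):
            keep = [c for c in range(X.shape[1]) if c not in cols]
            rss_drop[t, m], _b = _rss(X[:, keep], y)
    rss_full = np.maximum(rss_full, 1e-300)

    # weights: per-imputation model likelihood (profiled Gaussian)
    logw = -(n / 2.0) * np.log(rss_full)
    logw -= logw.max()
    w = np.exp(logw)
    w /= w.sum()

    lod_m = (n / 2.0) * np.log10(tss / rss_full)
    model_lod = float(_combine_lod(lod_m[None, :])[0])
    term_lod_m = (n / 2.0) * np.log10(rss_drop / rss_full[None, :])
    term_lod = _combine_lod(term_lod_m)
    term_pct = 100.0 * (rss_drop - rss_full[None, :]) / tss @ w
    total_pct = float(100.0 * (1.0 - rss_full / tss) @ w)

    beta_bar = w @ betas
    rows = []
    for l, (c, p) in enumerate(design.loci):
        a = beta_bar[design.locus_cols[l][0]]
        d = beta_bar[design.locus_cols[l][1]] if len(design.locus_cols[l]) > 1 else 0.0
        rows.append(
            {
                "term": f"Q{l + 1}",
                "chrom": c,
                "pos": imps.grid.pos[design.pos_idx[l]],
                "a": a,
                "d": d,
                "pct_var": term_pct[l],
                "lod": term_lod[l],
            }
        )
    for t, (i, j) in enumerate(design.interactions):
        rows.append(
            {
                "term": f"Q{i + 1}:Q{j + 1}",
                "chrom": "",
                "pos": np.nan,
                "a": beta_bar[design.int_cols[t][0]],
                "d": np.nan,
                "pct_var": term_pct[len(design.loci) + t],
                "lod": term_lod[len(design.loci) + t],
            }
        )
    return FittedQTLModel(
        terms=pd.DataFrame(rows),
        total_pct_var=total_pct,
        lod=model_lod,
        n=n,
        loci=design.loci,
        interactions=design.interactions,
        info={
            "M": M,
            "effective_imputations": float(1.0 / np.sum(w**2)),
            "pct_var_from_lod": 100.0 * (1.0 - 10.0 ** (-2.0 * model_lod / n)),
        },
    )


# ---------------------------------------------------------------------------
# scans conditional on a model
# ---------------------------------------------------------------------------


def scan_additional(imps, phenotype, loci, interactions=()):
    """Scan for one more QTL on top of a base model.

    At each grid position the base-model terms act as covariates; the LOD
    compares base+locus to base, combined across imputations.  Positions
    coincident with a modeled locus give LOD ~ 0.
    """
    y = np.asarray(phenotype, dtype=float)
    n = len(y)
    design = _ModelDesign(imps.grid, loci, interactions)
    G = imps.geno
    lod_pm = np.empty((G.shape[1], imps.M))
    for m in range(imps.M):
        X = design.matrix(G[:, :, m])
        q, _ = np.linalg.qr(X)
        yr = y - q @ (q.T @ y)
        rss0 = float(yr @ yr)
        xg = G[:, :, m].astype(float) - 1.0
        zg = (G[:, :, m] == GENO_AB).astype(float)
        xr = xg - q @ (q.T @ xg)
        zr = zg - q @ (q.T @ zg)
        rss1 = _two_var_rss(yr, xr, zr, rss0)
        lod_pm[:, m] = (n / 2.0) * np.log10(rss0 / rss1)
    return LODProfile(
        grid=imps.grid,
        lod=_combine_lod(np.maximum(lod_pm, 0.0)),
        method="addqtl",
        info={"M": imps.M, "base_loci": design.loci},
    )


def profile_qtl(imps, phenotype, loci, interactions, which, chrom=None):
    """Conditional LOD profile of one model QTL over its chromosome.

    Locus ``which`` is slid along the chromosome while every other model
    term stays fixed; its interactions move with it.  The LOD at each
    position compares the full model to the model with the locus (and its
    interactions) removed — the profile used to refine positions and to
    build per-QTL support intervals in a multiple-QTL context, where
    linked QTL would otherwise contaminate each other's single-locus
    profiles.
    """
    y = np.asarray(phenotype, dtype=float)
    n = len(y)
    grid = imps.grid
    loci = [(str(c), float(p)) for c, p in loci]
    chrom = loci[which][0] if chrom is None else chrom
    others = [l for q, l in enumerate(loci) if q != which]
    other_ints = []
    moving_partners = []
    for i, j in interactions:
        if which in (i, j):
            partner = j if i == which else i
            moving_partners.append(partner - (partner > which))
        else:
            other_ints.append((i - (i > which), j - (j > which)))
    base = _ModelDesign(grid, others, other_ints)
    cidx = grid.index_on(chrom)
    lod_pm = np.empty((len(cidx), imps.M))
    for m in range(imps.M):
        Xb = base.matrix(imps.geno[:, :, m])
        q, _ = np.linalg.qr(Xb)
        yr = y - q @ (q.T @ y)
        rss0 = float(yr @ yr)
        gsl = imps.geno[:, cidx, m]
        xg = gsl.astype(float) - 1.0
        zg = (gsl == GENO_AB).astype(float)
        two_state = bool(grid.is_x[cidx[0]])
        cols = [xg] + ([] if two_state else [zg])
        for p_ix in moving_partners:
            k = base.pos_idx[p_ix]
            xo = imps.geno[:, k, m].astype(float) - 1.0
            zo = (imps.geno[:, k, m] == GENO_AB).astype(float)
            partner_cols = [xo] + ([] if base.is_x[p_ix] else [zo])
            new = []
            for mov in cols[: (1 if two_state else 2)]:
                for pc in partner_cols:
                    new.append(mov * pc[:, None])
            cols = cols + new
        C = np.stack(cols, axis=-1)  # (n, Pc, k)
        flat = C.reshape(len(y), -1)
        Cr = (flat - q @ (q.T @ flat)).reshape(C.shape)
        G = np.einsum("npk,npl->pkl", Cr, Cr)
        b = np.einsum("npk,n->pk", Cr, yr)
        k = G.shape[-1]
        G = G + 1e-10 * np.trace(G, axis1=1, axis2=2)[:, None, None] / k * np.eye(k)
        beta = np.linalg.solve(G, b[..., None])[..., 0]
        rss1 = np.maximum(rss0 - np.einsum("pk,pk->p", beta, b), 1e-300)
        lod_pm[:, m] = (n / 2.0) * np.log10(rss0 / rss1)
    prof_lod = np.zeros(len(grid))
    prof_lod[cidx] = _combine_lod(np.maximum(lod_pm, 0.0))
    full = LODProfile(grid=grid, lod=prof_lod, method="profile",
                      info={"which": which, "chrom": chrom, "M": imps.M})
    return full


def _hill_climb(lod, k):
    while True:
        if k > 0 and lod[k - 1] > lod[k]:
            k -= 1
        elif k < len(lod) - 1 and lod[k + 1] > lod[k]:
            k += 1
        else:
            return k


def refine_positions(imps, phenotype, loci, interactions=(), rounds=2):
    """Refine model QTL positions by iterated conditional hill climbing.

    Each round slides every locus to the local maximum of its conditional
    profile nearest its current position (a refineqtl-style update; the
    local move keeps a locus attached to its own peak rather than jumping
    to another QTL's).  Returns the refined loci and the final per-locus
    profiles, from which 2-LOD support intervals are usually taken.
    """
    loci = [(str(c), float(p)) for c, p in loci]
    grid = imps.grid
    profiles = [None] * len(loci)
    for _ in range(max(rounds, 1)):
        for q in range(len(loci)):
            prof = profile_qtl(imps, phenotype, loci, interactions, q)
            cidx = grid.index_on(loci[q][0])
            start = int(np.argmin(np.abs(grid.pos[cidx] - loci[q][1])))
            k = _hill_climb(prof.lod[cidx], start)
            loci[q] = (loci[q][0], float(grid.pos[cidx[k]]))
            profiles[q] = prof
    return loci, profiles


@dataclass
class ScanTwoResult:
    """Two-dimensional scan: for each position pair, the LOD of the full
    (two loci + interaction) and additive (two loci) models against the
    null; the interaction LOD is their difference and is nonnegative."""

    grid_chrom: np.ndarray
    grid_pos: np.ndarray
    pairs: np.ndarray  # (k, 2) indices into the coarse grid
    full_lod: np.ndarray
    add_lod: np.ndarray

    @property
    def int_lod(self):
        return self.full_lod - self.add_lod

    def peak_interaction(self):
        """((chrom, pos), (chrom, pos), interaction LOD) at the best pair."""
        k = int(np.argmax(self.int_lod))
        i, j = self.pairs[k]
        return (
            (self.grid_chrom[i], float(self.grid_pos[i])),
            (self.grid_chrom[j], float(self.grid_pos[j])),
            float(self.int_lod[k]),
        )


def scan_two(imps, phenotype, coarsen=5.0, min_sep=None):
    """Two-QTL scan over a coarsened grid (default 5 cM spacing).

    ``min_sep`` (default: the coarsening step) excludes same-chromosome
    pairs closer than that separation, where the two loci are nearly
    collinear.
    """
    if coarsen is not None and coarsen <= 0:
        raise ValueError("grid coarsening must be positive")
    y = np.asarray(phenotype, dtype=float)
    n = len(y)
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss <= 0:
        raise ValueError("phenotype has zero variance")
    grid = imps.grid
    keep = []
    for c in grid.chromosomes():
        idx = grid.index_on(c)
        last = -np.inf
        for k in idx:
            if coarsen is None or grid.pos[k] >= last + coarsen or k == idx[0]:
                keep.append(k)
                last = grid.pos[k]
    keep = np.array(keep)
    sep = coarsen if min_sep is None else min_sep
    pairs = []
    for ai in range(len(keep)):
        for aj in range(ai + 1, len(keep)):
            i, j = keep[ai], keep[aj]
            if grid.chrom[i] == grid.chrom[j] and sep is not None \
                    and grid.pos[j] - grid.pos[i] < sep:
                continue
            pairs.append((ai, aj))
    pairs = np.array(pairs, dtype=int)
    G = imps.geno[:, keep, :]
    full_pm = np.empty((len(pairs), imps.M))
    add_pm = np.empty((len(pairs), imps.M))
    for m in range(imps.M):
        xg = G[:, :, m].astype(float) - 1.0
        zg = (G[:, :, m] == GENO_AB).astype(float)
        for k, (ai, aj) in enumerate(pairs):
            cols = [np.ones(n), xg[:, ai], xg[:, aj]]
            if not grid.is_x[keep[ai]]:
                cols.append(zg[:, ai])
            if not grid.is_x[keep[aj]]:
                cols.append(zg[:, aj])
            Xa = np.column_stack(cols)
            ti = [xg[:, ai]] + ([zg[:, ai]] if not grid.is_x[keep[ai]] else [])
            tj = [xg[:, aj]] + ([zg[:, aj]] if not grid.is_x[keep[aj]] else [])
            Xf = np.column_stack([Xa] + [ci * cj for ci in ti for cj in tj])
            rss_a, _ = _rss(Xa, y)
            rss_f, _ = _rss(Xf, y)
            add_pm[k, m] = (n / 2.0) * math.log10(tss / max(rss_a, 1e-300))
            full_pm[k, m] = (n / 2.0) * math.log10(tss / max(rss_f, 1e-300))
    full = _combine_lod(full_pm)
    add = _combine_lod(add_pm)
    return ScanTwoResult(
        grid_chrom=grid.chrom[keep],
        grid_pos=grid.pos[keep],
        pairs=pairs,
        full_lod=np.maximum(full, 0.0),
        add_lod=np.minimum(np.maximum(add, 0.0), full),
    )


# ---------------------------------------------------------------------------
# support intervals
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SupportInterval:
    """LOD-drop support interval around one peak."""

    chrom: str
    peak: float
    lower: float
    upper: float
    drop: float
    whole_chromosome: bool = False

    def __contains__(self, pos):
        return self.lower - 1e-9 <= pos <= self.upper + 1e-9

    def __str__(self):
        tag = " (whole chromosome)" if self.whole_chromosome else ""
        return f"{self.chrom}:{self.lower:.0f}-{self.upper:.0f} cM (peak {self.peak:.0f}){tag}"


def lod_support_interval(profile, chrom, peak_pos, drop=2.0):
    """Support interval: the contiguous grid run around the peak where
    LOD stays within ``drop`` of the peak value.

    If the whole chromosome stays above peak−drop the interval covers the
    chromosome and is flagged.  The nominated peak must be a local
    maximum of the profile on its chromosome.
    """
    if drop < 0:
        raise ValueError("LOD drop must be nonnegative")
    grid = profile.grid
    idx = grid.index_on(chrom)
    if len(idx) == 0:
        raise KeyError(f"chromosome {chrom!r} not in profile")
    lod = profile.lod[idx]
    pos = grid.pos[idx]
    k = int(np.argmin(np.abs(pos - peak_pos)))
    if (k > 0 and lod[k] < lod[k - 1] - 1e-9) or \
            (k < len(lod) - 1 and lod[k] < lod[k + 1] - 1e-9):
        raise ValueError(f"{chrom}:{peak_pos:g} is not a local maximum of the profile")
    thr = lod[k] - drop
    lo = k
    while lo > 0 and lod[lo - 1] >= thr:
        lo -= 1
    hi = k
    while hi < len(lod) - 1 and lod[hi + 1] >= thr:
        hi += 1
    whole = lo == 0 and hi == len(lod) - 1
    return SupportInterval(
        chrom=str(chrom),
        peak=float(pos[k]),
        lower=float(pos[lo]),
        upper=float(pos[hi]),
        drop=float(drop),
        whole_chromosome=bool(whole),
    )
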