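"""Synthetic crosses and synthetic posterior-lobe outlines.

This module generates the two study populations the rest of the package
analyzes — an F2 intercross and an F17 advanced intercross line (AIL)
between two inbred parents — together with lobe outlines whose shape is
driven by a configurable QTL architecture.  The genetics follow the
Drosophila rules that matter for mapping:

* crossovers occur in female meiosis only (Haldane model: per-chromosome
  crossover count ~ Poisson(map length / 100), positions uniform in cM);
  males transmit intact chromosomes;
* the X is hemizygous in males: sons receive a (possibly recombinant) X
  from their mother only;
* optional viability selection at nominated loci, applied to zygotes by
  rejection sampling, which reproduces the allele-frequency skew observed
  in long-running laboratory AILs;
* selective genotyping: only the phenotypic tails keep their genotypes,
  everyone keeps phenotypes.

Outlines are coordinate lists only (no rasters).  A lobe template is a
smooth half-ellipse-like blob closed by a horizontal baseline; a latent
shape score stretches it vertically by (1+s) and compresses it
horizontally by 1/(1+s), so area is preserved while the height:width
ratio moves — higher (Sam-like) scores give squatter lobes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core import (
    ARM_LENGTHS,
    ARM_OFFSETS,
    ARM_TO_CHROM,
    GENO_AB,
    GENO_BB,
    MISSING,
    GeneticMap,
    Population,
)
from .morphometrics import RawOutline

__all__ = [
    "QTLArchitecture",
    "CrossDesign",
    "LobeTemplate",
    "make_marker_panel",
    "simulate_cross",
    "assign_phenotypes",
    "genetic_values",
    "calibrate_residual_sd",
    "select_tails",
    "make_lobe_template",
    "render_lobe_outline",
    "score_shape_map",
    "study_marker_panel",
    "study_architecture",
    "f2_design",
    "f17_design",
    "parent_templates",
    "PARENT_HW",
]

#: Height:width ratios of the two mapping parents (tall/narrow vs squat/broad).
PARENT_HW = {"A": 1.08, "B": 0.70}

#: Lobe areas of the two parents, mm^2.
PARENT_AREA = {"A": 3.14e-3, "B": 3.06e-3}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QTLArchitecture:
    """Generative trait architecture on the latent (mPC1-like) scale.

    ``loci`` is a list of ``(chrom, pos_cM, a, d)``: additive effect *a* is
    half the difference between the two homozygote means (B-allele
    increasing), dominance *d* the heterozygote deviation from the
    homozygote midpoint.  ``interactions`` pairs locus indices with the
    four cross-term coefficients ``(aa, ad, da, dd)`` multiplying
    ``x_i*x_j, x_i*z_j, z_i*x_j, z_i*z_j`` where x is the -1/0/+1 additive
    coding and z the 0/1/0 dominance coding.

    Exactly one of ``residual_sd`` (per-lobe environmental SD, phenotype
    units) or ``heritability`` (target genetic fraction of per-lobe score
    variance, calibrated on the simulated population) must be set.
    ``paired_corr`` is the target correlation between the left- and
    right-lobe scores of the same fly.
    """

    loci: tuple
    interactions: tuple = ()
    residual_sd: float | None = None
    heritability: float | None = None
    paired_corr: float = 0.85

    def __post_init__(self):
        object.__setattr__(self, "loci", tuple(tuple(l) for l in self.loci))
        object.__setattr__(self, "interactions", tuple(
            (int(i), int(j), tuple(float(c) for c in cs)) for i, j, cs in self.interactions
        ))
        for i, j, cs in self.interactions:
            if not (0 <= i < len(self.loci) and 0 <= j < len(self.loci) and i != j):
                raise ValueError("interaction indices must name two distinct architecture loci")
            if len(cs) != 4:
                raise ValueError("each interaction needs 4 cross-term coefficients (aa, ad, da, dd)")
        if (self.residual_sd is None) == (self.heritability is None):
            raise ValueError("set exactly one of residual_sd and heritability")
        if self.residual_sd is not None and self.residual_sd <= 0:
            raise ValueError("residual SD must be positive")
        if self.heritability is not None and not 0 < self.heritability < 1:
            raise ValueError("heritability must be in (0, 1)")
        if not 0.0 <= self.paired_corr <= 1.0:
            raise ValueError("paired-lobe correlation target must be in [0, 1]")

    def positions(self):
        return [(c, p) for c, p, _a, _d in self.loci]


@dataclass(frozen=True)
class CrossDesign:
    """How a mapping population is bred.

    ``t`` is the final generation (2 = F2 intercross, 17 = the study's
    AIL).  Intermediate generations are kept at ``census`` individuals
    with an equal sex ratio and random union of gametes.  ``viability``
    lists ``(chrom, pos_cM, genotype_code, relative_fitness)`` entries
    applied to every zygote.  ``tail_count`` is the per-side quota used
    later by :func:`select_tails`.
    """

    t: int
    n_phenotyped: int
    census: int = 500
    reciprocal_f1: bool = False
    viability: tuple = ()
    tail_count: int = 47

    def __post_init__(self):
        object.__setattr__(self, "viability", tuple(tuple(v) for v in self.viability))
        if self.t < 2:
            raise ValueError("final generation t must be >= 2 (t=2 is an F2)")
        if self.census < 2:
            raise ValueError("census size must be at least 2")
        if self.n_phenotyped < 1:
            raise ValueError("need at least one phenotyped individual")
        for _c, _p, _g, w in self.viability:
            if not 0.0 < w <= 1.0:
                raise ValueError("relative fitnesses must be in (0, 1]")


# ---------------------------------------------------------------------------
# marker panel
# ---------------------------------------------------------------------------


def make_marker_panel(counts, arm_lengths=None):
    """Evenly spaced marker panel given per-arm counts.

    Markers on an arm of length L are placed at ``linspace(0, L, count)``
    within the arm (single markers sit at the arm midpoint), then shifted
    to chromosome coordinates, so a count of 11 on a 100 cM arm gives an
    exact 10 cM spacing.
    """
    arm_lengths = dict(ARM_LENGTHS if arm_lengths is None else arm_lengths)
    for arm in counts:
        if arm == "4" or ARM_TO_CHROM.get(arm) == "4":
            raise ValueError(
                "chromosome 4 cannot carry panel markers: the dot chromosome is out of scope"
            )
        if arm not in arm_lengths:
            raise ValueError(f"unknown arm {arm!r}")
        if counts[arm] < 1:
            raise ValueError(f"need at least one marker on arm {arm}")
    names, chroms, arms, pos = [], [], [], []
    for arm in ("X", "2L", "2R", "3L", "3R"):
        if arm not in counts:
            continue
        k, length = counts[arm], arm_lengths[arm]
        rel = np.array([length / 2.0]) if k == 1 else np.linspace(0.0, length, k)
        offset = ARM_OFFSETS.get(arm, 0.0)
        for i, p in enumerate(rel):
            names.append(f"{arm}{i + 1:02d}")
            chroms.append(ARM_TO_CHROM[arm])
            arms.append(arm)
            pos.append(offset + p)
    order = np.lexsort((np.array(pos), np.array([("X", "2", "3").index(c) for c in chroms])))
    return GeneticMap(
        names=[names[i] for i in order],
        chrom=np.array(chroms, dtype=object)[order],
        pos=np.array(pos)[order],
        arm=np.array(arms, dtype=object)[order],
    )


def study_marker_panel():
    """The study's 87-marker SNP panel layout: X=16, 2L=22, 2R=17, 3L=12, 3R=20."""
    return make_marker_panel({"X": 16, "2L": 22, "2R": 17, "3L": 12, "3R": 20})


# ---------------------------------------------------------------------------
# meiosis and breeding
# ---------------------------------------------------------------------------


class _SimState:
    """Haplotypes of one generation: chrom -> (n, 2, n_loci) int8 plus sexes.

    Males carry a duplicated maternal X in both slots, so summing slots
    yields the hemizygous codes 0/2 directly.
    """

    def __init__(self, is_male, haps):
        self.is_male = is_male
        self.haps = haps

    def __len__(self):
        return len(self.is_male)


def _female_gametes(haps, idx, pos, rng):
    """Recombinant gametes from female parents ``idx`` (Haldane model)."""
    n = len(idx)
    L = len(pos)
    span = float(pos[-1] - pos[0]) if L > 1 else 0.0
    phase = rng.integers(0, 2, n)
    k = rng.poisson(span / 100.0, n) if span > 0 else np.zeros(n, dtype=int)
    kmax = int(k.max()) if n else 0
    if kmax == 0:
        hap_idx = np.broadcast_to(phase[:, None], (n, L))
    else:
        u = rng.uniform(pos[0], pos[-1], (n, kmax))
        u = np.where(np.arange(kmax)[None, :] < k[:, None], u, np.inf)
        n_before = (u[:, :, None] <= pos[None, None, :]).sum(axis=1)
        hap_idx = (phase[:, None] + n_before) % 2
    parent = haps[idx]
    return np.take_along_axis(parent, hap_idx[:, None, :].astype(np.int64), axis=1)[:, 0, :]


def _male_gametes(haps, idx, rng):
    """Non-recombinant gametes: one intact homolog per chromosome."""
    choice = rng.integers(0, 2, len(idx))
    return haps[idx, choice, :]


def _sim_loci(gmap, extra):
    """Per-chromosome sorted simulation loci (markers + trait/selection loci).

    Returns ``{chrom: positions}`` plus index maps for markers and extras.
    """
    loci = {}
    for c in gmap.chromosomes():
        loci.setdefault(c, set()).update(gmap.pos[gmap.index_on(c)].tolist())
    for c, p in extra:
        if c not in loci:
            raise ValueError(f"locus {c}:{p} is not on a chromosome carrying markers")
        loci[c].add(float(p))
    loci = {c: np.array(sorted(s)) for c, s in loci.items()}

    def locate(c, p):
        j = int(np.argmin(np.abs(loci[c] - p)))
        return j

    marker_ix = [(c, locate(c, p)) for c, p in zip(gmap.chrom, gmap.pos)]
    extra_ix = [(c, locate(c, p)) for c, p in extra]
    return loci, marker_ix, extra_ix


def simulate_cross(design, gmap, seed, extra_loci=()):
    """Breed an intercross population and return its phenotyped males.

    ``extra_loci`` is a list of ``(chrom, pos)`` trait loci to track in
    addition to the markers; their genotypes are stored on the returned
    :class:`~lobeqtl.core.Population` (``qtl_loci`` / ``qtl_genotypes``)
    for phenotype assignment but are invisible to the mapping code.
    """
    rng = np.random.default_rng(seed)
    extra = [(str(c), float(p)) for c, p in extra_loci]
    sel = [(str(c), float(p), int(g), float(w)) for c, p, g, w in design.viability]
    loci, marker_ix, extra_ix = _sim_loci(gmap, extra + [(c, p) for c, p, _g, _w in sel])
    sel_ix = {}
    for c, p, g, w in sel:
        j = int(np.argmin(np.abs(loci[c] - p)))
        sel_ix[(c, p, g)] = (c, j, g, w)

    autosomes = [c for c in loci if c != "X"]
    has_x = "X" in loci

    def founders_f1(n):
        """Pooled F1 of size n (half female); allele 0 = parent A, 1 = parent B."""
        is_male = np.arange(n) % 2 == 1
        haps = {}
        for c in autosomes:
            h = np.zeros((n, 2, len(loci[c])), dtype=np.int8)
            h[:, 1, :] = 1
            haps[c] = h
        if has_x:
            hx = np.zeros((n, 2, len(loci["X"])), dtype=np.int8)
            # cross direction 1: mother A x father B -> daughters A/B, sons A
            hx[~is_male, 1, :] = 1
            if design.reciprocal_f1:
                # second half of each sex from the reciprocal cross (mother B)
                rec = np.zeros(n, dtype=bool)
                for sex_mask in (is_male, ~is_male):
                    ii = np.flatnonzero(sex_mask)
                    rec[ii[len(ii) // 2:]] = True
                hx[rec & is_male, :, :] = 1          # sons of a B mother carry a B X
                hx[rec & ~is_male, 0, :] = 1         # daughters: maternal slot B,
                hx[rec & ~is_male, 1, :] = 0         # paternal slot A
            haps["X"] = hx
        return _SimState(is_male, haps)

    def offspring(state, n, child_male, max_rounds=1000):
        mothers_pool = np.flatnonzero(~state.is_male)
        fathers_pool = np.flatnonzero(state.is_male)
        if len(mothers_pool) == 0 or len(fathers_pool) == 0:
            raise RuntimeError("a generation lost one sex entirely; increase the census size")
        out = {c: np.empty((n, 2, h.shape[2]), dtype=np.int8) for c, h in state.haps.items()}
        need = np.arange(n)
        for _ in range(max_rounds):
            if len(need) == 0:
                return _SimState(child_male.copy(), out)
            m = len(need)
            mothers = rng.choice(mothers_pool, m)
            fathers = rng.choice(fathers_pool, m)
            zyg = {}
            for c in autosomes:
                mat = _female_gametes(state.haps[c], mothers, loci[c], rng)
                pat = _male_gametes(state.haps[c], fathers, rng)
                zyg[c] = np.stack([mat, pat], axis=1)
            if has_x:
                mat = _female_gametes(state.haps["X"], mothers, loci["X"], rng)
                pat_x = state.haps["X"][fathers, 0, :]  # fathers are hemizygous
                cm = child_male[need]
                second = np.where(cm[:, None], mat, pat_x)
                zyg["X"] = np.stack([mat, second], axis=1)
            w = np.ones(m)
            for c, j, g, fit in sel_ix.values():
                geno = zyg[c][:, 0, j].astype(np.int16) + zyg[c][:, 1, j]
                w = w * np.where(geno == g, fit, 1.0)
            acc = rng.random(m) < w
            for c in zyg:
                out[c][need[acc]] = zyg[c][acc]
            need = need[~acc]
        worst = min(sel_ix.values(), key=lambda v: v[3])
        raise RuntimeError(
            f"viability selection at {worst[0]}:{loci[worst[0]][worst[1]]:g} cM left no "
            f"surviving zygotes within {max_rounds} rounds of rejection sampling"
        )

    state = founders_f1(design.census)
    for _gen in range(2, design.t):
        sexes = np.arange(design.census) % 2 == 1
        state = offspring(state, design.census, sexes)
    n = design.n_phenotyped
    state = offspring(state, n, np.ones(n, dtype=bool))

    genotypes = np.empty((n, len(gmap)), dtype=np.int8)
    for col, (c, j) in enumerate(marker_ix):
        genotypes[:, col] = state.haps[c][:, 0, j].astype(np.int16) + state.haps[c][:, 1, j]
    qtl_geno = np.empty((n, len(extra_ix)), dtype=np.int8)
    for col, (c, j) in enumerate(extra_ix):
        qtl_geno[:, col] = state.haps[c][:, 0, j].astype(np.int16) + state.haps[c][:, 1, j]

    label = f"F{design.t}"
    ids = np.array([f"{label}_{i + 1:04d}" for i in range(n)])
    return Population(
        ids=ids,
        genotypes=genotypes,
        gmap=gmap,
        phenotypes=pd.DataFrame(index=range(n)),
        genotyped=np.ones(n, dtype=bool),
        generation=label,
        qtl_loci=extra,
        qtl_genotypes=qtl_geno,
    )


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


def _codings(geno):
    x = geno.astype(float) - 1.0
    z = (geno == GENO_AB).astype(float)
    return x, z


def genetic_values(pop, arch):
    """Deterministic genetic value of every individual under an architecture."""
    xs, zs = [], []
    for c, p, _a, _d in arch.loci:
        g = pop.locus_genotypes(c, p)
        if np.any(g == MISSING):
            raise ValueError(f"missing genotypes at trait locus {c}:{p}")
        x, z = _codings(g)
        xs.append(x)
        zs.append(z)
    g = np.zeros(len(pop))
    for (c, p, a, d), x, z in zip(arch.loci, xs, zs):
        g += a * x + d * z
    for i, j, (aa, ad, da, dd) in arch.interactions:
        g += aa * xs[i] * xs[j] + ad * xs[i] * zs[j] + da * zs[i] * xs[j] + dd * zs[i] * zs[j]
    return g


def calibrate_residual_sd(pop, arch, fraction):
    """Residual SD making the genetic share of per-lobe score variance = fraction."""
    if not 0 < fraction < 1:
        raise ValueError("variance fraction must be in (0, 1)")
    vg = float(np.var(genetic_values(pop, arch)))
    if vg == 0:
        raise ValueError("architecture explains no variance in this population")
    return math.sqrt(vg * (1.0 - fraction) / fraction)


def assign_phenotypes(pop, arch, seed):
    """Attach left/right/used lobe scores generated under an architecture.

    The environmental variance is split into a shared per-fly component and
    an independent per-lobe component, sized so the left/right score
    correlation hits ``arch.paired_corr`` exactly in expectation.
    """
    rng = np.random.default_rng(seed)
    g = genetic_values(pop, arch)
    if arch.residual_sd is not None:
        sd = float(arch.residual_sd)
    else:
        sd = calibrate_residual_sd(pop, arch, arch.heritability)
    ve = sd * sd
    vg = float(np.var(g))
    rho = arch.paired_corr
    vs = rho * (vg + ve) - vg
    if vs < -1e-9 * (vg + ve):
        raise ValueError(
            f"paired-lobe correlation target {rho} is below the heritability "
            f"{vg / (vg + ve):.3f}; the two lobes of one fly share its genotype"
        )
    vs = max(vs, 0.0)
    vl = max(ve - vs, 0.0)
    n = len(pop)
    shared = rng.normal(0.0, math.sqrt(vs), n)
    left = g + shared + rng.normal(0.0, math.sqrt(vl), n)
    right = g + shared + rng.normal(0.0, math.sqrt(vl), n)
    side = rng.integers(0, 2, n)
    frame = pd.DataFrame(
        {
            "score_left": left,
            "score_right": right,
            "score": np.where(side == 0, left, right),
            "side_used": np.where(side == 0, "left", "right"),
            "genetic_value": g,
        }
    )
    return pop.with_phenotypes(frame)


def select_tails(pop, k, trait="score"):
    """Flag the k lowest and k highest individuals on a trait as genotyped.

    Everyone else keeps phenotypes but has every genotype set to missing.
    Ties at either cutoff are broken by individual id (ascending), which
    makes the selection deterministic.
    """
    y = pop.phenotype(trait)
    n = len(pop)
    if 2 * k > n:
        raise ValueError(f"cannot take {k} per tail from {n} individuals")
    order = np.lexsort((pop.ids, y))
    flag = np.zeros(n, dtype=bool)
    flag[order[:k]] = True
    flag[order[n - k:]] = True
    geno = pop.genotypes.copy()
    geno[~flag] = MISSING
    return replace(pop, genotypes=geno, genotyped=flag)


# ---------------------------------------------------------------------------
# lobe templates and outline rendering
# ---------------------------------------------------------------------------

# The template arc is y = rh*sin^3(theta) above the baseline, which meets
# the baseline tangentially (a C1-smooth closed curve, so a 25-harmonic
# Fourier series reconstructs it with sub-percent error).  Closed forms
# with x = rw*cos(theta): area = (3*pi/8)*rw*rh; centroid height =
# (int sin^7)/(2*int sin^4) * rh = 256/(210*pi) * rh; width through the
# centroid = 2*rw*cos(theta*) where sin^3(theta*) is the centroid height.
_SIN0 = 256.0 / (210.0 * math.pi)                # centroid height fraction of rh
_CHORD = 2.0 * math.sqrt(1.0 - _SIN0 ** (2.0 / 3.0))
_AREA_F = 3.0 * math.pi / 8.0


@dataclass(frozen=True)
class LobeTemplate:
    """A smooth synthetic lobe: a dome of half-width ``rw`` and height
    ``rh`` above a horizontal baseline, centroid at the origin.

    This is a synthetic stand-in for a traced lobe image: it has the
    features the morphometrics cares about (closed outline, baseline,
    controllable height:width ratio and area) and none of the biological
    texture.
    """

    rw: float
    rh: float

    @property
    def nominal_hw(self):
        return self.rh / (_CHORD * self.rw)

    @property
    def nominal_area(self):
        return _AREA_F * self.rw * self.rh

    def points(self, n_points=256):
        """Open outline trace from the left baseline corner over the apex to
        the right corner; the artificial baseline is the closing segment
        (last point back to first), so traversal is clockwise.

        Vertices are spaced (approximately) equally in contour length, the
        way a manual trace samples an outline; equal-angle sampling would
        pile vertices up near the baseline corners where the curve slows.
        """
        if n_points < 32:
            raise ValueError("need at least 32 outline points")
        theta = np.linspace(math.pi, 0.0, 8 * n_points)
        yb = -_SIN0 * self.rh
        dense = np.column_stack(
            [self.rw * np.cos(theta), yb + self.rh * np.sin(theta) ** 3]
        )
        seg = np.hypot(*np.diff(dense, axis=0).T)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        u = np.linspace(0.0, s[-1], n_points)
        return np.column_stack(
            [np.interp(u, s, dense[:, 0]), np.interp(u, s, dense[:, 1])]
        )


def make_lobe_template(hw, area):
    """Template calibrated so the measured H:W ratio and area hit the targets.

    Height through the centroid is ``rh`` (baseline to apex) and width is
    ``_CHORD * rw``, both exact for the continuous shape, so the
    calibration is closed form.
    """
    if hw <= 0 or area <= 0:
        raise ValueError("H:W ratio and area must be positive")
    rw = math.sqrt(area / (_AREA_F * _CHORD * hw))
    rh = _CHORD * hw * rw
    return LobeTemplate(rw=rw, rh=rh)


def parent_templates():
    """Templates calibrated to the two parents (H:W 1.08 and 0.70)."""
    return (
        make_lobe_template(PARENT_HW["A"], PARENT_AREA["A"]),
        make_lobe_template(PARENT_HW["B"], PARENT_AREA["B"]),
    )


def mid_template():
    """Template at the geometric-mean parental H:W, used for recombinants."""
    hw = math.sqrt(PARENT_HW["A"] * PARENT_HW["B"])
    area = 0.5 * (PARENT_AREA["A"] + PARENT_AREA["B"])
    return make_lobe_template(hw, area)


def score_shape_map(arch, template=None):
    """Affine map from latent score to the stretch factor s.

    Calibrated so the two parental genotypes land on the parental H:W
    endpoints when rendered from ``template``: stretching by (1+s)
    multiplies H:W by (1+s)^2.  Higher (Sam-like) scores give smaller s,
    hence squatter lobes — the inverse H:W/score relationship seen in the
    cross.
    """
    template = mid_template() if template is None else template
    hw0 = template.nominal_hw

    def uniform_value(code):
        x = float(code) - 1.0
        g = sum(a * x for _c, _p, a, _d in arch.loci)
        g += sum(cs[0] * x * x for _i, _j, cs in arch.interactions)
        return g

    g_a, g_b = uniform_value(0), uniform_value(2)
    s_a = math.sqrt(PARENT_HW["A"] / hw0) - 1.0
    s_b = math.sqrt(PARENT_HW["B"] / hw0) - 1.0
    beta = (s_b - s_a) / (g_b - g_a)
    alpha = s_a - beta * g_a
    return alpha, beta


def render_lobe_outline(score, template, shape_map=(0.0, 0.0), jitter_sd=0.0,
                        n_points=128, seed=0, outline_id="outline", side="left"):
    """Render one raw (open-trace) outline for a latent shape score.

    ``shape_map`` is the ``(alpha, beta)`` pair from
    :func:`score_shape_map`; ``s = alpha + beta * score`` stretches height
    by (1+s) and shrinks width by 1/(1+s), preserving area.  Coordinate
    jitter is independent Gaussian noise on every vertex.
    """
    alpha, beta = shape_map
    s = alpha + beta * float(score)
    if 1.0 + s <= 0.0:
        raise ValueError(f"shape scale factor 1+s = {1 + s:g} must be positive")
    pts = template.points(n_points)
    pts = pts * np.array([1.0 / (1.0 + s), 1.0 + s])
    if jitter_sd < 0:
        raise ValueError("jitter SD must be nonnegative")
    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        pts = pts + rng.normal(0.0, jitter_sd, pts.shape)
    return RawOutline(points=pts, outline_id=outline_id, side=side)


# ---------------------------------------------------------------------------
# study-condition factories
# ---------------------------------------------------------------------------


def study_architecture(heritability=0.265, paired_corr=0.85, residual_sd=None,
                       interaction_aa=9.2):
    """Three autosomal QTL plus a Q1xQ2 interaction, on the latent scale.

    Positions are on the regular (unexpanded) map: Q1 mid-2L, Q2 on 3L,
    Q3 at the chromosome-3 centromere.  Effects are the fine-mapped
    additive/dominance values (in units of 1e-4 on the shape-score scale,
    kept as plain numbers here).  The interaction is a single
    additive-by-additive cross term; its default size gives the
    interaction roughly the share of generative variance that the
    published decomposition attributes to it (see docs/methods.md).
    """
    kwargs = {"residual_sd": residual_sd} if residual_sd is not None else {
        "heritability": heritability}
    return QTLArchitecture(
        loci=(
            ("2", 28.0, 4.51, 6.76),
            ("3", 30.0, 6.02, 1.07),
            ("3", 47.5, 9.61, 1.27),
        ),
        interactions=((0, 1, (interaction_aa, 0.0, 0.0, 0.0)),),
        paired_corr=paired_corr,
        **kwargs,
    )


def f2_design(n_phenotyped=367, census=500):
    """The coarse-mapping F2: single cross direction, no selection."""
    return CrossDesign(t=2, n_phenotyped=n_phenotyped, census=census)


def f17_design(n_phenotyped=344, census=500, tail_count=47, with_selection=True):
    """The fine-mapping F17 AIL: reciprocal F1 pool, 15 further generations
    of random mating, and mild viability selection against the Sam
    homozygote/hemizygote at one X locus and the 3R telomere (emulating
    the observed allele-frequency skew)."""
    viability = (("X", 33.0, GENO_BB, 0.7), ("3", 108.0, GENO_BB, 0.7)) if with_selection else ()
    return CrossDesign(
        t=17,
        n_phenotyped=n_phenotyped,
        census=census,
        reciprocal_f1=True,
        viability=viability,
        tail_count=tail_count,
    )
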