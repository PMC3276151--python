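# Methods

`lobeqtl` dissects a male-specific shape trait — the posterior lobe of the
*Drosophila melanogaster* genital arch — with landmark-free outline
morphometrics and QTL mapping in an F2 intercross and an F17 advanced
intercross line (AIL).  Because the original image and genotype data are
not redistributable, the package ships a first-class synthetic-data module
that simulates both the crosses and the lobe outlines under the study's
design, so that every stage of the analysis is exercised end to end and
every estimator can be validated against a generative truth.

## Outline morphometrics

**Standard configuration.**  A raw outline is an ordered open trace of one
lobe; the artificial *baseline* is the closing segment between the trace's
endpoints (where the lateral plate meets the lobe).  Standardization is a
rigid transform plus at most one mirror: the baseline is rotated
horizontal, traversal handedness is fixed to clockwise (negative signed
area), the lobe is placed above the baseline, and the polygon's *area*
centroid (not the vertex mean — robust to uneven tracing density) is moved
to the origin.  The canonical pose is unique, so standardization is
idempotent and invariant to rotation, translation and mirroring of the
input.  Self-intersecting closures are kept but flagged and warned about.

**Elliptic Fourier analysis (EFA).**  The closed loop is parameterized by
cumulative chord length t ∈ [0, T]; x(t) and y(t) are expanded
independently in Fourier series (Kuhl–Giardina), using the exact
piecewise-linear integrals over polygon segments.  Each harmonic
contributes four coefficients (aᵢ, bᵢ, cᵢ, dᵢ); with the default n = 25
harmonics an outline becomes a 100-number descriptor.  The constant terms
A₀, C₀ are computed but excluded from the descriptor because outlines are
already centroid-centered, and no size/orientation normalization is
applied to the coefficients (outlines are standardized geometrically
beforehand).  Note that the contour-length parameterization matters
numerically: the first-harmonic coefficients of the 2:1 ellipse are
(1.8284, 0, 0, 1.0730), not the (2, 0, 0, 1) of the angle
parameterization, with a genuine third harmonic (0.1289, 0, 0, 0.0893);
the tests pin the implementation against an independent quadrature oracle.

**Shape space.**  Descriptors from a set of outlines enter an ordinary
PCA (SVD of the column-centered matrix).  Components are ordered by
variance explained, and signs are fixed deterministically — by a
designated reference outline (in the pipeline, a squat Sam-like parental
outline scores nonnegatively) or, absent one, by the largest loading.
The first component of the mapping-set PCA (``mPC1``) is the mapped
trait; it correlates strongly and negatively with the height:width
ratio, i.e. it measures how squat or slender a lobe is.

**Size metrics.**  Area is the shoelace area of the closed polygon (the
region bounded by the artificial baseline is included — the convention
must simply be constant across genotypes).  Height (width) is the total
chord length of the vertical (horizontal) line through the centroid,
summed over multiple crossings for non-convex outlines; H:W is their
ratio.  Slightly self-crossing (jittered) polygons are repaired with a
zero-width buffer before the chord intersection.

## Genetics simulator

**Maps and meiosis.**  The reference map covers the X, 2 (2L+2R) and 3
(3L+3R); arm lengths (66, 55+52, 47+63 cM) approximate the standard
*D. melanogaster* map, which is female-based because **males do not
recombine**.  Female meiosis follows the Haldane model: per chromosome, a
Poisson(L/100) number of crossovers at uniform cM positions, no
interference; male meiosis transmits intact chromosomes.  Sons receive
their single X from their mother.  Consequently a map *estimated* from
intercross genotypes is on a sex-averaged scale, roughly half the female
scale in an F2 — matching how such maps are estimated in practice.

**Crosses.**  An F2 is two generations (pooled F1, then intercross); the
F17 AIL runs 15 further generations of random mating (random union of
gametes, equal sex ratio) at a constant census, default 500 — the study
reports only "high census size", and 500 keeps drift modest at desktop
scale.  Reciprocal F1 pooling is modeled as a plain pooled F1 (no
parent-of-origin effects, consistent with reciprocal F1 males having
similar shapes), except that half the F1 males carry the other parent's
X.  Optional viability selection — default: relative fitness 0.7 for the
Sam homozygote/hemizygote at one mid-X locus and one 3R-telomeric locus —
is applied to zygotes by rejection sampling and reproduces the
allele-frequency skew that long-maintained AILs accumulate.  The loci and
strength are free parameters; the defaults are a plausible emulation, not
an inference.

**Trait architecture.**  Three autosomal QTL (mid-2L; 3L; the chromosome-3
centromere) with the fine-mapped additive/dominance effects
(a = 4.51, 6.02, 9.61; d = 6.76, 1.07, 1.27, all ×10⁻⁴ on the shape-score
scale) plus a Q1×Q2 interaction.  Only the published a and d are
available, so the interaction is a single additive×additive cross term;
its default (9.2) gives the interaction roughly the share of generative
variance that the published decomposition attributes to it (5.5 of 29
summed percentage points).  The residual SD is either given directly or
calibrated on the simulated population so the genetic share of per-lobe
score variance equals a target (default 26.5%).  Environmental variance is
split into a shared per-fly and an independent per-lobe part sized so the
left/right lobe score correlation is 0.85 in expectation; one side per fly
is designated the "used" score.

**Outline rendering.**  The synthetic lobe template is a smooth dome
y = rh·sin³θ over a horizontal baseline — chosen C¹-smooth at the
baseline so a 25-harmonic series reconstructs it to well under 1% of its
height, with closed-form H:W/area calibration (centroid height
256/(210π)·rh).  Vertices are spaced equally in contour length, as a
manual trace would be (equal-angle spacing would pile vertices at the
baseline corners below the jitter scale).  A latent score stretches the
template by (1+s) in height and 1/(1+s) in width — area-preserving, H:W
multiplied by (1+s)² — with s an affine map of the score calibrated so
the two parental genotypes land exactly on the parental H:W endpoints
(1.08 tall/narrow vs 0.70 squat/broad).  The sign convention follows the
cross: higher (Sam-like) scores give squatter lobes, hence the inverse
mPC1–H:W correlation.  Gaussian coordinate jitter (default SD 5×10⁻⁵ mm,
roughly a quarter image pixel at the study's magnification) models
tracing noise.  The generator makes no attempt to model real lobe
texture, vial/replicate environmental structure, or measurement failure
modes beyond jitter — passing tests validate the estimators, not the
biology of real images.

## QTL machinery

**Map estimation.**  Marker order is fixed; adjacent recombination
fractions are estimated by EM for the intercross (the double heterozygote
mixes coupling/repulsion phases; missing genotypes drop out of the
pairwise likelihood) and by direct counting on the hemizygous male X,
then converted to cM with the inverse Haldane function.  Fractions ≥ 0.5
are capped at 0.49 with a warning.  The F17 is analyzed as an intercross
on its own re-estimated (expanded) map — the approximation the original
analysis used; true AIL transition probabilities are out of scope.  Under
this design the expected F17/F2 autosomal map ratio follows from LD decay,
R_t ≈ ½(1 − (1 − r̄)^(t−1)) with r̄ the sex-averaged per-meiosis fraction,
giving ≈ 8–10× at this marker spacing — comfortably past the 7-fold the
AIL design is meant to deliver.

**Genotype probabilities and imputation.**  A hidden Markov model per
chromosome (intercross transitions from two independent gamete chains;
two hemizygous states on the male X, which never emits heterozygote
probability) with Haldane transition probabilities on the scan grid
(markers plus pseudomarkers every `step` cM, default 1), symmetric
genotyping-error emissions (default ε = 10⁻⁴) and uniform emission for
missing data.  Multiple imputation draws M (default 256) whole-chromosome
paths by forward-filtering backward-sampling, so imputed chromosomes are
coherent recombinant mosaics; a fully ungenotyped individual imputes from
the population prior.

**Scans.**  Interval mapping regresses the phenotype on additive
(−1/0/+1) and dominance (0/1/0) codings at each grid position within each
imputation — algebraically the genotype-class-means model, which is what
the vectorized implementation computes; on the male X the model is
additive-only automatically.  Per-imputation likelihood ratios combine as
LOD = log₁₀(mean LR) (likelihood-scale averaging, not mean LOD).
Composite interval mapping adds marker covariates chosen once by
RSS-forward selection on posterior-mean dosages (default 4 covariates);
at each test position, covariates within window/2 (default 10/2 cM) on
the same chromosome are dropped from both the null and full model.
Significance comes from permutations (default 1000) with X- and
autosome-specific thresholds, the threshold being the ⌈(1−α)P⌉-th order
statistic of per-permutation maximum LODs; under selective genotyping the
permutations are stratified, shuffling phenotypes separately within the
genotyped and ungenotyped subsets.  Selective genotyping itself is
handled by including every phenotyped individual, with non-tail genotypes
missing.

**Multiple-QTL models.**  A model is a set of grid loci plus interaction
pairs; interactions use the full 2×2 cross-products of (additive,
dominance) codings (four parameters for two autosomal loci).  Within each
imputation the model is an OLS fit; per-term %variance is the drop-one RSS
comparison 100·(RSS_reduced − RSS_full)/TSS, where dropping a locus also
drops its interactions; total %variance is 100·(1 − RSS_full/TSS).
Estimates combine across imputations weighted by the imputation's model
likelihood (∝ RSS^(−n/2)); LODs combine by mean-LR.  Drop-one variances of
linked terms may legitimately sum past the total; nothing is renormalized.
`scan_additional` profiles one extra QTL against a base model;
`scan_two` runs the coarsened (default 5 cM) two-dimensional epistasis
scan, with interaction LOD = full − additive, nonnegative by nesting;
`profile_qtl`/`refine_positions` give refineqtl-style conditional
profiles — essential here because the two chromosome-3 QTL are linked and
their single-QTL profiles merge — and 2-LOD support intervals are read off
a profile as the contiguous grid run within `drop` of the peak (a flat
profile flags the whole chromosome).

**A caution on selective genotyping.**  With only the phenotypic tails
genotyped, the per-imputation/likelihood-weighted %variance estimator is
noticeably attenuated (the ungenotyped majority's imputations are prior
draws and the importance weights degenerate), while fitting the genotyped
tails alone strongly *inflates* %variance; effect estimates themselves
are recovered nearly unbiased.  The package reports the conventional
estimator and documents the bias rather than silently correcting it;
simulations with full genotyping recover the generative variance fraction
accurately.

**Candidate-locus enrichment.**  The observed statistic is the sum of
scan LODs at the k candidate positions (snapped to the grid; X-linked
candidates are excluded, as X mapping power is compromised by the AIL
allele-frequency skew).  The null resamples N (default 10⁶) sets of k
autosomal grid positions, uniform over grid points without replacement
within a set (uniform-in-cM sampling is available behind a flag; the two
coincide on an evenly stepped grid).  The empirical p-value uses the +1
correction p = (1 + #{null ≥ observed})/(N + 1).  The shipped candidate
list is a synthetic fixture (the real positions are not published in
machine-readable form); real lists load from a three-column CSV.

## Numerical and reproducibility choices

Geometric assertions are held to 1e-9 on unit-scale fixtures; measured
values to stated percentages.  Degenerate cases are explicit errors
(zero-perimeter outlines, zero phenotypic variance, coincident model
loci, ε ∉ [0, 0.5), census < 2) or warnings with documented fallbacks
(r̂ capping, P·α < 1, self-intersecting outlines).  Tail selection breaks
ties by individual id.  Near-singular dominance columns in position scans
fall back to additive-only fits.  Every stochastic component takes an
explicit seed through `numpy.random.default_rng`; identical seeds give
byte-identical populations, imputations and pipeline outputs, and the
pipeline manifest records the config, its hash, derived stage seeds and
library versions.

## Problem sizes in the shipped checks

The test suite and the acceptance script run at desktop scale by design:
map-expansion checks use the full study sizes (367 F2 / 344 F17, census
500) since the simulator is fast; permutation-calibration replicates use
n = 120–200 with P = 200; the three-QTL recovery study uses the full
study design (n = 344, 47+47 tails, M = 256) over 20 replicates on a 2 cM
grid; Monte-Carlo oracles use N = 10⁵ resamples.  Larger settings change
none of the estimators, only their Monte-Carlo error.

## Known limitations

The F17 intercross approximation ignores AIL-specific transition
probabilities and drift-induced genotype-frequency distortion; the
candidate fixture is synthetic; no landmark/Procrustes morphometrics, no
image processing, no chromosome-4 or physical-map (Mb/cytology)
reporting; CIM covariate selection is one fixed greedy rule, and (as in
the original analysis) CIM profiles are sensitive to the window and
covariate count.
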