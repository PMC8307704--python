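# Methods

`scarkit` re-implements, as a tested pipeline, the quantitative machinery of a
rat incisional-wound study of pre-incisional N-acetylcysteine (NAC): collagen
fiber organization analysis of Masson's-trichrome (MT) histology, wound
histomorphometry with healing/remodeling indices, scar planimetry from
photographs, rater-score aggregation, and the study's group-pooling
statistical procedure. The study's raw images and measurements were never
deposited, so every stage runs against seeded synthetic data whose ground
truth is known in closed form; the only real numbers in the package are the
published group-level summary tables (`scarkit.reference`), which
parameterize the simulators and anchor the index-formula oracle.

## Collagen fiber organization

### Model

Fiber orientations are *axial* (defined modulo 180°). All circular statistics
are computed on doubled angles: a pixel orientation θ contributes the unit
phasor `exp(2iθ)`. Organization is summarized by the directional variance

    V = 1 − |Σ w·exp(2iθ)| / Σ w,

the weighted circular variance of doubled angles — 0 for perfect alignment, 1
in the uniform limit. For a doubled-angle von Mises distribution with
concentration κ the population value is `V(κ) = 1 − I₁(κ)/I₀(κ)` (modified
Bessel functions), which is the closed-form target the image pipeline must
recover from phantoms.

### Segmentation

MT renders collagen blue and muscle/cytoplasm red. A pixel is collagen when
`blue/(red+1e−6) > ratio_threshold` (default 1.0, strict, so neutral gray is
excluded); the collagen weight is `clip(blue − red, 0, 1)`. The threshold is
a parameter because the original analysis code does not document one.

### Orientation estimation

At each collagen pixel `c`, every other collagen pixel `j` inside a disk of
radius `window_radius_px` (default 12) contributes a unit vector at twice the
angle of the segment c→j, scaled by j's collagen weight (weighted vector
summation). Orientation is half the resultant angle; certainty
`r = |resultant|/Σw ∈ [0,1]`.

Two refinements proved necessary for parameter recovery and are both exposed
as parameters:

* **Line-of-sight constraint** (`line_of_sight=True`). A neighbour counts
  only if the discrete segment from c to j lies entirely on the collagen
  mask. Without it, a straight fiber passing *near* c at perpendicular
  offset d contributes net perpendicular doubled-angle signal — for any
  nonnegative radial weight profile g the chord integral
  `C(d) = 2∫ g(r)(r²−2d²)/(r√(r²−d²)) dr` is strictly negative near the disk
  rim, so no radial decay (flat, 1/r, 1/r², Gaussian — all were measured)
  can fix it; on dense aligned phantoms the measured variance inflates by
  +0.3–0.4. With the constraint, detached fibers are blocked by the
  background gap between them while own-fiber and genuinely crossing pixels
  still contribute. The segment walk samples once per unit step of the
  dominant axis and accepts either tied cell at half-integer crossings; this
  construction commutes with the 8 axis symmetries, making the field exactly
  invariant under right-angle rotations.
* **Certainty-weighted pooling** (`certainty_power`, default 3). The
  statistical weight of a pixel in variance estimates is its collagen weight
  times `r^certainty_power`. Pixels whose neighbourhood is orientationally
  ambiguous — fiber crossings, interiors of merged bundles, where no single
  axial orientation exists — have small resultants and are down-weighted.

With defaults, the full pipeline (segment → orient → pool) recovers V(κ)
within ≈0.045 across κ ∈ {0, 0.5, 1, 2, 5, 10} on 384 px phantoms at target
density 0.35. The residual at κ = 0 is dominated by finite-sample truth, not
estimator error: a phantom with n fibers has expected drawn variance
`≈ 1 − √(π/4n)` (≈0.966 at n = 700), not 1.

### Region metrics

Local directional variance is computed in a disk of radius 50 px around every
defined pixel (borders truncate the disk; normalization uses included weights
only). Overall directional variance pools a whole region. Fiber density is
the mask fraction of the region; blue intensity the mean blue channel over
mask pixels. A section is analyzed in five regions — the scar S plus four
500 × 500 px boxes LD, LP, RD, RP (left/right × distant/proximal) — and the
pooled pairs RD&LD, RP&LP are concatenations of per-pixel data, not averages
of per-box metrics. Box size is configurable below 500 px for small test
fixtures; the invariants (square, equal, non-overlapping, in-bounds) are
always enforced.

## Fiber phantoms

Phantoms render `n_fibers` straight anti-aliased segments of thickness 3 px
(sub-pixel rows max-combined) on a red/pink background. Orientations are
drawn by sampling a von Mises on the doubled circle and halving — the
standard axial construction, giving the Bessel-ratio variance target exactly.
Fiber length is solved from the target collagen fraction via the
Boolean-model coverage formula `p = 1 − exp(−nLt/HW)` and refined by up to
four deterministic re-renders, so the realized fraction (coverage > 0.5)
lands within ~0.005 of target. Colors: collagen ≈ (0.2, 0.3, blue_level),
background ≈ (red_level, 0.4, 0.4), defaults blue_level = 0.72,
red_level = 0.92 — chosen so a boundary pixel's blue = red crossover falls
exactly at coverage 0.5, making the generator's density ground truth and the
ratio segmentation agree to the knife-edge pixel. Color blending uses a
sharpened alpha (`clip((a−0.35)/0.3, 0, 1)`) so that mask-edge pixels stay
near the pure collagen color; geometric anti-aliasing is unaffected and the
crossover stays at 0.5.

What phantoms deliberately do not emulate: fiber waviness and branching,
bundle-scale thickness variation, nuclei and staining artifacts, uneven
illumination. A green recovery test therefore establishes that the estimator
is unbiased for straight-fiber fields of known κ — not that it is accurate on
arbitrary tissue.

## Histomorphometry

Ten measurements per section (µm/µm²): wound depth D, dermal proliferation
area DPA, epidermis thickness EPI, re-epithelialization zone length L,
natural dermis thickness N, new epidermis thickness NEO, wound border
distance S, central connective-tissue thickness T, hair-follicle distance H,
blue-stained scar area B. Input aliases E→EPI, NE→NEO, HRI→RHI are accepted.

The source prints eight derived indices but not their formulas. They were
recovered from the measurement definitions and locked:

    SCI = (L−S)/L      DCI = (N−D)/N      WSI = (N−T)/N
    GCI = SCI+DCI      GHI = GCI−WSI
    RHI = (H0−H)/H0    MRI = (B0−B)/B0    GRI = (RHI+MRI)/2

with H0, B0 the day-7 baselines (same-group day-7 means by default;
per-animal baselines configurable). Locking criterion: applied to the
published group means, the formulas must reproduce ≥ 80% of the evaluable
printed index means within ±0.02. They reproduce 42/50 (84%); residuals are
explained by mean-of-ratios vs ratio-of-means (the study averaged per-sample
indices; we can only form ratios of printed means). The six day-7 RHI/MRI
cells are non-evaluable: under the day-7-baseline definition they are
identically zero at the group level, while the printed day-7 values encode
per-animal baselines (and the day-7 control row, RHI = −2.76 / MRI = +2.35,
is a probable column misprint) — reported, not reconciled. Group summaries
average per-sample indices (mean ± SD of ratios), matching the study's
tabulation.

The dose-scaling utility implements the Meeh–Rubner allometric surface
`A = k·m^(2/3)`; k defaults to 10.0, which gives 396.9 cm² for a 250 g rat
(conventionally quoted as ~400 cm²).

### Morphometry simulator

Measurements are sampled independently per cell from Gaussians truncated at
zero, with default moments equal to the published group means ± SD (control
column for CONT; pooled-NAC column for NAC15/NAC45 and for NAC30 at days
14/60; NAC30's own day-7 column). Only marginal moments are published, so no
inter-measurement correlation is imposed (an optional D ≤ N constraint
exists). Consequence worth knowing: with large printed SDs, independent draws
make per-sample ratio indices heavy-tailed (e.g. small-L draws produce
extreme SCI), so simulated index summaries are more dispersed than the
printed ones; tests that need exact index values use zero-SD tables.

## Planimetry

Annotations are pixel polygons/polylines/segments with a pixels-per-mm
calibration from the photographed scale bar. Area is the shoelace formula
(self-intersecting polygons rejected via shapely validity); length is summed
Euclidean segments. A wound record averages up to 3 replicate areas, 3
lengths, and all 9 width segments (3 regions × 3) with equal weight — the
source is ambiguous between per-region-then-overall averaging, which is
identical under equal counts. Days are restricted to the photographic
schedule {1, 2, 3, 4, 7, 14, 21, 28, 35, 45, 60}.

The time-series simulator uses exponential decay with lognormal noise per
dimension; the source gives no time-course model, so this is acknowledged
plumbing. Defaults (area 60 mm², length 15 mm, width 4 mm for a fresh 1.5 cm
incision; decay 0.05/day for area/width, 0.005/day for length; noise SD
0.15) were chosen once as a plausible macroscopic course; the 0.03 % NAC
group gets a 1.6× faster area/width decay to inject the study's
"smaller early scar" effect qualitatively.

## Histology scoring

Scores are visual-analog values on [0, 3] (a continuous extension of the
ordinal Abramov 0–3 grades; the appendix defining per-parameter anchors is
not available, so the range is configurable), quantized to 0.1. Aggregation
is mean ± SD across raters per sample-parameter, tolerating missing raters.
Binary wound-closure calls use majority vote; exact ties are excluded from
rates with a warning. The simulator adds Gaussian noise to a stated truth,
clips, and quantizes.

## Group statistics

Per endpoint and day: (1) Shapiro–Wilk per group, parametric branch only if
every group passes (p > α; groups with n < 3 or zero variance force the
nonparametric branch); (2) the three NAC concentrations are compared by
one-way ANOVA + Tukey or Kruskal–Wallis; (3) if they do not differ (omnibus
p > α, strict), they pool into gNAC; (4) pooled → gNAC vs CONT by Student's
t (pooled variance) or Mann–Whitney U; not pooled → NAC30 vs CONT via Tukey
over all four groups (or Mann–Whitney U). α = 0.05 throughout. "Two-tailed
ANOVA" in the source is read as standard one-way ANOVA. No multiple-testing
correction is applied by default, mirroring the source; a Benjamini–Hochberg
helper exists but is off. Whether the source tested normality per group or
on pooled residuals is not stated; per-group was chosen. Under a simulated
global Gaussian null the full pipeline's type-I rate is ≈0.05 (checked at
10³ replicates).

Note on the normality gate: with k Gaussian groups the parametric branch is
taken with probability 0.95^k (≈0.857 for k = 3), which is what the
calibration tests assert.

## Numerical choices

* Angle convention: degrees, axial domain [0, 180), measured from the image
  x-axis toward increasing rows; origin top-left, row-major pixels.
* Certainty floor 1e−9 total neighbourhood weight below which orientation is
  undefined and excluded from all statistics; ratio-segmentation ε = 1e−6.
* Disks truncate at image borders; normalization by included weights only.
* Zero total weight in a variance, empty regions, and zero index
  denominators raise typed errors rather than returning silent NaN.
* All randomness flows through explicit integer seeds into
  `numpy.random.default_rng`; no global state. Identical spec + seed gives
  byte-identical outputs.

## Known limitations

* The phantom world contains straight fibers only; waviness or curvature
  would require an orientation ground truth defined per arc segment.
* At collagen fractions ≫ 0.5, merged fiber bundles leave few unambiguous
  pixels and the variance estimate degrades; recovery is validated at 0.35.
* The morphometry simulator's independence assumption produces heavy-tailed
  simulated index distributions (above).
* Day-7 printed RHI/MRI values cannot be checked against any baseline
  definition constructible from the published tables.
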