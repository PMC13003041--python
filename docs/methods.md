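# Methods

## Scope and model

`axopath` re-implements, as a tested library, the quantitative arm of a
viral-overexpression mouse study of Parkinson's-type axonopathy: bilateral
AAV delivery of A53T α-synuclein to the substantia nigra, with readouts at
60 and 120 days. The package covers five layers:

1. slice-wise image operators replicating an ImageJ-style batch macro;
2. axonal-swelling quantification from z-stacks with physical particle
   filters;
3. region densitometry, glial positive-area fractions and stereological
   estimators;
4. the composite Axonal Degeneration Index (ADI): per-time-point z-scoring
   of striatal TH optical density and swelling counts, followed by a
   three-stage classification;
5. the group statistics applied to those quantities.

## Swelling quantification

The macro operates on transmitted-light immunostain stacks (dark signal on
a bright field). Processing order: 8-bit conversion (linear min–max
rescale, rounding half away from zero), contrast inversion (v → 255 − v),
rolling-ball background subtraction, constant pixel subtraction, median
smoothing (disc radius 1), linear contrast enhancement, moment-preserving
automatic thresholding, 26-connected component labelling.

The rolling-ball background is the true grayscale opening with a
ball-height structuring element, h(dx,dy) = √(r² − dx² − dy²); the
historical paraboloid approximation is deliberately not used. Opening is
anti-extensive and idempotent, which the tests verify directly.

A component is an axonal swelling when its **maximum single-slice
cross-section strictly exceeds 0.53 µm²** and it contains **at least 5
voxels**. The area threshold is a 2-D quantity while components are 3-D;
applying the area test to the largest cross-section and the voxel test to
the 3-D component is the only reading that uses both stated units. The
strict/non-strict split follows the wording of the filters ("larger than"
vs "a minimum of"). A maximum-intensity-projection mode (`projection_2d`)
is available for comparison; projection happens after inversion so the
signal survives.

The macro's unpublished settings are exposed as configuration with these
defaults: rolling-ball radius 15 px, pixel subtraction 70 (8-bit units),
median radius 1 px, contrast saturation 0.0035 (the common auto-contrast
convention), Moments thresholding. The threshold bin itself is assigned to
background (foreground = intensity > threshold), consistent with the
p-tile semantics of the Moments method.

### Moment-preserving (Tsai) threshold

From the normalised histogram the first three gray-level moments m₁…m₃ are
computed; the two-level image preserving them has levels z₀ < z₁, roots of
z² + c₁z + c₀ = 0 with c₀ = (m₁m₃ − m₂²)/(m₂ − m₁²) and
c₁ = (m₁m₂ − m₃)/(m₂ − m₁²), and background fraction
p₀ = (z₁ − m₁)/(z₁ − z₀). The threshold is the smallest bin whose
cumulative fraction reaches p₀ (deterministic tie-break). The
implementation is validated against a sympy-based solution of the original
moment-preservation system.

A note on degenerate inputs: a uniformly bright ("saturated") image carries
no structure; rolling-ball subtraction maps it to zero and the measured
positive fraction is 0, exactly as the ImageJ pipeline would report. Area
fractions are therefore only meaningful for images with a resolvable
background, and the coverage tests use discrete objects.

## Stereology

Optical fractionator: N = ΣQ / (ssf · asf · hsf) with
asf = frame² / (frame + separation)². "Separation" is read as the gap
between counting frames (grid step = frame side + separation); the
alternative reading (separation = full step) would make the frame larger
than its grid cell and is rejected, though it remains selectable
(`separation_is_gap=False`). Defaults: ssf = 1/5, 50 µm frames, 60 µm
gaps, hsf = 0.95, giving N = 2547.4 for ΣQ = 100. Cavalieri volume:
V = Σareas · thickness / ssf; density = N / V. Disector counting rules act
upstream — counts arrive as data.

Unbiasedness is checked by Monte-Carlo: a uniform point process of known
size is sampled with random section phase, frame-grid offset and disector
height window; over 500 draws the mean estimate lies within 2 SEM of truth.

## Densitometry

OD = mean ROI intensity − mean background-ROI intensity (corpus callosum /
basal cerebral peduncle style normalisation); adding a constant to the
whole image cancels. Brightfield scans can be photometrically inverted
first (`invert=True`) so that more staining yields larger OD; units remain
arbitrary scanner units, no absolute calibration is attempted. Per-animal
OD is the mean across that animal's sections.

## The staging index

Within each time point, TH OD and swelling count are z-scored with the
sample SD across **transduced animals only** — controls present no
swellings, so including them would both be impossible for the swelling
variable and distort the TH spread. Stages:

| stage | TH z | swelling z |
|---|---|---|
| 1 (early) | > 0.3 | < −0.5 |
| 2 (intermediate) | −0.3 … 0.3 (closed) | any |
| 3 (advanced) | < −0.3 | > 0.5 or < −0.5 |

Rules are evaluated in the order 1, 3, 2. Two regions of the plane are not
covered by the stated rules (TH z > 0.3 with swelling z ≥ −0.5, and
TH z < −0.3 with |swelling z| ≤ 0.5); they fall back to stage 2, the
natural catch-all given that the intermediate stage tolerates "variable"
swelling. The fallback is configurable and logged when used. The group
index is the arithmetic mean of stage scores, matching the printed group
summaries; sexes are compared with the Mann-Whitney U test.

An exhaustive scan of [−3, 3]² at 0.01 resolution confirms the ordered
rules are total and single-valued.

### Reconstructing score vectors from printed summaries

Group summaries (mean ± SD, n ≤ 15, scores in {1,2,3}) pin down the
underlying per-animal vectors: all multisets whose mean rounds to the
printed mean are enumerated and ranked by |sample SD − printed SD|; ties
are reported, never silently broken. For the published groups the nearest-SD
solutions are unique: (3,3,3,2,2) and (2,2,2,1,1) at 60 days,
(3,3,2,2,1) and (3,3,2,2) at 120 days. The printed 60-day SDs (0.6) differ
slightly from the admissible vectors' SD (0.548); the discrepancy is noted
and left as printed. An independent composition-based enumeration serves as
the test oracle.

## Statistics

* **Mann-Whitney U** — midranks; U = R_x − n_x(n_x+1)/2 for the first
  sample; two-sided p from the normal approximation with tie-corrected
  variance n_x n_y[(N+1) − Σ(t³−t)/(N(N−1))]/12 and 0.5 continuity
  correction. Exact enumeration is used for small untied samples
  (N ≤ 12). Null calibration: Monte-Carlo type-I error at α = 0.05
  (n = 10 + 10, 5000 replicates) falls in [0.04, 0.06].
* **Shapiro-Wilk** — Royston's algorithm (3 ≤ n ≤ 50), via scipy.
* **Two-way ANOVA** — OLS fit with Type II sums of squares (designs here
  are near-balanced, where SS types essentially agree); factors are group
  and sex with an interaction; optional explicit log transform, recorded
  in the result notes, never automatic.
* **ANCOVA** — response ~ group + covariate, Type II F for the group term.
* **Power** — per-group n = 2(z₁₋α/₂ + z_power)²/d² + z²₁₋α/₂/4
  (normal approximation with small-sample correction; 7.94 → 8 at d = 1.5,
  α = 0.05, power 0.80) plus the exact noncentral-t solution by search.

No multiple-testing correction and no repeated-measures modelling: each
time point is analysed independently and animals are cross-sectional.

## Synthetic data

### Image stacks

Default calibration 0.1 µm/pixel, 1 µm z-step, so the 0.53 µm² area filter
equals 53 pixels. Fields are 144 × 144 × 10 voxels. Fibres are curvilinear
tubes (Gaussian profile, ≈0.16 µm calibre, intensity 60) from a smoothed
random walk; swellings are anisotropic Gaussian blobs truncated at 2σ
(intensity 180), with the half-maximum radius drawn from 0.5–0.8 µm for
objects built to pass both filters and 0.15–0.25 µm for distractors that
fail the area filter. Ground-truth pass/fail flags are computed from the
rasterised half-maximum ellipsoid at the configured calibration. A smooth
tilted-plane background (amplitude 10) and i.i.d. Gaussian pixel noise
(SD 3 by default) are added. Objects are placed by rejection sampling with
pairwise clearance; a `brightfield` rendering flag photometrically inverts
the stack to emulate transmitted-light acquisition, which is what the full
macro expects. The generator does not model a microscope PSF, axial
blurring, or swellings attached to fibres — detection scores on it bound
the algorithmic, not the optical, error.

### Cohorts

One row per animal over sex × group × time point (5 per cell by default,
time points 60 and 120 days). TH OD is normal around a sex- and
time-dependent mean (baseline 100, declines 35/45 OD units for males and
12/40 for females at the two time points, noise SD 7) — males ahead early,
sexes converging late, the pattern of the study's striatal data. Swelling
counts are negative-binomial (dispersion 8) around a sex-specific inverted-U
time profile (Gaussian bump, width 45 days, peak 250 at day 60 for males
and day 120 for females); the distributional family is a modelling choice —
the study reports none — selected for its overdispersion. Controls carry
structurally zero swellings and baseline TH. With these settings, across
200 seeds the mean male index exceeds the female one at day 60 in >80% of
cohorts and the sex gap shrinks by day 120 in the majority — the qualitative
published pattern — without any per-seed tuning.

## Numerical choices

* Rounding half away from zero wherever 8-bit quantisation occurs.
* Even-sized medians are the mean of the central pair.
* Degenerate contrast ranges are a warned no-op; a single-bin histogram
  thresholds at that bin; zero within-stratum SD raises with the variable
  and time point named.
* Problem sizes in tests (20 detection stacks, 500 stereology draws, 5000
  rank-test replicates, 200 cohort seeds) are chosen to make the Monte-Carlo
  bounds sharp while keeping the suite fast on a laptop.

## Known limitations

* The swelling macro's unpublished constants (pixel subtraction, median
  radius, contrast saturation, rolling-ball radius) are this package's
  defaults, not recovered values; conclusions about the original study's
  exact counts cannot be drawn from them.
* Area-fraction measurements depend on background subtraction and are
  undefined in spirit for featureless images (see above).
* The staging thresholds are taken as fixed constants; the package does not
  re-derive them from data distributions.
* Synthetic cohorts use independent animals; litter, batch and staining-run
  effects present in real data are not modelled.
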