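# Methods

## Coordinate conventions

All arrays use canonical `(slice, row, col)` order: slice index increases
lateral→medial (from the glenoid level toward the medial scapular border of a
sagittal-oblique shoulder acquisition), row index increases
superior→inferior. The two spatial partitions are defined along exactly these
axes, so the convention is fixed once at I/O time. Files written by the
package store the canonical array with a positive diagonal affine; foreign
NIfTI files are normalised with nibabel's closest-canonical reorientation,
and a YAML `axes:` override (axis permutation + flips) covers files whose
headers do not encode the acquisition convention. Indices are 0-based
internally; reports are 1-based (Q1–Q4).

Masks are filled voxel labelings (ROIs segmented inside the fascial
borders), not contours; no sub-voxel geometry is attempted.

## Fat-fraction quantification

The per-voxel fat fraction of a two-point Dixon fat/water pair is
`%fat = 100·F/(F+W)`, undefined (NaN) where `F+W = 0`. Undefined voxels
inside a mask are excluded from all means and counted in the output rather
than imputed as 0% or 100%, since either imputation biases the regional
mean; the count makes silent mask/volume misalignment visible.

Two whole-muscle estimators are provided and always reported side by side:

- `slice_mean` (default): the mean over slices containing the muscle of the
  per-slice ROI mean — the literal "average over consecutive images", which
  weights every slice equally regardless of cross-sectional area;
- `voxel`: the mean over all labelled voxels — the self-consistent 3D
  estimator, which recombines exactly from any partition of the muscle
  (`Σ region_mean·region_count / total_count`).

They differ when slice area correlates with slice %fat; on the default
phantoms the difference is well under 0.1 %fat. Muscle volume is voxel count
× voxel volume, accumulated per slice (area × slice thickness), reported in
cm³. Area is pixel-count × pixel area, consistent with masks being voxel
labelings.

## Spatial partitions

**Superior–inferior quartiles.** Within each slice containing the muscle,
the occupied row extent `[r_min, r_max]` is split into four bands of height
`h = (r_max − r_min + 1)/4`; the voxel at row `r` joins band
`min(4, ⌊(r − r_min)/h⌋ + 1)`. Band row-counts within a slice differ by at
most one. Bands are computed per slice (the muscle cross-section drifts
superiorly/inferiorly across slices); a `global` extent mode uses one 3D
bounding box instead. The floor rule is deterministic and
iteration-order-free, but its band boundaries round downward: for extents
not divisible by 4 the band sizes (e.g. 3,2,3,2 for 10 rows) are not
palindromic, so reflecting a volume superior↔inferior maps Q1↔Q4/Q2↔Q3
exactly only for 4-divisible extents and shifts boundary rows by at most one
band otherwise. Tests assert exactly this.

**Lateral/intermediate/medial tertiles.** The occupied slice range (the
segmentation is bounded laterally by the glenoid and medially by the medial
scapular border, so the mask's extent operationalises those landmarks) is
split into three contiguous groups of `⌊n/3⌋` slices; the `n mod 3`
remainder slices are handed out one per group, lateral-first by default
(configurable — the choice is arbitrary but must be deterministic). A muscle
spanning fewer than 3 slices is a degenerate-extent error.

Both partitions are disjoint and exhaustive over the muscle by construction;
region volumes and voxel counts therefore recombine exactly to the
whole-muscle values, which the tests assert rather than assume. Regional
%fat uses the same two estimators as the whole muscle, restricted to the
region. Quartile volumes are emitted alongside tertile volumes even though
quartile reporting conventionally covers %fat only.

## Reliability statistics

Ratings tables are complete n-subject × k-rater designs under the crossed
random-effects model `y_ij = μ + s_i + r_j + e_ij`. From the two-way ANOVA
mean squares (between-subjects MSB, between-raters MSJ, residual MSE):

- **ICC(2,1)** (two-way random, absolute agreement, single measures — the
  default, appropriate when raters are interchangeable):
  `(MSB − MSE) / (MSB + (k−1)·MSE + k·(MSJ − MSE)/n)`;
- **ICC(3,1)** (two-way mixed, consistency): `(MSB − MSE) / (MSB + (k−1)·MSE)`.

95% confidence intervals use the exact F-distribution intervals for each
form (McGraw & Wong; identical to SPSS and pingouin, against which the
implementation is cross-checked). Degenerate inputs: a table with zero total
variance raises; identical rater columns with subject variance give ICC = 1
with a collapsed CI. Small-sample point estimates may fall below −1; they
are reported as computed.

Qualitative bands follow the published cut-points (≤0.20 poor, 0.21–0.40
fair, 0.41–0.60 moderate, 0.61–0.80 good, 0.81–1.00 very good), implemented
as half-open intervals at the midpoints (0.205, 0.405, 0.605, 0.805) so
every real value receives a band.

**SEM** defaults to `SD_pooled·√(1 − ICC)` with the SD pooled over all
measurements; `√MSE` (the ANOVA residual) is available, and the two differ
in general. **MDC** is `z·√2·SEM` with default `z = 1`: the √2 multiplier is
what reproduces every self-consistently rounded SEM/MDC pair in the
reliability tables this package mirrors (1.74→2.46, 0.55→0.78, 0.61→0.86,
0.96→1.36, 1.54→2.18, 2.95→4.17, 1.10→1.56, 2.9→4.1); the conventional
MDC95 is available via `z = 1.96`.

**Concurrent validity** between two measurement methods reuses the ICC
machinery with the methods as the two "raters"; a fixed offset of one SD
between methods lowers the absolute-agreement ICC but not the consistency
ICC, which the tests verify against a brute-force oracle.

**Sample size.** The smallest n to show ICC > ρ₀ when the truth is ρ₁, at
one-sided level α with power 1−β, uses the variance-stabilising transform
`z(ρ) = ½·ln((1 + (k−1)ρ)/(1 − ρ))` with sampling variance
`k / (2(k−1)(n−2))`: `n = ⌈2 + k/(2(k−1)) · ((z_α + z_β)/(z₁ − z₀))²⌉`.
For ρ₀ = 0.75, ρ₁ = 0.95, α = 0.05, power 0.80, k = 2 this gives n = 11;
conventions differing by ±1 in the degrees of freedom give 10. Because the
literature is not unanimous on the constant, the returned n is validated by
a Monte-Carlo power oracle (one-sided F-test of H₀: ICC = ρ₀), which reaches
the requested 80% power at n = 11 and not at n = 10.

## Synthetic phantoms

The phantom emulates a sagittal-oblique shoulder acquisition at voxel
spacing 1.2 × 1.2 × 2.0 mm on a 64 × 64 × 24 grid — a desk-scale stand-in
for the full 320 × 320 × 120 acquisition that keeps every test and the
acceptance run in seconds while preserving all geometry logic. Three muscles
(supraspinatus; combined infraspinatus/teres minor; subscapularis) are
elliptical cross-sections whose centres and semi-axes interpolate linearly
across their occupied slice ranges; default mean fat fractions (11.7, 10.5,
13.1 %fat) sit in the 8–16 %fat range reported for cuff-pathology patients.
True fat fields are uniform, linear in row and/or slice, or piecewise
constant per tertile; the truth record carries the exact per-voxel field,
analytic per-region means and analytic volumes, so noise-free recovery is
tested at 1e-9.

Intensities are `fat = L·f/100 + ε`, `water = L·(1−f/100) + ε` with
`ε ~ N(0, σ)` clipped at zero and `L = 1000` the water signal level.
Gaussian (not Rician) noise is a deliberate simplification: the pipeline
consumes reconstructed magnitude fat/water pairs, and Gaussian noise keeps
the ground truth analytic. The phantom has no bias field, no chemical-shift
artifacts, no partial-volume fuzz at muscle borders and no anatomically
realistic muscle shapes — passing tests therefore demonstrate correctness of
the quantification and statistics, not robustness to acquisition physics.

**Rater variability** is simulated by translating each muscle by up to
`max_shift` voxels per axis and flipping boundary voxels (the inner edge of
the ROI and background voxels touching it) with probability
`boundary_op_prob`; a perturbation that erases a muscle raises. **Ratings
tables** are drawn directly from the variance-components model. For
simulated cohorts the defaults are μ = 12 %fat, between-subject SD 3 %fat
(the spread across patients in published tables), rater SD 0.2 %fat —
trained raters following one protocol introduce little systematic offset,
consistent with published inter-rater ICCs near 0.97 — and error SD set to
hit the target ICC. With only k = 2 raters the realized rater-pair draw
shifts the large-n limit of ICC(2,1) by O(σ_rater²), which is why a small
rater SD matters for tight parameter-recovery checks; this is a property of
the estimand, not an implementation artifact.

The simulated 13-subject, 2-rater study (the cohort size the reliability
framework targets) additionally varies per-subject muscle size (semi-axis
scale SD 8%) and per-subject base fat fractions (SD 1.5 %fat), and uses
intensity noise σ = 5. Regional ICCs from this cohort can be low in regions
where between-subject variance of regional %fat is small relative to
segmentation-perturbation noise; the end-to-end checks assert structure and
finiteness, not specific ICC magnitudes, because patient-derived ICCs are
not reproducible from synthetic data.

## Numerical choices

- Zero-denominator fat-fraction voxels → NaN, excluded and counted.
- Residual sum of squares clamped at 0 against floating round-off.
- CI bounds clamped to bracket the point estimate and not exceed 1.
- Tertile remainder goes lateral-first; quartile ties break by floor.
- All generators accept integer seeds and are bit-reproducible; study runs
  write a config-hash manifest so reruns are verifiable byte-for-byte.

## Problem sizes

Default test/acceptance sizes: phantoms 64 × 64 × 24; ICC oracle checks on
100 random designs (n ≤ 8, k ≤ 3); parameter recovery at n = 2000 ratings;
CI coverage over 1000 replicates at n = 30; partition invariants over 50
random masks; simulated studies of 13 subjects × 2 raters. These were chosen
as the smallest sizes at which the statistical assertions are stable.
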