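# rcfat

**3D intramuscular fat quantification and reliability analysis for Dixon
fat-water MRI of the rotator cuff.**

Fat infiltration of the rotator cuff muscles (supraspinatus, combined
infraspinatus/teres minor, subscapularis) is a key prognostic factor after a
cuff tear, but the common clinical gradings score a single sagittal slice by
eye. `rcfat` quantifies fat in three dimensions from a two-point Dixon
fat/water acquisition and a multi-label muscle segmentation, resolves *where*
in the muscle the fat sits, and provides the measurement-property statistics
(ICC, SEM, MDC, sample size) needed to judge whether an observed change
exceeds measurement error.

## What it computes

Given co-registered fat and water volumes and a muscle label mask (NIfTI):

- **Voxelwise fat fraction** — `%fat = 100 · Fat / (Fat + Water)`, undefined
  where the combined signal is zero.
- **Whole-muscle %fat** — mean of the per-slice ROI means over all slices
  containing the muscle (`slice_mean`, the default), or the mean over all
  labelled voxels (`voxel`); both are reported.
- **3D muscle volume** — per-slice labelled area × slice thickness, summed
  over slices, in cm³.
- **Spatial distribution** — each muscle partitioned into four
  superior→inferior bands per slice (quartiles Q1–Q4, Q1 superior-most) and
  into three contiguous lateral/intermediate/medial slice groups (tertiles)
  spanning the occupied slice range, with %fat and volume per region.
- **Reliability** — for repeated measurements `y_ij = μ + s_i + r_j + e_ij`
  (subject i, rater j), the single-measure intraclass correlation from the
  two-way ANOVA mean squares — ICC(2,1), absolute agreement, by default —
  with exact F-based 95% confidence intervals, the standard error of
  measurement `SEM = SD·√(1 − ICC)`, and the minimal detectable change
  `MDC = √2 · SEM`.
- **Study design** — the number of subjects needed to demonstrate an ICC
  above a minimally acceptable value, via the variance-stabilising transform
  of the ICC.

A synthetic-phantom module generates fat/water/mask volumes with known
ground truth (elliptical muscle cross-sections, spatially varying fat fields,
Gaussian intensity noise), simulated second-rater segmentations (boundary
flips and small translations), and variance-component ratings tables, so the
whole pipeline is testable without any imaging data.

## Worked example

```python
from rcfat import default_phantom_spec, make_phantom, compute_fat_fraction, icc
from rcfat.fat_quant import summarize_muscles
from rcfat.phantom import VarianceComponents, simulate_ratings
import pandas as pd

spec = default_phantom_spec(noise_sd=20.0, seed=42, si_gradient=0.1)
vol, mask, truth = make_phantom(spec)
ff = compute_fat_fraction(vol)
print(pd.DataFrame([s.__dict__ for s in summarize_muscles(ff, mask)]))
```

```
 label name  mean_fat_pct_slice  mean_fat_pct_voxel  volume_cm3  n_voxels  n_slices  n_undefined_excluded
     1   SS               12.53               12.53       13.86      4813        20                     0
     2   IS               11.46               11.47       25.81      8962        22                     0
     3   SC               14.00               14.00       15.99      5553        18                     0
```

Each row is one muscle: both %fat estimators (here nearly identical because
the phantom's slice areas are similar), the 3D volume in cm³, the voxel and
slice counts, and how many in-mask voxels had undefined fat fraction. The
supraspinatus value 12.53 %fat sits ~0.8 above its base value because the
superior→inferior gradient adds fat toward the inferior rows.

Reliability of repeated measurements follows the fitted-model idiom:

```python
vc = VarianceComponents(mu=12.0, sigma_subject=3.0, sigma_rater=0.2, sigma_error=0.66)
res = icc(simulate_ratings(vc, n_subjects=13, k_raters=2, seed=1))
print(res.summary())
```

```
Reliability (two-way ANOVA ICC)
==============================================
model:        two_way_random_absolute_single
n subjects:   13    k raters: 2
ICC:          0.856  [95% CI 0.592, 0.954]  (very_good)
mean:         12.352
SEM (sd_sqrt): 0.732
MDC:          1.036
mean squares: MSB=7.174 MSJ=0.02822 MSE=0.5957
```

The true ICC implied by the variance components is 0.95; at n = 13 the point
estimate scatters around it and the 95% CI is wide — exactly why the
sample-size helper exists: `sample_size_icc(SampleSizeSpec(rho0=0.75,
rho1=0.95))` returns the n needed to show the ICC exceeds 0.75.

## Command line

```bash
rcfat simulate phantom --noise-sd 10 --seed 1 --outdir demo/
rcfat quantify --fat demo/fat.nii.gz --water demo/water.nii.gz --mask demo/mask.nii.gz --out summary.csv
rcfat regions  --fat demo/fat.nii.gz --water demo/water.nii.gz --mask demo/mask.nii.gz --scheme tertile --out regions.csv
rcfat simulate ratings -n 13 -k 2 --seed 1 --out ratings.csv
rcfat reliability --ratings ratings.csv --out rel.csv
rcfat samplesize --rho0 0.75 --rho1 0.95
rcfat run-study --config study.yaml
```

`run-study` quantifies every subject × rater triplet listed in a YAML config
and writes reliability tables (one row per muscle × region with ICC, 95% CI,
mean, SEM, MDC) plus a concurrent-validity table and a JSON run manifest.

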