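# lesionmap

Voxel-based lesion-symptom mapping (VLSM) for cohorts of binary 3-D lesion
masks on a shared reference grid, with permutation + FDR inference,
white-matter-atlas overlap quantification, and survival-based validation of
ROI-involvement risk groups. A fully synthetic cohort generator (lesions,
clinical covariates, right-censored survival, ground-truth effect region)
makes every stage testable without any imaging data.

## What it does

1. **lesion handling** (`lesionmap.core`) — NIfTI mask I/O with strict grid
   validation, binarization, per-lesion volume/centroid, dual-rater mask
   discrepancy + union merging, cohort stacking, clinical-table validation.
2. **simulation** (`lesionmap.simulate`) — seeded synthetic cohorts: one
   ellipsoidal lesion per patient, an ellipsoidal ground-truth "effect
   region" that lowers the functional score (KPS) and multiplies the event
   hazard for overlapping patients, plus a synthetic tube-tract atlas.
3. **mapping** (`lesionmap.vlsm`) — at every sufficiently-lesioned voxel,
   OLS of the binary lesion indicator on
   `[intercept, outcome, age, sex, volume]` (continuous columns z-scored);
   the outcome coefficient's t statistic is the map statistic, sign-flipped
   so adverse association (lesion with *lower* KPS / *shorter* OS) is
   positive. Significance = one-sided per-voxel permutation threshold (95th
   percentile; max-statistic mode available) AND Benjamini-Hochberg FDR on
   add-one permutation p-values. Freedman-Lane residual permutation is
   available as an option.
4. **atlas overlap** (`lesionmap.atlas`) — ROI-vs-tract overlap counts and
   fractions (floor-truncated to 2 decimals for report parity), plus
   centroid-to-labeled-region lookup.
5. **outcome analysis** (`lesionmap.survival`) — high/low risk groups by
   >= 1-voxel ROI overlap; Kaplan-Meier, two-group log-rank, univariate Cox
   hazard ratio (Efron ties, Wald CI), fixed-horizon survival ROC with a
   seeded bootstrap CI (patients censored before the horizon excluded);
   Pearson chi-square (no continuity correction) and Welch/Student t tests
   for cohort characteristics.
6. **pipeline** (`lesionmap.pipeline`, `lesionmap.cli`) — end-to-end runs
   from a YAML config with deterministic per-stage seeding, atomic run
   manifests, and checksummed outputs.

## CLI

```bash
# synthetic cohort (masks/, clinical.tsv, effect_region.nii, ground_truth.json)
lesionmap simulate --n-patients 120 --seed 1 --out cohort/

# single-outcome map + ROI
lesionmap vlsm --masks cohort/masks --clinical cohort/clinical.tsv \
    --outcome kps --n-perm 500 --alpha 0.05 --seed 1 --out vlsm_out/

# ROI x atlas overlap table
lesionmap overlap --roi vlsm_out/roi_kps.nii --atlas atlas_dir/ --out overlap.tsv

# risk-group survival validation against existing ROI masks
lesionmap validate --config pipeline.yaml --rois vlsm_out/roi_kps.nii

# everything from one config (optionally simulating the cohort first)
lesionmap run-all --config pipeline.yaml --seed 1 --out run1/
```

A minimal `pipeline.yaml`:

```yaml
seed: 1
output_dir: run1
outcomes: [kps, os]
n_permutations: 500
horizon: 12.0
simulation:
  n_patients: 120
  kps_effect: -25.0
```

## Notes

- Masks must already be spatially normalized: all inputs are validated
  against one reference grid (shape, voxel size, origin; 1e-4 mm
  tolerance). Registration/segmentation are out of scope.
- Survival time units are whatever the clinical table declares; nothing
  assumes years or months.
- OS enters the design raw by default; `log_time` switches to log(OS).
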