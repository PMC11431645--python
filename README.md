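# petfuse

Weighted PET/CT fusion radiomics for predicting recurrence-free survival
(RFS) in head-and-neck cancer.

Head-and-neck tumors are imaged with paired FDG-PET (metabolic activity, in
SUV) and CT (anatomy, in HU). This package implements the full analysis
chain a radiomics study of RFS needs:

1. **Preprocessing** — NIfTI I/O, z-score intensity normalization
   `I' = (I − μ)/σ`, monotone contrast enhancement, ROI cropping, and
   spacing homogenization (PET is resampled onto the finer CT grid). PET is
   assumed to be in SUV units; a missing body weight falls back to 75 kg for
   SUV scaling.
2. **Radiomics** — 49 features per (volume, mask) pair: first-order
   histogram statistics, mask shape descriptors (volume, surface,
   sphericity `π^{1/3}(6V)^{2/3}/A`, axes, …), and texture features from
   four gray-level matrices (GLCM, GLRLM, GLSZM, GLDM) computed in 3D over
   13 direction offsets on a discretized copy of the in-mask intensities.
   Peritumoral context is available through exact spacing-aware dilation of
   the lesion mask by a physical radius r (mm).
3. **Weighted fusion** — the convex combination with PET weight `wp`,
   at the image level (`F = (1−wp)·CT* + wp·PET*` voxelwise) or the feature
   level (`g_k = (1−wp)·z(ct_k) + wp·z(pet_k)` per paired feature), with
   `wp` swept over {0.1, …, 0.9}, plus concatenated modality combinations
   (CT_PET, CT_WF, …).
4. **Survival model** — univariate-concordance feature selection with
   correlation pruning, then a stacked bag of regressors (ridge, kNN,
   random forest, gradient boosting) fit to `log(time)` on event-observed
   patients and combined by non-negative least squares; risk is
   `−log(predicted time)`. Evaluation is by stratified out-of-fold
   cross-validation.
5. **Evaluation** — RMSLE, MAPE, Pearson r with p, Harrell's concordance
   index (censoring-aware; reduces to the plain rank-agreement form without
   censoring or ties), Kaplan–Meier curves, and the two-group log-rank test
   for median-split risk stratification.

Because the real cohort (the MICCAI 2022 HECKTOR challenge data) is
registration-gated, the package ships a first-class synthetic phantom
generator: paired CT/PET volumes on different grids with ellipsoidal
tumors and nodes, physiological background uptake, controllable uptake /
texture / volume hazard effects, clinical covariates, and right-censored
exponential outcomes. Every experiment is testable end to end against the
planted ground truth.

## Worked example

```python
import dataclasses
from petfuse import (
    CohortSpec, ExperimentConfig, ModelConfig, generate_cohort,
    extract_modality_tables, run_modality_sweep,
)

spec = CohortSpec(n_patients=60, seed=7, pet_uptake_effect=0.4,
                  texture_effect=0.0, volume_effect=0.0)
cfg = ExperimentConfig(cohort=spec, seed=7, wp_grid=(0.1, 0.5, 0.9),
                       model=ModelConfig(learners="compact"))
patients = generate_cohort(spec)
tables = extract_modality_tables(patients)
print(run_modality_sweep(cfg, patients, tables)
      [["arm", "rmsle", "mape", "pearson_r", "c_index"]].round(3))
```

prints

```
          arm  rmsle     mape  pearson_r  c_index
0          CT  1.139  172.505      0.137    0.534
1         PET  1.126  218.416      0.409    0.638
2  WF(wp=0.1)  1.170  181.330      0.090    0.516
3  WF(wp=0.5)  1.029  168.159      0.373    0.663
4  WF(wp=0.9)  1.142  216.557      0.401    0.651
```

Only PET uptake carries hazard signal in this cohort, so CT hovers at a
C-index near 0.5 (chance ranking), PET is clearly prognostic, and the
PET-heavy fused arms track or beat the single modalities — the qualitative
behaviour the wp sweep is designed to detect (at n = 60 the ordering among
nearby weights is noisy; the acceptance studies average repeated CV splits
over larger cohorts). RMSLE and MAPE compare predicted with actual event
times (lower is better); MAPE is large here because an exponential outcome
at modest n is intrinsically hard to predict in absolute time even when
ranking (C-index) is good.

A command-line interface mirrors the library:

```bash
petfuse generate --seed 7 --n-patients 60 --out cohort/
petfuse all --seed 7 --arms modality_sweep,km_stratification --out results/
petfuse report --run-dir results/
```

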