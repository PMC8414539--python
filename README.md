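# fwtract

Free-water-corrected white matter tract microstructure and its association
with subjective cognitive decline (SCD) scores — a tested, desk-scale
implementation of the full analysis pipeline, validated end to end on
synthetic phantoms and simulated cohorts.

## What it does

Conventional diffusion-tensor metrics are contaminated by partial-volume
free water (CSF, edema). The bi-tensor free-water elimination model splits
each voxel's single-shell diffusion MRI signal into an isotropic
free-water compartment and an anisotropic tissue compartment,

```
S(b, g) = S0 · [ (1 − f) · exp(−b · gᵀ D_t g) + f · exp(−b · d_iso) ]
```

with free-water fraction `f ∈ [0, 1]`, tissue tensor `D_t` and fixed
free-water diffusivity `d_iso = 3.0e-3 mm²/s`. From the fitted tissue
tensor the package computes the corrected scalars FA_T, MD_T, AD_T, RD_T
plus the FW map, averages them within 11 canonical white matter tract
templates (cingulum bundle, fornix, ILF, UF, tapetum, SLF, medial/middle
frontal gyri, IFG pars opercularis / orbitalis / triangularis), yielding
55 values per subject, and then runs the association cascade against a
bounded SCD questionnaire total (range 5–174):

1. **Per-tract standardized GLMs** — one tract metric per model plus a
   fixed covariate block (age, sex, race/ethnicity, education, FSRP,
   APOE-ε4, diagnosis, GDS, hippocampal and white matter volume);
   Benjamini–Hochberg FDR across the 11 tracts within each metric family;
   partial Cohen's f² per model.
2. **CSF interaction and competitive models** — does a tract metric
   explain SCD variance beyond covariates + CSF Aβ42?
   ΔR²_adj = R²_adj(base + metric) − R²_adj(base), in percentage points.
3. **Backward stepwise selection** — greedy removal maximizing R²_adj over
   the covariates plus all competitively significant tract terms (a
   tract's MD_T is dropped when its RD_T also qualifies).

Because no cohort data ship with the package, a first-class synthetic
layer generates (a) single-shell DWI phantoms with known bi-tensor ground
truth and Rician noise, and (b) cohort tables whose SCD score is a known
noisy linear function of tract metrics and covariates — so every stage is
testable against ground truth.

## Worked example

```python
from fwtract import (CohortSimConfig, simulate_cohort,
                     run_primary_analysis, competitive_models)

cohort = simulate_cohort(CohortSimConfig(
    n_subjects=236,
    tract_effects={"fornix_RDt": 0.3, "ilf_RDt": 0.25},  # planted truths
    seed=42,
))
table = run_primary_analysis(cohort)
print(table[table.metric == "RDt"].sort_values("p").head(4))
```

```
               tract metric  beta  beta_se     p     q    f2
              fornix    RDt 0.259    0.059 0.000 0.000 0.086
                 ilf    RDt 0.249    0.061 0.000 0.000 0.075
middle_frontal_gyrus    RDt 0.226    0.060 0.000 0.001 0.062
                  uf    RDt 0.212    0.060 0.001 0.002 0.055
```

The two planted tracts surface with the largest standardized coefficients
(β is in SD units: +0.26 SD of SCD per SD of fornix RD_T) and survive the
FDR correction; neighbouring tracts echo the signal because tract metrics
are correlated (exchangeable ρ = 0.3 by default). Continuing,

```python
comp = competitive_models(cohort)   # CSF Aβ42 subset, n = 104
print(f"base model R2_adj = {100 * comp.base_r2adj:.2f}%")
```

reports `base model R2_adj = 14.09% (n = 104)` and a fornix RD_T
ΔR²_adj of `5.40` percentage points — the unique variance that tract adds
beyond covariates and CSF Aβ42.

The same stages are scriptable from the shell:

```
fwtract simulate-dwi   --out-dir dwi/ --seed 1 --snr 40
fwtract fit-fw         --dwi dwi/dwi.nii.gz --bval dwi/dwi.bval \
                       --bvec dwi/dwi.bvec --out-dir maps/
fwtract simulate-cohort --out cohort.csv --seed 1
fwtract associate      --cohort cohort.csv --out associations.csv
fwtract run-all        --config config.yaml
```

`run-all` writes a JSON manifest with per-stage row counts and SHA-256
checksums; reruns with the same config and seed are bit-identical.

## Layout

| module | contents |
| --- | --- |
| `fwtract.gradients` | acquisition schemes, FSL bval/bvec I/O |
| `fwtract.phantom` | bi-tensor forward model, Rician-noise phantoms |
| `fwtract.cohort` | cohort simulator with known association structure |
| `fwtract.tensorfit` | single-tensor WLS fit, eigenvalue scalars |
| `fwtract.freewater` | voxelwise free-water elimination, scalar maps |
| `fwtract.roi` | tract atlas handling, 55-value metric extraction |
| `fwtract.stats` | GLMs, FDR, interactions, competitive models, stepwise |
| `fwtract.pipeline` / `cli` / `config` / `io` | end-to-end runner, CLI, YAML config, NIfTI/CSV I/O |

See `docs/methods.md` for the model, estimator and simulation details.
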