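# Methods

## Signal model

A voxel's diffusion-weighted signal at b-value `b` along unit gradient `g`
is modelled as a two-compartment mixture,

    S(b, g) = S0 · [ (1 − f) · exp(−b · gᵀ D_t g) + f · exp(−b · d_iso) ],

where `f` is the free-water volume fraction, `D_t` the tissue diffusion
tensor (mm²/s) and `d_iso` the diffusivity of unrestricted water. The
default `d_iso = 3.0e-3 mm²/s` is the diffusivity of free water at body
temperature; it is configurable but fixed during fitting, as is standard
for free-water elimination. The emulated acquisition is single-shell:
b = 0 plus 32 directions at b = 1000 s/mm², directions laid out by
electrostatic repulsion with antipodal symmetry.

## Free-water estimator

Per voxel, the package minimizes the squared signal misfit over
`(f, λ1, λ2, λ3, Euler angles)` with box constraints `f ∈ [0, 1]` and
tissue eigenvalues in `[0.1e-3, 2.5e-3] mm²/s` (a physiological window
that keeps the tissue tensor from absorbing the water compartment), using
trust-region-reflective least squares with an analytic Jacobian. S0 is
fixed at the mean unweighted signal, which the model reproduces exactly
at b = 0. Initialization follows the classic warm start: a single-tensor
WLS fit, with `f0` set by where the observed mean diffusivity (MD) falls
between a tissue-MD prior (0.6e-3 mm²/s) and `d_iso`, clipped to
[0.01, 0.99], and initial tissue eigenvalues obtained by removing the
implied water contribution.

**Why a tissue-MD prior is part of the objective.** At a single shell the
likelihood surface has a long, nearly flat valley trading `f` against the
tissue trace: the per-voxel Fisher information gives a Cramér–Rao bound
of roughly 1.8 on `sd(f)` at b0 SNR 40 for the phantom's tissue, i.e. the
unpenalized voxelwise estimate is essentially unconstrained along the
valley (empirically, RMSE(f) ≈ 0.25 with only the box constraints
active). All practical single-shell free-water methods therefore
regularize. This package uses an empirical-Bayes penalty: a first,
unpenalized pass estimates the voxel's noise level σ̂ from its residuals
(σ̂² = SSR/(n − 7)); a second pass then minimizes

    Σ (S_model − S_obs)² + σ̂² · (MD_t − m0)² / τ²,

a Gaussian prior MD_t ~ N(m0, τ²) with `m0 = 0.6e-3` and
`τ = 0.1e-3 mm²/s` (a plausible population spread of healthy white matter
tissue MD). Because the penalty is weighted by σ̂ it vanishes on
noise-free data — exact signals are recovered exactly (machine precision
in the round-trip tests) — while under noise it selects the
physiologically plausible point on the valley. With the defaults, the
504-voxel validation phantom gives max |f̂ − f| ≈ 8e-15 noise-free and
RMSE(f) ≈ 0.02, RMSE(RD_T) ≈ 2e-5 mm²/s at b0 SNR 40. The prior biases
tissue whose true MD differs from `m0`; `md_tissue_prior`, `md_prior_sd`
and the noise weighting are exposed in `FreeWaterOptions`.

Voxels are fit independently (results cannot depend on traversal order).
An optional spatial smoothness penalty on `f` (`reg_weight`, default 0)
adds three smooth-then-refit outer iterations that tether each voxel's
`f` to its 6-neighborhood mean.

**Degeneracy flagging.** For isotropic tissue the single-shell model is
non-identifiable — distinct `(f, d)` pairs produce identical signals (the
tests construct such pairs explicitly). Voxels whose fitted tissue FA
falls below `fa_floor = 0.10` are flagged `unidentifiable` and excluded
from the scalar maps, as are non-convergent voxels and voxels with
non-positive signals. Convergence uses a relative tolerance of 1e-10 on
the squared-residual decrease within 200 model evaluations.

Corrected scalars use the standard eigenvalue definitions; MD_T is
computed as `(AD_T + 2·RD_T)/3` so that the identity holds exactly in
floating point.

## Phantoms

Phantoms are unions of non-overlapping uniform boxes, each with its own
tissue tensor, principal direction and free-water fraction; background
voxels carry zero signal so that downstream code exercises its
invalid-voxel handling. Noise is Rician — the magnitude of the noise-free
signal plus complex Gaussian noise with σ = S0/SNR, SNR defined on b0 —
reproducible bit-for-bit from the seed. The recovery phantom stacks one
slab per f level (0 … 0.6) with tissue eigenvalues
(1.4, 0.2, 0.2)·10⁻³ mm²/s, i.e. typical healthy deep white matter with
MD = 0.6e-3 and FA ≈ 0.84, each slab with a different fiber direction.
Ground-truth maps (f, FA_T, MD_T, AD_T, RD_T) are stored alongside the
signal.

What the phantoms do **not** emulate: head motion, eddy currents,
susceptibility distortion, spatially varying noise, partial-volume mixing
at region boundaries, or crossing fibers. Passing the recovery tests
therefore demonstrates correctness of the estimator under the stated
model, not robustness to acquisition artifacts.

## Cohort simulator

The simulator emulates a memory-and-aging cohort table: demographic /
clinical covariates with marginals matching a 236-person cohort of
dementia-free adults (age 73 ± 7, education 16 ± 3, 63% male, 42% MCI,
…), CSF biomarkers observed on a 104/236 lumbar-puncture subset, 55
tract-metric columns, and an SCD questionnaire total bounded to [5, 174]
with memory / executive / language subscores partitioned by fixed weights
(37 : 11 : 14, matching the instrument's mean subscore shares).

Tract metrics are drawn as a 55-dimensional Gaussian with configurable
correlation (exchangeable ρ = 0.3 by default — white matter metrics are
strongly inter-correlated in vivo) and rescaled to plausible raw units.
The SCD total is generated on the standardized scale,
`SCD_z = Σ β_k z_k + ε`, mapped to the instrument scale
(mean 62, SD 23) and **clipped** at the bounds — the simplest bounded
mechanism; the instrument itself is bounded, and clipping under default
effect sizes is rare (< 1%). The default configuration has *no* tract
effects (a null cohort with respect to white matter) and moderate
covariate effects (diagnosis, depression score, age, hippocampal volume,
CSF Aβ42). An ordinal item-level generative model would be more faithful
to a questionnaire but is out of scope; the linear-Gaussian form is what
the downstream GLMs assume, which is exactly what calibration tests need.

## Statistics

- **Standardization**: outcome and continuous predictors are z-scored
  (sample SD, ddof 1) over analyzed rows; binary indicators stay 0/1, so
  coefficients are in SD units. Constant columns raise an error naming
  the column; rank-deficient designs raise an error listing the collinear
  columns.
- **Per-tract GLMs**: OLS with one tract metric + the covariate block;
  partial Cohen's f² = (R²_full − R²_reduced)/(1 − R²_full) with the
  reduced model omitting only the tract term. FDR (Benjamini–Hochberg,
  via statsmodels) is applied across the 11 tracts within each of the 5
  metric families; the same family structure is used for the competitive
  analysis. α = 0.05 is the single significance constant.
- **Competitive models**: complete-case on CSF Aβ42;
  ΔR²_adj in percentage points with
  R²_adj = 1 − (1 − R²)(n − 1)/(n − p − 1).
- **Backward stepwise**: pure R²_adj maximization — remove whichever
  variable's removal most increases R²_adj, stop at a local maximum; ties
  break on earliest column order; covariates are removable. The candidate
  pre-filter drops a tract's MD_T when its RD_T also qualifies (the two
  are nearly collinear). Note that R²_adj-maximization is equivalent to
  removing variables with partial |t| < 1, so pure-noise candidates are
  retained in ~32% of replicates — a property of the method, asserted in
  the tests. A p-value-threshold stepwise variant would behave
  differently and is not implemented.
- **Descriptive table**: equal-variance t or Kruskal–Wallis per a
  per-variable normality flag supplied in configuration (not inferred),
  chi-square without continuity correction for categorical variables.

## Validation problem sizes

Monte-Carlo checks use 500 replicates at n = 236 for null FDR
calibration, 1000 replicates for CI coverage (nominal 95% within ±2%),
200 replicates at n = 104 for competitive-model power, and a 504-voxel
phantom for free-water recovery; `scripts/acceptance.py` repeats the same
computations at 200/500 replicates. These sizes put Monte-Carlo standard
errors well inside the asserted tolerances while keeping a full run in
minutes on one CPU.

## Known limitations

- The free-water estimator is a local (voxelwise) MAP fit; it
  approximates, but is not identical to, regularized gradient-descent
  implementations used on clinical data.
- Accuracy claims are conditional on the tissue-MD prior being
  approximately right; grossly atypical tissue (MD far from 0.6e-3) is
  estimated with bias under noise.
- ROI aggregation is the arithmetic mean over binarized templates;
  probability-weighted averaging is a noted variant, not implemented.
- No registration, motion or eddy-current handling: maps and templates
  are assumed co-registered on a shared grid, and mismatched grids are an
  error, never silently resampled.
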