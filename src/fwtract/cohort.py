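"""Simulated aging cohorts with a known association structure.

The generator emulates the kind of memory-and-aging cohort table the
statistics cascade consumes: demographic and clinical covariates, CSF
biomarkers on a lumbar-puncture subset, 55 tract-metric columns (11 tracts
x 5 free-water-corrected metrics) and a bounded subjective cognitive
decline (SCD) questionnaire total with memory / executive function /
language subscores.

Generative model.  Tract metrics are drawn as a 55-dimensional Gaussian
with a configurable correlation structure and rescaled to plausible
per-metric means and spreads.  The SCD total is a noisy linear function of
standardized covariates and tract metrics,

    SCD_z = Σ_k β_k · z_k + ε,   ε ~ N(0, residual_sd²)
    SCD   = clip(62 + 23 · SCD_z, 5, 174)

with standardized effect sizes β_k set in the config; the instrument is
bounded to [5, 174] and its total is partitioned into the three subscores
by fixed weights.  Covariate marginals default to the demographics of a
236-person cohort of 60+-year-old adults without dementia (age 73 ± 7 y,
education 16 ± 3 y, 63% male, 42% MCI, ...); they are cosmetic and
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .roi import CANONICAL_TRACTS, METRICS, metric_columns

SCD_BOUNDS = (5.0, 174.0)  # instrument range of the 45-item questionnaire

#: (memory, executive function, language) share of the SCD total; the
#: defaults mirror mean subscores of 37, 11 and 14 on a mean total of 62.
SUBSCORE_WEIGHTS = (37.0 / 62.0, 11.0 / 62.0, 14.0 / 62.0)

# per-metric-family marginal mean and SD used to put the latent z-scores
# on a physically plausible raw scale (diffusivities in mm²/s)
_METRIC_SCALE = {
    "FW": (0.18, 0.04),
    "FAt": (0.45, 0.05),
    "MDt": (0.78e-3, 0.05e-3),
    "ADt": (1.25e-3, 0.07e-3),
    "RDt": (0.55e-3, 0.05e-3),
}

#: marginal (mean, sd) of the continuous covariates
_COVARIATE_SCALE = {
    "age": (73.0, 7.0),
    "education": (16.0, 3.0),
    "fsrp": (12.0, 4.0),
    "gds": (2.5, 2.5),
    "hippocampal_volume": (7228.0, 767.0),
    "white_matter_volume": (450_000.0, 45_000.0),
    "csf_abeta42": (706.0, 241.0),
    "csf_ttau": (422.0, 212.0),
    "csf_ptau": (61.0, 26.0),
}

_BINARY_RATES = {
    "sex_male": 0.63,
    "race_white": 0.86,
    "apoe4": 0.35,
}


@dataclass(frozen=True)
class CohortSimConfig:
    """Knobs of the cohort generator.

    tract_effects:
        Standardized effects of tract-metric columns on the SCD total,
        keyed by column name (e.g. ``"fornix_RDt": 0.25``); metrics not
        listed have no effect.  Empty by default, i.e. the default cohort
        is a null cohort with respect to white matter.
    covariate_effects:
        Standardized effects of covariates (binary covariates enter as 0/1
        indicators).
    residual_sd:
        SD of the SCD residual on the standardized scale.
    tract_corr:
        Either an exchangeable correlation coefficient for the 55 metrics
        or a full 55 x 55 correlation matrix; must be positive
        semi-definite.
    mci_prop:
        Mixture proportion of MCI vs cognitively unimpaired.
    csf_fraction:
        Fraction of subjects with CSF biomarkers (the rest are NaN).
    """

    n_subjects: int = 236
    tract_effects: dict = field(default_factory=dict)
    covariate_effects: dict = field(
        default_factory=lambda: {
            "diagnosis_mci": 0.45,
            "gds": 0.25,
            "age": 0.10,
            "hippocampal_volume": -0.15,
            "csf_abeta42": -0.20,
        }
    )
    residual_sd: float = 0.85
    tract_corr: float | np.ndarray = 0.3
    mci_prop: float = 99.0 / 236.0
    subscore_weights: tuple = SUBSCORE_WEIGHTS
    scd_mean: float = 62.0
    scd_sd: float = 23.0
    csf_fraction: float = 104.0 / 236.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if not 0.0 < self.mci_prop < 1.0:
            raise ValueError("mci_prop must lie in (0, 1)")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")
        if not 0.0 < self.csf_fraction <= 1.0:
            raise ValueError("csf_fraction must lie in (0, 1]")
        if abs(sum(self.subscore_weights) - 1.0) > 1e-9:
            raise ValueError("subscore weights must sum to 1")

    def correlation_matrix(self) -> np.ndarray:
        k = len(metric_columns())
        if np.isscalar(self.tract_corr):
            rho = float(self.tract_corr)
            corr = np.full((k, k), rho)
            np.fill_diagonal(corr, 1.0)
        else:
            corr = np.asarray(self.tract_corr, dtype=float)
            if corr.shape != (k, k):
                raise ValueError(f"tract_corr must be {k} x {k}, got {corr.shape}")
        if np.min(np.linalg.eigvalsh(corr)) < -1e-10:
            raise ValueError("tract metric correlation matrix is not PSD")
        return corr


def simulate_cohort(config: CohortSimConfig | None = None) -> pd.DataFrame:
    """Draw one cohort table from the configured generative model.

    Returns one row per subject with covariates, CSF biomarkers (NaN
    outside the lumbar-puncture subset), the 55 tract-metric columns, and
    SCD total plus subscores.  Bit-reproducible for a fixed seed.
    """
    cfg = config or CohortSimConfig()
    corr = cfg.correlation_matrix()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_subjects

    df = pd.DataFrame({"subject_id": [f"sub-{i + 1:04d}" for i in range(n)]})
    z: dict[str, np.ndarray] = {}

    for name, rate in _BINARY_RATES.items():
        df[name] = rng.binomial(1, rate, n)
    df["diagnosis_mci"] = rng.binomial(1, cfg.mci_prop, n)

    for name, (mu, sd) in _COVARIATE_SCALE.items():
        draw = rng.normal(mu, sd, n)
        if name in ("gds", "fsrp", "csf_ttau", "csf_ptau"):
            draw = np.clip(draw, 0.0, None)
        df[name] = draw
        z[name] = (draw - mu) / sd

    # latent standardized tract metrics with the configured correlation
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(corr.shape[0]))
    latent = rng.standard_normal((n, corr.shape[0])) @ chol.T
    cols = metric_columns()
    for j, col in enumerate(cols):
        metric = col.rsplit("_", 1)[1]
        mu, sd = _METRIC_SCALE[metric]
        df[col] = mu + sd * latent[:, j]
        z[col] = latent[:, j]

    lp = np.zeros(n)
    for name, beta in cfg.covariate_effects.items():
        lp += beta * (df[name].to_numpy() if name in _BINARY_RATES or
                      name == "diagnosis_mci" else z[name])
    for col, beta in cfg.tract_effects.items():
        if col not in z:
            raise KeyError(f"unknown tract metric column {col!r}")
        lp += beta * z[col]

    noise = rng.normal(0.0, cfg.residual_sd, n) if cfg.residual_sd > 0 else 0.0
    scd = cfg.scd_mean + cfg.scd_sd * (lp + noise)
    scd = np.clip(scd, *SCD_BOUNDS)
    df["scd_total"] = scd
    w_mem, w_exe, w_lang = cfg.subscore_weights
    df["scd_memory"] = w_mem * scd
    df["scd_executive"] = w_exe * scd
    df["scd_language"] = w_lang * scd

    # lumbar-puncture subset: CSF observed only for a random subset
    n_csf = int(round(cfg.csf_fraction * n))
    csf_rows = rng.choice(n, size=n_csf, replace=False)
    missing = np.setdiff1d(np.arange(n), csf_rows)
    for col in ("csf_abeta42", "csf_ttau", "csf_ptau"):
        df.loc[missing, col] = np.nan

    return df


COLUMN_DICTIONARY = {
    "subject_id": "subject identifier",
    "age": "age in years",
    "sex_male": "1 = male",
    "race_white": "1 = non-Hispanic white",
    "education": "years of education",
    "apoe4": "1 = APOE-e4 carrier",
    "diagnosis_mci": "1 = mild cognitive impairment, 0 = cognitively unimpaired",
    "fsrp": "Framingham Stroke Risk Profile score (age points excluded)",
    "gds": "Geriatric Depression Scale score",
    "hippocampal_volume": "hippocampal volume, mm^3",
    "white_matter_volume": "white matter volume, mm^3",
    "csf_abeta42": "CSF amyloid-beta 42, pg/mL (NaN outside CSF subset)",
    "csf_ttau": "CSF total tau, pg/mL (NaN outside CSF subset)",
    "csf_ptau": "CSF phosphorylated tau, pg/mL (NaN outside CSF subset)",
    "scd_total": "subjective cognitive decline total score, range 5-174",
    "scd_memory": "SCD memory subscore",
    "scd_executive": "SCD executive function subscore",
    "scd_language": "SCD language subscore",
    "{tract}_{metric}": "mean metric within tract; metrics FW, FAt, MDt, ADt, "
                        "RDt; diffusivities in mm^2/s",
}
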