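"""Association cascade: standardized per-tract GLMs with FDR, CSF
interaction models, competitive adjusted-R² models and backward stepwise
selection, plus a group-comparison descriptive table.

Model conventions
-----------------
"Standardized" means the outcome and every continuous predictor are
z-scored over the analyzed rows while binary indicators stay 0/1, so the
tract coefficient β is in SD units.  Each per-tract model regresses the
SCD outcome on one tract metric plus the full covariate block; the
reported effect size is the partial Cohen's f² of the tract term,
f² = (R²_full − R²_reduced) / (1 − R²_full), where the reduced model omits
only that term (equivalently t²/df_resid).  Multiple-comparison correction
is Benjamini–Hochberg across the 11 tracts within each metric family.

The competitive analysis asks whether a tract metric explains variance in
the outcome beyond a base model of covariates plus CSF Aβ42:
ΔR²_adj = R²_adj(base + metric) − R²_adj(base), reported in percentage
points with R²_adj = 1 − (1 − R²)(n − 1)/(n − p − 1).  Backward stepwise
selection then greedily removes whichever variable's removal most
increases R²_adj, stopping at a local maximum; ties break on earliest
column order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .roi import CANONICAL_TRACTS, METRICS

DEFAULT_COVARIATES = (
    "age",
    "sex_male",
    "race_white",
    "education",
    "apoe4",
    "diagnosis_mci",
    "fsrp",
    "gds",
    "hippocampal_volume",
    "white_matter_volume",
)

DEFAULT_ALPHA = 0.05  # the single a-priori significance constant


@dataclass(frozen=True)
class AnalysisConfig:
    """Covariate block, CSF competitor and significance level of the cascade."""

    covariates: tuple = DEFAULT_COVARIATES
    csf: str = "csf_abeta42"
    outcome: str = "scd_total"
    alpha: float = DEFAULT_ALPHA
    roi_statistic: str = "mean"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")


@dataclass
class AssociationResult:
    """One tract-metric model: standardized β, its SE, p, q and Cohen's f²."""

    tract: str
    metric: str
    beta: float
    beta_se: float
    p: float
    q: float
    f2: float
    n: int


@dataclass
class CompetitiveModelsResult:
    """Competitive analysis output: per-term table plus the base model fit."""

    table: pd.DataFrame  # tract, metric, delta_r2adj_pct, p, q
    base_r2adj: float  # fraction, not percentage points
    base_p: float
    n: int


@dataclass
class StepwiseResult:
    """Backward stepwise selection trace and final model."""

    selected: tuple
    final_r2adj: float
    trace: list  # (variable removed, r2adj after removal)
    initial_r2adj: float
    n: int


def is_binary(values) -> bool:
    """True when the column holds only 0/1 (missing values ignored)."""
    u = pd.unique(pd.Series(values).dropna())
    return len(u) > 0 and set(np.asarray(u, dtype=float)).issubset({0.0, 1.0})


def standardize(frame: pd.DataFrame, variables) -> pd.DataFrame:
    """Z-score the listed columns (mean 0, sample SD 1) over the rows given.

    Raises on a zero-variance column, naming it.
    """
    out = frame.copy()
    for name in variables:
        col = out[name].astype(float)
        sd = col.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"zero-variance column: {name!r}")
        out[name] = (col - col.mean()) / sd
    return out


def _build_design(
    cohort: pd.DataFrame, outcome: str, predictors
) -> tuple[pd.Series, pd.DataFrame, int]:
    """Complete-case standardized design: z-scored outcome and continuous
    predictors, binary indicators untouched, plus a constant."""
    cols = [outcome, *predictors]
    data = cohort[cols].dropna().astype(float)
    n = len(data)
    continuous = [c for c in cols if not is_binary(data[c])]
    data = standardize(data, continuous)
    y = data[outcome]
    x = sm.add_constant(data[list(predictors)], has_constant="add")
    _check_rank(x)
    return y, x, n


def _check_rank(x: pd.DataFrame) -> None:
    arr = np.asarray(x, dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        collinear = []
        for j, name in enumerate(x.columns):
            sub = np.delete(arr, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                collinear.append(str(name))
        raise ValueError(
            f"rank-deficient design (rank {rank} < {arr.shape[1]} columns); "
            f"collinear columns: {collinear}"
        )


def fit_tract_glm(
    cohort: pd.DataFrame,
    tract: str,
    metric: str,
    outcome: str = "scd_total",
    covariates=DEFAULT_COVARIATES,
) -> AssociationResult:
    """OLS of the standardized outcome on one tract metric + covariates.

    Reports the tract term's standardized β, SE, two-sided p and partial
    Cohen's f² (full vs tract-omitted model).  The q-value is filled in by
    :func:`run_primary_analysis` once the metric family is complete.
    """
    term = f"{tract}_{metric}"
    y, x, n = _build_design(cohort, outcome, [term, *covariates])
    if n <= x.shape[1] + 2:
        raise ValueError(f"too few complete cases (n = {n}) for the design")
    full = sm.OLS(y, x).fit()
    reduced = sm.OLS(y, x.drop(columns=term)).fit()
    f2 = max(0.0, (full.rsquared - reduced.rsquared) / (1.0 - full.rsquared))
    return AssociationResult(
        tract=tract,
        metric=metric,
        beta=float(full.params[term]),
        beta_se=float(full.bse[term]),
        p=float(full.pvalues[term]),
        q=np.nan,
        f2=f2,
        n=n,
    )


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p))):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def run_primary_analysis(
    cohort: pd.DataFrame,
    outcome: str = "scd_total",
    covariates=DEFAULT_COVARIATES,
    tracts=CANONICAL_TRACTS,
    metrics=METRICS,
) -> pd.DataFrame:
    """One GLM per (tract, metric) with FDR across tracts within each family.

    Returns a 55-row table (for the canonical atlas) with columns ``tract``,
    ``metric``, ``beta``, ``beta_se``, ``p``, ``q``, ``f2``, ``n``.
    """
    rows = []
    for metric in metrics:
        family = [
            fit_tract_glm(cohort, tract, metric, outcome=outcome,
                          covariates=covariates)
            for tract in tracts
        ]
        q = fdr_adjust([r.p for r in family])
        for r, qv in zip(family, q):
            r.q = float(qv)
            rows.append(vars(r).copy())
    return pd.DataFrame(rows)


def run_association_suite(
    cohort: pd.DataFrame,
    outcomes=("scd_total", "scd_memory", "scd_executive", "scd_language"),
    covariates=DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Primary analysis repeated per outcome (total score and subscores)."""
    parts = []
    for outcome in outcomes:
        part = run_primary_analysis(cohort, outcome=outcome, covariates=covariates)
        part.insert(0, "outcome", outcome)
        parts.append(part)
    return pd.concat(parts, ignore_index=True)


@dataclass
class InteractionResult:
    """Product-term test of a tract metric x CSF measure on the outcome."""

    term: str
    beta: float
    beta_se: float
    p: float
    n: int


def fit_interaction(
    cohort: pd.DataFrame,
    tract: str,
    metric: str,
    csf: str = "csf_abeta42",
    outcome: str = "scd_total",
    covariates=DEFAULT_COVARIATES,
) -> InteractionResult:
    """Does the tract metric's association with the outcome depend on CSF?

    Adds the CSF measure, the tract metric and their product (of the
    standardized terms) to the covariate block and reports the product
    term.
    """
    term = f"{tract}_{metric}"
    cols = [outcome, term, csf, *covariates]
    data = cohort[cols].dropna().astype(float)
    continuous = [c for c in cols if not is_binary(data[c])]
    data = standardize(data, continuous)
    inter = f"{term}_x_{csf}"
    data[inter] = data[term] * data[csf]
    y = data[outcome]
    x = sm.add_constant(
        data[[term, csf, inter, *covariates]], has_constant="add"
    )
    _check_rank(x)
    fit = sm.OLS(y, x).fit()
    return InteractionResult(
        term=inter,
        beta=float(fit.params[inter]),
        beta_se=float(fit.bse[inter]),
        p=float(fit.pvalues[inter]),
        n=len(data),
    )


def competitive_models(
    cohort: pd.DataFrame,
    covariates=DEFAULT_COVARIATES,
    csf: str = "csf_abeta42",
    outcome: str = "scd_total",
    tracts=CANONICAL_TRACTS,
    metrics=METRICS,
) -> CompetitiveModelsResult:
    """Unique variance of each tract metric beyond covariates + CSF Aβ42.

    Rows are restricted to complete cases on the CSF measure (the
    lumbar-puncture subset).  ΔR²_adj is in percentage points; q-values are
    per metric family across tracts.
    """
    y, x_base, n = _build_design(cohort, outcome, [csf, *covariates])
    base = sm.OLS(y, x_base).fit()

    subset = cohort.dropna(subset=[outcome, csf, *covariates])
    rows = []
    for metric in metrics:
        fam_rows = []
        for tract in tracts:
            term = f"{tract}_{metric}"
            y_f, x_f, n_f = _build_design(subset, outcome, [term, csf, *covariates])
            full = sm.OLS(y_f, x_f).fit()
            fam_rows.append(
                {
                    "tract": tract,
                    "metric": metric,
                    "delta_r2adj_pct": 100.0
                    * (full.rsquared_adj - base.rsquared_adj),
                    "p": float(full.pvalues[term]),
                    "n": n_f,
                }
            )
        q = fdr_adjust([r["p"] for r in fam_rows])
        for r, qv in zip(fam_rows, q):
            r["q"] = float(qv)
            rows.append(r)
    table = pd.DataFrame(rows)[
        ["tract", "metric", "delta_r2adj_pct", "p", "q", "n"]
    ]
    return CompetitiveModelsResult(
        table=table,
        base_r2adj=float(base.rsquared_adj),
        base_p=float(base.f_pvalue),
        n=n,
    )


def select_stepwise_candidates(
    competitive: CompetitiveModelsResult,
    covariates=DEFAULT_COVARIATES,
    alpha: float = DEFAULT_ALPHA,
) -> list[str]:
    """Covariates plus tract terms nominally significant in the
    competitive analysis, dropping a tract's MDt when its RDt also
    qualifies (the two are nearly collinear)."""
    sig = competitive.table[competitive.table["p"] < alpha]
    terms = [f"{r.tract}_{r.metric}" for r in sig.itertuples(index=False)]
    keep = []
    for term in terms:
        tract, metric = term.rsplit("_", 1)
        if metric == "MDt" and f"{tract}_RDt" in terms:
            continue
        keep.append(term)
    return [*covariates, *keep]


def backward_stepwise(
    cohort: pd.DataFrame,
    candidates,
    outcome: str = "scd_total",
) -> StepwiseResult:
    """Greedy backward elimination maximizing adjusted R².

    At each step the variable whose removal yields the largest increase in
    R²_adj is dropped; the procedure stops when no single removal
    increases it, so the returned set is locally optimal under
    leave-one-out refits.  Deterministic; ties break on earliest column
    order.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("empty candidate set for stepwise selection")
    cols = [outcome, *candidates]
    data = cohort[cols].dropna().astype(float)
    n = len(data)
    continuous = [c for c in cols if not is_binary(data[c])]
    data = standardize(data, continuous)
    y = data[outcome]

    def r2adj(variables) -> float:
        x = sm.add_constant(data[list(variables)], has_constant="add")
        return float(sm.OLS(y, x).fit().rsquared_adj)

    current = list(candidates)
    initial = current_r2 = r2adj(current)
    trace: list[tuple[str, float]] = []
    while len(current) > 1:
        best_var = None
        best_r2 = current_r2
        for var in current:  # earliest-column tie-break via strict >
            trial = [v for v in current if v != var]
            r2 = r2adj(trial)
            if r2 > best_r2 + 1e-15:
                best_var, best_r2 = var, r2
        if best_var is None:
            break
        current.remove(best_var)
        current_r2 = best_r2
        trace.append((best_var, best_r2))
    return StepwiseResult(
        selected=tuple(current),
        final_r2adj=current_r2,
        trace=trace,
        initial_r2adj=initial,
        n=n,
    )


def cohort_describe(
    cohort: pd.DataFrame,
    group_col: str,
    continuous=(),
    categorical=(),
    nonnormal=frozenset(),
) -> pd.DataFrame:
    """Two-group comparison table.

    Continuous variables get an equal-variance two-sample t test, or a
    Kruskal–Wallis H test when listed in ``nonnormal`` (the per-variable
    normality call is configuration, not inference); categorical variables
    get a chi-square test on the contingency table without continuity
    correction.
    """
    levels = pd.unique(cohort[group_col].dropna())
    if len(levels) != 2:
        raise ValueError(f"{group_col!r} must define exactly two groups")
    groups = [cohort[cohort[group_col] == lev] for lev in levels]
    for lev, grp in zip(levels, groups):
        if len(grp) < 2:
            raise ValueError(f"group {lev!r} has fewer than 2 rows")

    rows = []
    for var in continuous:
        a = groups[0][var].dropna().to_numpy(dtype=float)
        b = groups[1][var].dropna().to_numpy(dtype=float)
        if var in nonnormal:
            if np.array_equal(np.sort(a), np.sort(b)):
                stat, p = 0.0, 1.0  # identical samples: no rank separation
            else:
                stat, p = scipy.stats.kruskal(a, b)
            test = "kruskal"
        else:
            stat, p = scipy.stats.ttest_ind(a, b, equal_var=True)
            if np.isnan(stat) and np.array_equal(a, b):
                stat, p = 0.0, 1.0
            test = "t"
        rows.append({"variable": var, "test": test, "statistic": float(stat),
                     "p": float(p)})
    for var in categorical:
        table = pd.crosstab(cohort[group_col], cohort[var])
        if table.to_numpy().min() == 0 and table.shape[1] == 1:
            stat, p = 0.0, 1.0  # degenerate one-level variable
        else:
            stat, p, _, _ = scipy.stats.chi2_contingency(table, correction=False)
        rows.append({"variable": var, "test": "chi2", "statistic": float(stat),
                     "p": float(p)})
    return pd.DataFrame(rows)
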