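"""Association cascade: standardization, GLMs, FDR, competitive models,
stepwise selection and the descriptive table."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fwtract import (
    AnalysisConfig,
    CohortSimConfig,
    backward_stepwise,
    cohort_describe,
    competitive_models,
    fdr_adjust,
    fit_interaction,
    fit_tract_glm,
    run_association_suite,
    run_primary_analysis,
    select_stepwise_candidates,
    simulate_cohort,
    standardize,
)


def bh_step_up(p):
    """Independent Benjamini–Hochberg step-up oracle (direct enumeration)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        running = min(running, p[i] * m / (rank + 1))
        q[i] = running
    return q


# ---------------------------------------------------------------- standardize


def test_standardize_zero_mean_unit_sd(rng):
    df = pd.DataFrame({"x": rng.normal(3.0, 2.0, 100)})
    out = standardize(df, ["x"])
    assert abs(out.x.mean()) < 1e-12
    assert out.x.std(ddof=1) == pytest.approx(1.0, abs=1e-12)


def test_standardize_rejects_constant_column():
    df = pd.DataFrame({"x": np.ones(10)})
    with pytest.raises(ValueError, match="'x'"):
        standardize(df, ["x"])


def test_standardized_simple_regression_equals_pearson(rng):
    x = rng.normal(size=200)
    y = 0.4 * x + rng.normal(size=200)
    df = pd.DataFrame({"fornix_RDt": x, "scd_total": y})
    res = fit_tract_glm(df, "fornix", "RDt", covariates=())
    r = np.corrcoef(x, y)[0, 1]
    assert res.beta == pytest.approx(r, abs=1e-12)


# ------------------------------------------------------------------ tract GLM


def test_planted_effect_recovered_within_three_se():
    cfg = CohortSimConfig(
        n_subjects=5000, tract_effects={"fornix_RDt": 0.3},
        covariate_effects={}, seed=1,
    )
    cohort = simulate_cohort(cfg)
    res = fit_tract_glm(cohort, "fornix", "RDt")
    # the GLM standardizes the outcome, so truth is 0.3 / sd(lp + noise)
    truth = 0.3 / np.sqrt(0.3**2 + cfg.residual_sd**2)
    assert abs(res.beta - truth) < 3 * res.beta_se


def test_duplicated_predictor_raises_rank_error(rng):
    cohort = simulate_cohort(CohortSimConfig(n_subjects=100, seed=2))
    cohort["fornix_RDt"] = cohort["age"]
    with pytest.raises(ValueError, match="collinear"):
        fit_tract_glm(cohort, "fornix", "RDt", covariates=("age",))


def test_f2_zero_for_exactly_orthogonal_term(rng):
    y = rng.normal(size=300)
    raw = rng.normal(size=300)
    design = np.column_stack([np.ones(300), y])
    x = raw - design @ np.linalg.lstsq(design, raw, rcond=None)[0]
    df = pd.DataFrame({"scd_total": y, "uf_FW": x})
    res = fit_tract_glm(df, "uf", "FW", covariates=())
    assert res.f2 <= 1e-12
    assert abs(res.beta) < 1e-12


# ----------------------------------------------------------------------- FDR


def test_fdr_single_p_is_identity():
    assert fdr_adjust([0.04])[0] == pytest.approx(0.04)


def test_fdr_eleven_tracts_matches_oracle():
    p = np.arange(0.01, 0.12, 0.01)
    assert np.allclose(fdr_adjust(p), bh_step_up(p), atol=1e-15)


def test_fdr_all_ones():
    assert np.allclose(fdr_adjust(np.ones(7)), 1.0)


def test_fdr_rejects_out_of_range():
    with pytest.raises(ValueError):
        fdr_adjust([0.5, 1.2])


@settings(deadline=None, max_examples=200, derandomize=True)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
def test_fdr_matches_oracle_and_dominates_p(p):
    q = fdr_adjust(p)
    assert np.allclose(q, bh_step_up(p), atol=1e-12)
    assert np.all(q >= np.asarray(p) - 1e-15)
    assert np.all(q <= 1.0)


# ------------------------------------------------------------ primary analysis


def test_primary_analysis_has_55_rows():
    cohort = simulate_cohort(CohortSimConfig(seed=3))
    table = run_primary_analysis(cohort)
    assert len(table) == 55
    assert set(table.metric) == {"FW", "FAt", "MDt", "ADt", "RDt"}
    assert table.groupby("metric").size().eq(11).all()
    assert (table.q >= table.p - 1e-15).all()
    assert (table.f2 >= 0).all()


def test_subscore_suite_adds_three_runs():
    cohort = simulate_cohort(CohortSimConfig(n_subjects=150, seed=4))
    suite = run_association_suite(cohort)
    assert len(suite) == 4 * 55
    assert suite.outcome.nunique() == 4


# ---------------------------------------------------------------- interaction


def _interaction_frame(beta, n, seed):
    rng = np.random.default_rng(seed)
    z_t = rng.normal(size=n)
    z_c = rng.normal(size=n)
    age = rng.normal(70, 7, n)
    y = 0.2 * z_t - 0.2 * z_c + beta * z_t * z_c + rng.normal(size=n)
    return pd.DataFrame(
        {"scd_total": y, "fornix_RDt": z_t, "csf_abeta42": z_c, "age": age}
    )


def test_interaction_effect_recovered():
    df = _interaction_frame(0.4, 3000, seed=5)
    res = fit_interaction(df, "fornix", "RDt", covariates=("age",))
    # product of z-scores: truth scales with sd(y)
    truth = 0.4 / df.scd_total.std(ddof=1)
    assert abs(res.beta - truth) < 3 * res.beta_se


def test_constant_csf_rejected():
    df = _interaction_frame(0.0, 100, seed=6)
    df["csf_abeta42"] = 5.0
    with pytest.raises(ValueError):
        fit_interaction(df, "fornix", "RDt", covariates=("age",))


def test_interaction_type_one_error_calibrated():
    """Under no true product effect the test rejects at ≈ the nominal 5%."""
    hits = 0
    reps = 500
    for rep in range(reps):
        df = _interaction_frame(0.0, 200, seed=1000 + rep)
        res = fit_interaction(df, "fornix", "RDt", covariates=("age",))
        hits += res.p < 0.05
    rate = hits / reps
    tol = 3 * np.sqrt(0.05 * 0.95 / reps)
    assert abs(rate - 0.05) < tol


# ---------------------------------------------------------- competitive models


def test_orthogonal_term_cannot_increase_adjusted_r2(rng):
    cohort = simulate_cohort(
        CohortSimConfig(n_subjects=150, csf_fraction=1.0, seed=7)
    )
    y = cohort.scd_total.to_numpy()
    covs = ("age", "gds")
    block = np.column_stack(
        [np.ones(len(cohort)), y, cohort.csf_abeta42, cohort.age, cohort.gds]
    )
    raw = rng.normal(size=len(cohort))
    cohort["uf_FW"] = raw - block @ np.linalg.lstsq(block, raw, rcond=None)[0]
    comp = competitive_models(cohort, covariates=covs, tracts=("uf",),
                              metrics=("FW",))
    assert comp.table.delta_r2adj_pct.iloc[0] <= 1e-9


def test_delta_r2adj_matches_closed_form_oracle(rng):
    """Worked n = 30 dataset: ΔR²_adj recomputed from the two models' RSS."""
    n = 30
    covs = pd.DataFrame(
        {f"c{i}": rng.normal(size=n) for i in range(3)}
    )
    csf = rng.normal(size=n)
    term = rng.normal(size=n)
    y = 0.5 * csf + 0.6 * term + covs.c0 + rng.normal(size=n)
    cohort = pd.concat(
        [covs, pd.DataFrame({"csf_abeta42": csf, "fornix_RDt": term,
                             "scd_total": y})], axis=1,
    )
    comp = competitive_models(cohort, covariates=("c0", "c1", "c2"),
                              tracts=("fornix",), metrics=("RDt",))

    def z(v):
        v = np.asarray(v, dtype=float)
        return (v - v.mean()) / v.std(ddof=1)

    def r2adj(cols):
        x = np.column_stack([np.ones(n)] + [z(cohort[c]) for c in cols])
        yz = z(y)
        beta, *_ = np.linalg.lstsq(x, yz, rcond=None)
        rss = float(((yz - x @ beta) ** 2).sum())
        tss = float(((yz - yz.mean()) ** 2).sum())
        r2 = 1.0 - rss / tss
        p = x.shape[1] - 1
        return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)

    base_cols = ["csf_abeta42", "c0", "c1", "c2"]
    expected = 100.0 * (r2adj(["fornix_RDt", *base_cols]) - r2adj(base_cols))
    assert comp.table.delta_r2adj_pct.iloc[0] == pytest.approx(expected,
                                                               abs=1e-9)
    assert comp.base_r2adj == pytest.approx(r2adj(base_cols), abs=1e-12)


def test_base_model_recovers_designed_r2():
    """Cohort built with var(SCD_z) = 0.36 + 0.64: base R²_adj ≈ 0.36."""
    cfg = CohortSimConfig(
        n_subjects=2000,
        covariate_effects={"csf_abeta42": 0.6},
        residual_sd=0.8,
        csf_fraction=1.0,
        scd_sd=15.0,  # keeps clipping inactive
        seed=8,
    )
    cohort = simulate_cohort(cfg)
    comp = competitive_models(cohort, covariates=("age", "gds"))
    assert comp.base_r2adj == pytest.approx(0.36, abs=0.035)


def test_competitive_model_detects_planted_informative_tract():
    """A tract with a strong planted partial effect (partial r ≈ 0.45) at
    the CSF-subset sample size n = 104 shows ΔR²_adj > 0 with q < 0.05 in
    at least 90% of replicates."""
    effect = 0.45
    residual = float(np.sqrt(1.0 - effect**2))
    hits = 0
    reps = 200
    for rep in range(reps):
        cohort = simulate_cohort(
            CohortSimConfig(
                n_subjects=104, csf_fraction=1.0,
                tract_effects={"fornix_RDt": effect},
                residual_sd=residual, scd_sd=15.0, seed=70_000 + rep,
            )
        )
        comp = competitive_models(cohort, metrics=("RDt",))
        row = comp.table[comp.table.tract == "fornix"].iloc[0]
        hits += int((row.delta_r2adj_pct > 0) and (row.q < 0.05))
    assert hits / reps >= 0.90


# -------------------------------------------------------------------- stepwise


def _stepwise_frame(n, seed):
    rng = np.random.default_rng(seed)
    x1 = rng.normal(size=n)
    x2 = rng.normal(size=n)
    noise_var = rng.normal(size=n)
    y = 0.5 * x1 + 0.4 * x2 + rng.normal(size=n)
    return pd.DataFrame(
        {"scd_total": y, "x1": x1, "x2": x2, "x_noise": noise_var}
    )


def test_noise_variable_removed_true_support_kept():
    """Backward elimination on R²_adj drops a variable exactly when its
    partial |t| < 1, so a pure-noise candidate is removed in about 68% of
    replicates while strong true predictors are never removed.  Checked
    over 40 replicates."""
    removed_noise = 0
    reps = 40
    for rep in range(reps):
        df = _stepwise_frame(1500, seed=900 + rep)
        res = backward_stepwise(df, ["x1", "x2", "x_noise"])
        assert {"x1", "x2"} <= set(res.selected)
        removed_noise += "x_noise" not in res.selected
    # binomial(40, 0.68): observing fewer than 18 removals is a < 0.1% event
    assert removed_noise >= 18


def test_fixed_point_when_no_removal_helps():
    df = _stepwise_frame(3000, seed=10)
    res = backward_stepwise(df, ["x1", "x2"])
    assert set(res.selected) == {"x1", "x2"}
    assert res.trace == []
    assert res.final_r2adj == res.initial_r2adj


def test_stepwise_result_is_locally_optimal():
    """Exhaustive leave-one-out refits (independent numpy oracle) confirm no
    single removal improves the final adjusted R²."""
    cohort = simulate_cohort(
        CohortSimConfig(n_subjects=120, csf_fraction=1.0, seed=11)
    )
    candidates = ["age", "gds", "diagnosis_mci", "fornix_RDt", "ilf_RDt",
                  "uf_FW", "csf_abeta42"]
    res = backward_stepwise(cohort, candidates)

    data = cohort[["scd_total", *candidates]].dropna().astype(float)

    def z(col):
        v = data[col].to_numpy()
        if set(np.unique(v)).issubset({0.0, 1.0}):
            return v
        return (v - v.mean()) / v.std(ddof=1)

    yz = z("scd_total")

    def r2adj(cols):
        x = np.column_stack([np.ones(len(data))] + [z(c) for c in cols])
        beta, *_ = np.linalg.lstsq(x, yz, rcond=None)
        rss = float(((yz - x @ beta) ** 2).sum())
        tss = float(((yz - yz.mean()) ** 2).sum())
        r2 = 1.0 - rss / tss
        p = x.shape[1] - 1
        return 1.0 - (1.0 - r2) * (len(data) - 1) / (len(data) - p - 1)

    final = r2adj(list(res.selected))
    assert final == pytest.approx(res.final_r2adj, abs=1e-10)
    for var in res.selected:
        others = [v for v in res.selected if v != var]
        if others:
            assert r2adj(others) <= final + 1e-12


def test_empty_candidates_rejected():
    cohort = simulate_cohort(CohortSimConfig(n_subjects=50, seed=12))
    with pytest.raises(ValueError, match="empty"):
        backward_stepwise(cohort, [])


def test_candidate_prefilter_drops_collinear_mdt():
    cohort = simulate_cohort(
        CohortSimConfig(
            n_subjects=400,
            csf_fraction=1.0,
            tract_effects={"fornix_RDt": 0.5, "fornix_MDt": 0.5},
            seed=13,
        )
    )
    comp = competitive_models(cohort, covariates=("age",))
    cands = select_stepwise_candidates(comp, covariates=("age",))
    sig = comp.table[comp.table.p < 0.05]
    assert "fornix_RDt" in cands
    if "fornix_RDt" in [f"{r.tract}_{r.metric}" for r in sig.itertuples()]:
        assert "fornix_MDt" not in cands


# ------------------------------------------------------------------- describe


def test_identical_groups_give_zero_statistics():
    rng = np.random.default_rng(14)
    half = pd.DataFrame(
        {"age": rng.normal(70, 5, 40), "sex_male": rng.binomial(1, 0.5, 40)}
    )
    cohort = pd.concat([half.assign(group=0), half.assign(group=1)],
                       ignore_index=True)
    table = cohort_describe(cohort, "group", continuous=("age",),
                            categorical=("sex_male",))
    assert np.allclose(table.statistic, 0.0, atol=1e-12)


def test_chi_square_matches_hand_computation():
    """2x2 counts (30, 20 / 10, 40): χ² = Σ(O−E)²/E evaluated by hand."""
    group = [0] * 50 + [1] * 50
    var = [1] * 30 + [0] * 20 + [1] * 10 + [0] * 40
    cohort = pd.DataFrame({"group": group, "flag": var})
    table = cohort_describe(cohort, "group", categorical=("flag",))
    observed = np.array([[20.0, 30.0], [40.0, 10.0]])
    row = observed.sum(axis=1, keepdims=True)
    col = observed.sum(axis=0, keepdims=True)
    expected = row * col / observed.sum()
    chi2_hand = float(((observed - expected) ** 2 / expected).sum())
    assert table.statistic.iloc[0] == pytest.approx(chi2_hand, rel=1e-12)


def test_kruskal_equals_squared_rank_sum_z():
    """For two tie-free groups, H equals the square of the rank-sum z."""
    rng = np.random.default_rng(15)
    values = rng.permutation(np.arange(1.0, 31.0))  # distinct values, no ties
    group = np.array([0] * 14 + [1] * 16)
    cohort = pd.DataFrame({"group": group, "score": values})
    table = cohort_describe(cohort, "group", continuous=("score",),
                            nonnormal={"score"})
    # brute-force rank computation
    ranks = pd.Series(values).rank().to_numpy()
    n1, n2 = 14, 16
    n = n1 + n2
    r1 = ranks[group == 0].sum()
    z = (r1 - n1 * (n + 1) / 2.0) / np.sqrt(n1 * n2 * (n + 1) / 12.0)
    assert table.statistic.iloc[0] == pytest.approx(z**2, rel=1e-12)


def test_describe_requires_two_groups():
    cohort = pd.DataFrame({"group": [0] * 5, "age": np.arange(5.0)})
    with pytest.raises(ValueError, match="two groups"):
        cohort_describe(cohort, "group", continuous=("age",))


def test_tiny_group_rejected():
    cohort = pd.DataFrame({"group": [0, 0, 0, 1], "age": [1.0, 2.0, 3.0, 4.0]})
    with pytest.raises(ValueError, match="fewer than 2"):
        cohort_describe(cohort, "group", continuous=("age",))


def test_alpha_must_be_probability():
    with pytest.raises(ValueError, match="alpha"):
        AnalysisConfig(alpha=1.5)
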