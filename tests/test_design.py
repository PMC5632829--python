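import numpy as np
import pandas as pd
import pytest

from camexposure.design import (
    FitError,
    SurveyDesign,
    build_design_matrix,
    estimate_margin_rates,
    fit_models,
    fit_weighted_poisson,
    stratified_rate_ratios,
    wald_interaction_test,
)
from camexposure.segmentation import segment, summarise_children
from camexposure.synthetic import GeneratorConfig, simulate_cohort


def _iid_design(n, weights=None, rng=None):
    w = weights if weights is not None else np.ones(n)
    return SurveyDesign(strata=np.zeros(n, int), clusters=np.arange(n), weights=w)


def _intercept(n):
    return pd.DataFrame({"intercept": np.ones(n)})


def test_design_validation():
    with pytest.raises(ValueError, match="nested"):
        SurveyDesign(strata=[0, 1], clusters=["a", "a"], weights=[1, 1])
    with pytest.raises(ValueError, match="positive"):
        SurveyDesign(strata=[0, 0], clusters=["a", "b"], weights=[1, 0])
    d = SurveyDesign(strata=[0, 0, 1, 1], clusters=list("abcd"), weights=np.ones(4))
    assert d.df == 2
    assert d.df == d.n_clusters - d.n_strata


def test_intercept_only_equals_weighted_ratio():
    """Closed-form oracle: the weighted Poisson MLE with offset is
    log(sum(w y) / sum(w t))."""
    rng = np.random.default_rng(0)
    for _ in range(25):
        n = rng.integers(3, 40)
        y = rng.poisson(5, n).astype(float)
        t = rng.uniform(100, 10_000, n)
        w = rng.uniform(0.2, 5.0, n)
        fit = fit_weighted_poisson(y, _intercept(n), np.log(t), _iid_design(n, w))
        closed = np.log((w @ y) / (w @ t))
        assert fit.params.iloc[0] == pytest.approx(closed, abs=1e-8)


def test_example_counts_two_and_four_give_rate_three():
    y = np.array([2.0, 4.0])
    t = np.full(2, 36_000.0)
    fit = fit_weighted_poisson(y, _intercept(2), np.log(t), _iid_design(2))
    rate, lo, hi = fit.rate_per_day()
    assert rate == pytest.approx(3.0, abs=1e-8)
    assert lo <= rate <= hi


def test_weight_scale_invariance():
    rng = np.random.default_rng(1)
    n = 30
    y = rng.poisson(4, n).astype(float)
    t = rng.uniform(1000, 5000, n)
    w = rng.uniform(0.5, 2.0, n)
    X = _intercept(n)
    X["x"] = rng.normal(size=n)
    f1 = fit_weighted_poisson(y, X, np.log(t), _iid_design(n, w))
    f2 = fit_weighted_poisson(y, X, np.log(t), _iid_design(n, 7.3 * w))
    pd.testing.assert_series_equal(f1.params, f2.params, atol=1e-9, rtol=0)
    pd.testing.assert_frame_equal(f1.conf_int(), f2.conf_int(), atol=1e-8, rtol=0)


def test_matches_statsmodels_glm_and_hc0():
    """Independent reference: statsmodels weighted Poisson GLM. Point
    estimates agree; with one stratum and each unit its own cluster, the
    design covariance equals HC0 x n/(n-1)."""
    sm = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(2)
    n = 80
    x = rng.normal(size=n)
    g = (rng.random(n) < 0.4).astype(float)
    t = rng.uniform(500, 5000, n)
    y = rng.poisson(np.exp(-6.0 + 0.3 * x + 0.5 * g) * t)
    w = rng.uniform(0.5, 3.0, n)
    X = pd.DataFrame({"intercept": 1.0, "x": x, "g": g})
    fit = fit_weighted_poisson(y.astype(float), X, np.log(t), _iid_design(n, w))

    glm = sm.GLM(
        y, X.to_numpy(), family=sm.families.Poisson(), offset=np.log(t), var_weights=w
    ).fit(cov_type="HC0")
    assert np.allclose(fit.params.to_numpy(), glm.params, atol=1e-7)
    hc0 = np.asarray(glm.cov_params())
    assert np.allclose(fit.cov.to_numpy(), hc0 * n / (n - 1), rtol=1e-5)


def test_separation_flagged_with_infinite_ci():
    y = np.array([3.0, 5.0, 0.0, 0.0])
    X = pd.DataFrame({"intercept": np.ones(4), "g": [0, 0, 1, 1.0]})
    t = np.full(4, 1000.0)
    fit = fit_weighted_poisson(y, X, np.log(t), _iid_design(4))
    assert fit.separation == ["g"]
    rr = fit.rate_ratios()
    assert rr.loc["g", "ci_low"] == 0.0 and np.isinf(rr.loc["g", "ci_high"])


def test_rate_ratio_recovery_two_groups():
    """Groups with true rates 10 and 20 per day -> RR ~ 2 within MC error."""
    rng = np.random.default_rng(3)
    n = 400
    g = np.repeat([0.0, 1.0], n // 2)
    t = np.full(n, 4 * 36_000.0)
    lam = np.where(g == 1, 20.0, 10.0) / 36_000.0 * t
    y = rng.poisson(lam).astype(float)
    X = pd.DataFrame({"intercept": 1.0, "g": g})
    fit = fit_weighted_poisson(y, X, np.log(t), _iid_design(n))
    rr = fit.rate_ratios().loc["g"]
    # 3 MC SE of log RR ~ 3 * sqrt(1/sum(y1) + 1/sum(y0))
    se = np.sqrt(1 / y[g == 1].sum() + 1 / y[g == 0].sum())
    assert np.log(rr["rr"]) == pytest.approx(np.log(2.0), abs=3 * se)
    assert rr["ci_low"] < rr["rr"] < rr["ci_high"]


def test_margin_rates_additive_and_zero_cells_flagged(small_cohort, vocab):
    eps = segment(small_cohort.coded, permissive=True)
    summ = summarise_children(eps, small_cohort.children, vocab)
    summ["noncore_setting_empty"] = 0
    svy = SurveyDesign.from_children(small_cohort.children)
    cols = ["noncore_total"] + [
        c for c in summ.columns if "noncore_setting_" in c
    ]
    mr = estimate_margin_rates(summ, svy, count_columns=cols)
    parts = mr.drop(index=["noncore_total", "noncore_setting_empty"])["rate"]
    assert parts.sum() == pytest.approx(mr.loc["noncore_total", "rate"], rel=1e-9)
    assert mr.loc["noncore_setting_empty", "flag"] == "zero_count"
    assert mr.loc["noncore_setting_empty", "rate"] == 0.0


def test_margin_rate_recovers_generator_truth(small_cohort, vocab):
    """Homogeneous cohort with known home-setting non-core intensity: the
    design-based estimate sits within 3 MC SE of the configured rate."""
    eps = segment(small_cohort.coded, permissive=True)
    summ = summarise_children(eps, small_cohort.children, vocab)
    svy = SurveyDesign.from_children(small_cohort.children)
    mr = estimate_margin_rates(summ, svy, count_columns=["noncore_setting_home"])
    got = mr.loc["noncore_setting_home", "rate"]
    truth = 8.9  # configured home-setting non-core intensity
    n_eps = summ["noncore_setting_home"].sum()
    mc_se = truth / np.sqrt(n_eps)
    assert got == pytest.approx(truth, abs=3 * mc_se)


def test_design_matrix_levels_and_interactions(small_cohort):
    X1 = build_design_matrix(small_cohort.children, 1)
    assert list(X1.columns) == ["intercept", "eth_Maori", "eth_Pacific", "male", "age"]
    X3 = build_design_matrix(small_cohort.children, 3)
    inter = [c for c in X3.columns if ":decile_" in c]
    assert len(inter) == 4
    assert np.allclose(
        X3["eth_Maori:decile_low"], X3["eth_Maori"] * X3["decile_low"]
    )


def test_children_missing_demographics_dropped_from_models(small_cohort, vocab):
    eps = segment(small_cohort.coded, permissive=True)
    summ = summarise_children(eps, small_cohort.children, vocab)
    kids = small_cohort.children.copy()
    kids.loc[kids.index[:6], "age"] = np.nan
    svy = SurveyDesign.from_children(kids)
    fits = fit_models(summ, kids, svy, outcome="noncore_total", models=(1,))
    assert fits[1].n_obs == len(kids) - 6


def test_interaction_test_errors_without_matching_terms(small_cohort, vocab):
    eps = segment(small_cohort.coded, permissive=True)
    summ = summarise_children(eps, small_cohort.children, vocab)
    svy = SurveyDesign.from_children(small_cohort.children)
    fits = fit_models(summ, small_cohort.children, svy, models=(1, 3))
    with pytest.raises(ValueError, match="no coefficients"):
        wald_interaction_test(fits[1])
    w = wald_interaction_test(fits[3])
    assert w.f_stat >= 0 and w.df_num == 4
    assert w.df_den == svy.df - w.df_num + 1  # survey-adjusted Wald


def test_stratified_rr_reference_is_unity(small_cohort, vocab):
    eps = segment(small_cohort.coded, permissive=True)
    summ = summarise_children(eps, small_cohort.children, vocab)
    svy = SurveyDesign.from_children(small_cohort.children)
    fit3 = fit_models(summ, small_cohort.children, svy, models=(3,))[3]
    rr = stratified_rate_ratios(fit3)
    ref = rr[rr["ethnicity"] == "NZE"]
    assert (ref["rr"] == 1.0).all()
    # model algebra: within the reference decile the stratified RR is exp(beta_eth)
    maori_med = rr.query("ethnicity == 'Maori' and decile_group == 'medium'")["rr"].iloc[0]
    assert maori_med == pytest.approx(np.exp(fit3.params["eth_Maori"]))


def test_interaction_multiplier_recovered(intensity_table, vocab):
    """A known Pacific x low-decile non-core multiplier of 1.5 reappears as a
    within-stratum RR about 1.5x the reference-decile Pacific RR."""
    cfg = GeneratorConfig(
        seed=99,
        include_marketing_free=False,
        intensity_table=intensity_table,
        schools_per_stratum=3,
        children_per_school=6,
        wear_days=4,
        interaction_multipliers={("Pacific", "low"): 1.5},
    )
    co = simulate_cohort(cfg)
    eps = segment(co.coded, permissive=True)
    summ = summarise_children(eps, co.children, vocab)
    svy = SurveyDesign.from_children(co.children)
    fit3 = fit_models(summ, co.children, svy, models=(3,))[3]
    rr = stratified_rate_ratios(fit3)
    pac_low = rr.query("ethnicity == 'Pacific' and decile_group == 'low'").iloc[0]
    assert pac_low["rr"] == pytest.approx(1.5, abs=0.1)
    pac_med = rr.query("ethnicity == 'Pacific' and decile_group == 'medium'")["rr"].iloc[0]
    assert pac_med == pytest.approx(1.0, abs=0.1)


def test_estimator_consistency_at_large_n(intensity_table, vocab):
    """Relative bias of the overall non-core rate < 2% at ~10x study size."""
    cfg = GeneratorConfig(
        seed=7,
        include_marketing_free=False,
        intensity_table=intensity_table,
        children_per_school=60,  # 28 schools x 60 = 1680 children
        wear_days=4,
    )
    co = simulate_cohort(cfg)
    eps = segment(co.coded, permissive=True)
    summ = summarise_children(eps, co.children, vocab)
    svy = SurveyDesign.from_children(co.children)
    mr = estimate_margin_rates(summ, svy, count_columns=["noncore_total"])
    rate = mr.loc["noncore_total", "rate"]
    assert abs(rate - 27.3) / 27.3 < 0.02
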