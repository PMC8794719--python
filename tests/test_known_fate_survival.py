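"""Known-fate likelihood engine: closed-form oracles, AICc machinery,
model averaging, and parameter recovery at study-scale samples."""

import math

import numpy as np
import pandas as pd
import pytest

from sagepop.core_types_io import FemaleHistory, NestHistory, ValidationError
from sagepop.known_fate_survival import (
    DesignSpec,
    IntervalSurvival,
    derive_window_products,
    expand_female_histories,
    expand_nest_histories,
    fit_known_fate,
    model_average,
    rank_models,
    window_product,
)


def _single_interval_females(n_alive, n_dead):
    out = []
    for i in range(n_alive):
        out.append(FemaleHistory(f"a{i}", "ASY", 2013, 1, ["alive", "censored"]))
    for i in range(n_dead):
        out.append(FemaleHistory(f"d{i}", "ASY", 2013, 1, ["dead"]))
    return out


def test_intercept_mle_equals_binomial_closed_form():
    fit = fit_known_fate(_single_interval_females(3, 1), "intercept")
    s_hat = 1.0 / (1.0 + math.exp(-fit.coefficients[0]))
    assert s_hat == pytest.approx(0.75, abs=1e-6)
    assert fit.log_likelihood == pytest.approx(3 * math.log(0.75) + math.log(0.25))
    assert fit.K == 1 and fit.n_effective == 4


def test_collapsed_design_likelihood_equals_binomial(sim_cohorts):
    # any design that collapses to one shared probability must hit the
    # aggregate binomial MLE exactly
    females, _, _ = sim_cohorts
    rec = expand_female_histories(females)
    fit = fit_known_fate(rec, "intercept")
    y = rec["survived"].to_numpy()
    p = y.mean()
    binom_ll = y.sum() * math.log(p) + (len(y) - y.sum()) * math.log(1 - p)
    assert fit.log_likelihood == pytest.approx(binom_ll, abs=1e-8)


def test_all_survive_boundary_flagged():
    fit = fit_known_fate(_single_interval_females(6, 0), "intercept")
    assert fit.separation and fit.penalized


def test_matches_statsmodels_glm(sim_cohorts):
    sm = pytest.importorskip("statsmodels.api")
    females, _, _ = sim_cohorts
    rec = expand_female_histories(females)
    fit = fit_known_fate(rec, "year + age")
    X = fit.design_rows(rec)
    res = sm.GLM(rec["survived"].to_numpy(), X, family=sm.families.Binomial()).fit()
    assert fit.coefficients == pytest.approx(res.params, abs=1e-5)
    assert fit.log_likelihood == pytest.approx(res.llf, abs=1e-6)


def test_monthly_survival_recovery_at_large_n(rng):
    # 200 females, true monthly s = 0.95, intercept-only
    hists = []
    for i in range(200):
        states = []
        for _m in range(12):
            if rng.random() < 0.95:
                states.append("alive")
            else:
                states.append("dead")
                break
        hists.append(FemaleHistory(f"f{i}", "ASY", 2013, 1, states))
    fit = fit_known_fate(hists, "intercept")
    s_hat = 1.0 / (1.0 + math.exp(-fit.coefficients[0]))
    n_int = fit.n_effective
    mc_se = math.sqrt(0.95 * 0.05 / n_int)
    assert abs(s_hat - 0.95) < 3 * mc_se


def test_rank_models_weights(sim_cohorts):
    females, _, _ = sim_cohorts
    rec = expand_female_histories(females)
    ranked = rank_models([fit_known_fate(rec, m) for m in
                          ("intercept", "year", "year + age")])
    weights = [f.akaike_weight for f in ranked]
    assert sum(weights) == pytest.approx(1.0, abs=1e-12)
    assert ranked[0].delta_aicc == 0.0
    assert all(a.aicc <= b.aicc for a, b in zip(ranked, ranked[1:]))


def test_akaike_weight_ratios_match_delta_rule():
    # weight ratio exp(delta/2): 2.72 at delta 2, 1.65 at delta 1
    w0 = 1.0 / (1.0 + math.exp(-1.0))
    assert w0 / (1 - w0) == pytest.approx(2.72, abs=0.01)
    w1 = 1.0 / (1.0 + math.exp(-0.5))
    assert w1 / (1 - w1) == pytest.approx(1.65, abs=0.01)


def test_rank_models_refuses_mixed_data(sim_cohorts):
    females, nests, _ = sim_cohorts
    f1 = fit_known_fate(expand_female_histories(females), "intercept")
    f2 = fit_known_fate(expand_nest_histories(nests), "intercept")
    with pytest.raises(ValidationError, match="different data"):
        rank_models([f1, f2])


def test_model_average_identity_and_convexity(sim_cohorts):
    females, _, _ = sim_cohorts
    rec = expand_female_histories(females)
    single = rank_models([fit_known_fate(rec, "intercept")])
    avg1 = model_average(single, year=2014)
    only = single[0].interval_survival(2014)
    assert avg1.p == pytest.approx(only.p)
    pair = rank_models([fit_known_fate(rec, "intercept"),
                        fit_known_fate(rec, "year")])
    avg2 = model_average(pair, year=2014)
    per = [f.interval_survival(2014).p for f in pair]
    lo = np.minimum(*per)
    hi = np.maximum(*per)
    assert np.all(avg2.p >= lo - 1e-12) and np.all(avg2.p <= hi + 1e-12)
    # unconditional variance >= weighted within-model variance
    within = sum(f.akaike_weight * f.interval_survival(2014).se ** 2 for f in pair)
    assert np.all(avg2.se ** 2 >= within - 1e-15)


def test_unconditional_variance_formula():
    # two models, weights 0.5/0.5, estimates 0.4/0.6, zero within-model var
    theta = np.array([0.4, 0.6])
    w = np.array([0.5, 0.5])
    point = w @ theta
    var = w @ (0.0 + (theta - point) ** 2)
    assert point == pytest.approx(0.5) and var == pytest.approx(0.01)


def test_window_products_closed_forms():
    iv = IntervalSurvival(window=27, year=2013, age=None,
                          p=np.full(27, 0.97), se=np.full(27, 0.0))
    ns, _ = derive_window_products(iv, "nest27")
    assert ns == pytest.approx(0.97 ** 27)
    assert ns == pytest.approx(0.440, abs=1e-3)
    ivm = IntervalSurvival(window=12, year=2013, age=None,
                           p=np.full(12, 0.95), se=np.full(12, 0.01))
    ann, se = derive_window_products(ivm, "annual12")
    assert ann == pytest.approx(0.95 ** 12)
    assert ann == pytest.approx(0.540, abs=1e-3)
    assert se > 0
    ivz = IntervalSurvival(window=12, year=2013, age=None,
                           p=np.array([0.9] * 11 + [0.0]), se=np.full(12, 0.01))
    assert derive_window_products(ivz, "annual12")[0] == 0.0


def test_seasonal_window_needs_months():
    iv = IntervalSurvival(window=12, year=2013, age=None,
                          p=np.full(12, 0.9), se=np.full(12, 0.01))
    with pytest.raises(ValidationError):
        derive_window_products(iv, "season4")
    s, _ = derive_window_products(iv, "season4", months=[2, 3, 4, 5])
    assert s == pytest.approx(0.9 ** 4)


def _simulate_study(rng, n_per_year=30, years=range(2013, 2019),
                    s_annual=(0.27, 0.45, 0.75, 0.61, 0.58, 0.54),
                    winter_uplift=0.0, age_gap=0.9):
    """Monthly histories under year+age(+winter) truth structure."""
    hists = []
    i = 0
    for year, s_ann in zip(years, s_annual):
        base = s_ann ** (1 / 12)
        for age, mult in (("ASY", 1.0), ("SY", age_gap)):
            for _ in range(n_per_year // 2):
                i += 1
                states = []
                for m in range(1, 13):
                    s = min(base * mult, 0.999)
                    if m == 1 or m >= 10:
                        s = min(s + winter_uplift, 0.999)
                    if rng.random() < s:
                        states.append("alive")
                    else:
                        states.append("dead")
                        break
                hists.append(FemaleHistory(f"f{i}", age, year, 1, states))
    return hists


SY_TRUTH = (0.20, 0.37, 0.68, 0.53, 0.50, 0.46)
ASY_TRUTH = (0.27, 0.45, 0.75, 0.61, 0.58, 0.54)


def _simulate_table_truth(rng, n_age):
    hists = []
    i = 0
    for yi, year in enumerate(range(2013, 2019)):
        for age, s_ann in (("SY", SY_TRUTH[yi]), ("ASY", ASY_TRUTH[yi])):
            s = s_ann ** (1 / 12)
            for _ in range(n_age):
                i += 1
                states = []
                for _m in range(12):
                    if rng.random() < s:
                        states.append("alive")
                    else:
                        states.append("dead")
                        break
                hists.append(FemaleHistory(f"f{i}", age, year, 1, states))
    return hists


def test_female_survival_recovery_study_scale(rng):
    """Median |annual survival error| <= 0.05 under the published annual
    survival truth, at the study's upper-range cohort (50 females/year)."""
    errors = []
    for _ in range(100):
        rec = expand_female_histories(_simulate_table_truth(rng, n_age=25))
        ranked = rank_models([fit_known_fate(rec, "year + age + winter")])
        for yi, year in enumerate(range(2013, 2019)):
            for age, s_true in (("SY", SY_TRUTH[yi]), ("ASY", ASY_TRUTH[yi])):
                iv = model_average(ranked, year=year, age=age)
                s_hat, _ = derive_window_products(iv, "annual12")
                errors.append(abs(s_hat - s_true))
    assert np.median(errors) <= 0.05


def test_nest_survival_recovery_study_scale(rng):
    """Median |27-day NS error| <= 0.05 with ~25 nests/year, intercept truth."""
    dns_true = 0.35 ** (1 / 27)
    errors = []
    for _ in range(100):
        nests = []
        for year in range(2013, 2019):
            for i in range(25):
                states = []
                for _d in range(27):
                    if rng.random() < dns_true:
                        states.append("active")
                    else:
                        states.append("failed")
                        break
                nests.append(NestHistory(f"n{year}{i}", f"f{year}{i}", "ASY",
                                         "first", year, 100, states))
        fit = fit_known_fate(nests, "intercept")
        iv = model_average(rank_models([fit]), year=2013)
        ns_hat, _ = derive_window_products(iv, "nest27")
        errors.append(abs(ns_hat - 0.35))
    assert np.median(errors) <= 0.05


def test_model_selection_recovers_winter_effect(rng):
    """Data simulated with a winter uplift prefer the winter design."""
    wins = []
    for _ in range(50):
        hists = _simulate_study(rng, n_per_year=60, winter_uplift=0.06)
        rec = expand_female_histories(hists)
        fits = {m: fit_known_fate(rec, m)
                for m in ("year + age + winter", "year + age")}
        wins.append(fits["year + age + winter"].aicc < fits["year + age"].aicc)
    assert np.mean(wins) > 0.5
    # and on average the generating design scores lower AICc
    assert np.mean(wins) >= 0.6


def test_exact_window_product_se_positive(sim_cohorts):
    females, _, _ = sim_cohorts
    fit = fit_known_fate(expand_female_histories(females), "year + age")
    p, se = window_product(fit, year=2015, age="ASY")
    assert 0 < p < 1 and se > 0
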