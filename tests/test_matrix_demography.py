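"""Fecundity, eigen-structure, and the parametric bootstrap of lambda."""

import numpy as np
import pytest

from sagepop.core_types_io import (
    AnnualVitalRates,
    RateEstimate,
    RateKey,
    ValidationError,
)
from sagepop.matrix_demography import (
    BootstrapConfig,
    FecundityInputs,
    beta_moment_match,
    bootstrap_lambda,
    build_matrix,
    dominant_eigen,
    fecundity,
    matrix_from_params,
    multi_year_summary,
    params_from_rates,
)


def test_fecundity_2013_adult_values():
    f = fecundity(FecundityInputs(ni1=0.94, cs1=6.33, ns1=0.19, ni2=0.20,
                                  cs2=4.64, ns2=0.17, h=0.95, s_chick=0.21))
    direct = (0.94 * 6.33 * 0.19 + (1 - 0.19) * 0.20 * 4.64 * 0.17) \
        * 0.95 * 0.5 * 0.21
    assert f == pytest.approx(direct)
    assert f == pytest.approx(0.126, abs=5e-4)


def test_fecundity_structural_cases():
    base = dict(ni1=0.9, cs1=6.0, ns1=0.5, ni2=0.3, cs2=4.5, ns2=0.4,
                h=0.95, s_chick=0.25)
    assert fecundity(FecundityInputs(**{**base, "s_chick": 0.0})) == 0.0
    f_ns1 = fecundity(FecundityInputs(**{**base, "ns1": 1.0}))
    assert f_ns1 == pytest.approx(0.9 * 6.0 * 0.95 * 0.5 * 0.25)


def test_dominant_eigenvalue_matches_numpy(rng):
    for _ in range(1000):
        a = rng.uniform(0, 2, size=(2, 2))
        lam = dominant_eigen(a[0, 0], a[0, 1], a[1, 0], a[1, 1])
        ev = np.linalg.eigvals(a)
        assert lam == pytest.approx(float(np.max(ev.real)), abs=1e-12)


def test_lambda_nondecreasing_in_entries(rng):
    h = 1e-7
    for _ in range(200):
        a = rng.uniform(0.05, 1.5, size=(2, 2))
        base = dominant_eigen(*a.ravel())
        for i in range(2):
            for j in range(2):
                b = a.copy()
                b[i, j] += h
                assert dominant_eigen(*b.ravel()) >= base - 1e-14


def test_eigenvectors_normalized(packaged_rates):
    m = build_matrix(packaged_rates[0], sjuv_mode="table")
    assert m.w.sum() == pytest.approx(1.0)
    assert float(m.v @ m.w) == pytest.approx(1.0)
    # eigen-equations hold
    assert m.a @ m.w == pytest.approx(m.lam * m.w, abs=1e-12)
    assert m.v @ m.a == pytest.approx(m.lam * m.v, abs=1e-12)


def test_reproductive_only_bottom_row_gives_adult_survival():
    params = dict.fromkeys(
        ("NI1_SY", "NI1_ASY", "NI2", "NS1_SY", "NS1_ASY", "NS2", "S_chick"), 0.0
    )
    params.update(CS1_SY=6.0, CS1_ASY=6.0, CS2_SY=4.6, CS2_ASY=4.4, H=0.95,
                  S_juv=0.5, S_SY=0.3, S_ASY=0.6)
    m = matrix_from_params(params)
    assert m.lam == pytest.approx(0.6)  # fecundity-free top row


def test_zero_matrix_has_zero_lambda():
    params = dict.fromkeys(
        ("NI1_SY", "NI1_ASY", "NI2", "NS1_SY", "NS1_ASY", "NS2", "S_chick",
         "S_juv", "S_SY", "S_ASY"), 0.0
    )
    params.update(CS1_SY=6.0, CS1_ASY=6.0, CS2_SY=4.6, CS2_ASY=4.4, H=0.95)
    assert matrix_from_params(params).lam == 0.0


def test_2015_point_lambda_exceeds_one(packaged_rates):
    rates_2015 = next(a for a in packaged_rates if a.year == 2015)
    assert build_matrix(rates_2015, sjuv_mode="table").lam > 1.0


def test_missing_rate_named_in_error(packaged_rates):
    broken = AnnualVitalRates(year=2013)
    for key, est in packaged_rates[0].rates.items():
        if key.rate_name != "S_chick":
            broken.add(est)
    with pytest.raises(ValidationError, match="S_chick"):
        params_from_rates(broken)


def test_cs2_fallback_uses_offset(packaged_rates):
    # 2013 has no tabled CS2 for yearlings: falls back to CS1 - 1.39
    p = params_from_rates(packaged_rates[0], sjuv_mode="table")
    assert p["CS2_SY"] == pytest.approx(6.26 - 1.39)
    assert p["CS2_ASY"] == pytest.approx(4.64)  # tabled value kept
    p_off = params_from_rates(packaged_rates[0], sjuv_mode="table", cs2_mode="offset")
    assert p_off["CS2_ASY"] == pytest.approx(6.33 - 1.63)


def test_beta_moment_match_closed_form(rng):
    a, b = beta_moment_match(0.5, 0.0125)
    assert (a, b) == pytest.approx((9.5, 9.5))
    draws = rng.beta(a, b, size=100_000)
    assert draws.mean() == pytest.approx(0.5, abs=0.005)
    assert draws.var() == pytest.approx(0.0125, rel=0.05)


def test_beta_moment_match_infeasible_clipped():
    a, b = beta_moment_match(0.5, 0.4)  # var above m(1-m)
    assert a > 0 and b > 0


def _degenerate_year():
    avr = AnnualVitalRates(year=2013)
    vals = {
        ("NI1", "SY"): 0.9, ("NI1", "ASY"): 0.95, ("NI2", "pooled"): 0.3,
        ("CS1", "SY"): 6.0, ("CS1", "ASY"): 6.5,
        ("H", "pooled"): 0.95, ("NS1", "SY"): 0.5, ("NS1", "ASY"): 0.3,
        ("NS2", "pooled"): 0.4, ("S_chick", "pooled"): 0.25,
        ("S_juv", "pooled"): 0.4, ("S_annual", "SY"): 0.35,
        ("S_annual", "ASY"): 0.5,
    }
    for (name, age), mean in vals.items():
        avr.add(RateEstimate(RateKey(name, age), 2013, mean, 0.0, 10))
    return avr


def test_zero_se_bootstrap_is_degenerate(rng):
    res = bootstrap_lambda(_degenerate_year(),
                           BootstrapConfig(n_replicates=500, sjuv_mode="table"),
                           rng)
    assert np.all(res.replicates == res.lambda_point)
    lo, hi = res.ci
    assert lo == hi == res.lambda_point


def test_bootstrap_draw_supports(packaged_rates, rng):
    cfg = BootstrapConfig(n_replicates=2000, sjuv_mode="table")
    res = bootstrap_lambda(packaged_rates[2], cfg, rng)
    assert np.all(res.replicates > 0)
    assert np.all(np.isfinite(res.replicates))


def test_2013_decline_supported(packaged_rates, rng):
    for mode in ("table", "derived"):
        res = bootstrap_lambda(
            packaged_rates[0], BootstrapConfig(n_replicates=5000, sjuv_mode=mode), rng
        )
        assert res.classification == "decreasing"
        assert res.ci[1] < 1.0


def test_bootstrap_reproducible_and_stable(packaged_rates):
    cfg = BootstrapConfig(n_replicates=4000, sjuv_mode="derived")
    r1 = bootstrap_lambda(packaged_rates[0], cfg, np.random.default_rng(9))
    r2 = bootstrap_lambda(packaged_rates[0], cfg, np.random.default_rng(9))
    assert np.array_equal(r1.replicates, r2.replicates)
    big = bootstrap_lambda(
        packaged_rates[0], BootstrapConfig(n_replicates=8000, sjuv_mode="derived"),
        np.random.default_rng(10),
    )
    assert abs(r1.ci[0] - big.ci[0]) < 0.02
    assert abs(r1.ci[1] - big.ci[1]) < 0.02


def _fake_result(year, lam, reps):
    from sagepop.matrix_demography import LambdaResult

    return LambdaResult(year=year, lambda_point=lam,
                        replicates=np.asarray(reps, dtype=float), matrix=None)


def test_multi_year_geometric_mean_idempotent_and_symmetric():
    same = [_fake_result(2013 + i, 0.9, [0.9] * 100) for i in range(6)]
    s = multi_year_summary(same)
    assert s.geo_mean_point == pytest.approx(0.9)
    assert s.geo_mean_boot_mean == pytest.approx(0.9)
    two = [_fake_result(2013, 0.5, [0.5] * 100), _fake_result(2014, 2.0, [2.0] * 100)]
    assert multi_year_summary(two).geo_mean_point == pytest.approx(1.0)
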