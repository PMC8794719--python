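"""Brood-count likelihood: exhaustive-path oracle, degenerate cases,
two-stage selection and parameter recovery."""

import itertools
import math

import numpy as np
import pytest
from scipy.special import comb, expit

from sagepop.brood_survival import (
    BroodModelSpec,
    RHO_MODEL_SET,
    brood_likelihood,
    fit_brood_model,
    two_stage_selection,
)
from sagepop.core_types_io import BroodHistory
from sagepop.synthetic_data import SimulationTruth, simulate_broods


def _enumerate_loglik(n0, counts, phi, rho):
    """Brute-force likelihood: sum over every latent alive-count path."""
    def binom(n, k, p):
        if k > n:
            return 0.0
        return float(comb(n, k)) * p ** k * (1 - p) ** (n - k)

    total = 0.0
    for path in itertools.product(range(n0 + 1), repeat=5):
        prob = 1.0
        prev = n0
        for t, a in enumerate(path):
            prob *= binom(prev, a, phi[t]) * binom(a, counts[t], rho[t])
            prev = a
            if prob == 0.0:
                break
        total += prob
    return math.log(total) if total > 0 else -math.inf


def _flat_spec_loglik(hist, phi_val, rho_val):
    spec = BroodModelSpec("intercept", "intercept")
    params = np.array([math.log(phi_val / (1 - phi_val)),
                       math.log(rho_val / (1 - rho_val))])
    return brood_likelihood([hist], spec, params), spec, params


def test_dp_matches_exhaustive_enumeration_point_case():
    h = BroodHistory("b1", 2013, 2, [1, 1, 1, 1, 1])
    ll, _, _ = _flat_spec_loglik(h, 0.9, 0.9)
    assert ll == pytest.approx(_enumerate_loglik(2, h.counts, [0.9] * 5, [0.9] * 5))


def test_dp_matches_enumeration_random_parameters(rng):
    """100 random (phi, rho, history) draws with N0 <= 4."""
    for _ in range(100):
        n0 = int(rng.integers(1, 5))
        phi = float(rng.uniform(0.2, 0.95))
        rho = float(rng.uniform(0.2, 0.95))
        # feasible counts: simulate one trajectory
        alive, counts = n0, []
        for t in range(5):
            alive = int(rng.binomial(alive, phi))
            counts.append(int(rng.binomial(alive, rho)))
        h = BroodHistory("b", 2013, n0, counts)
        ll, _, _ = _flat_spec_loglik(h, phi, rho)
        oracle = _enumerate_loglik(n0, counts, [phi] * 5, [rho] * 5)
        assert ll == pytest.approx(oracle, abs=1e-10)


def test_perfect_detection_reduces_to_known_fate():
    # with rho = 1 the counts are the latent states and the likelihood is
    # the product of the binomial thinning terms
    h = BroodHistory("b1", 2013, 4, [3, 2, 2, 1, 1])
    phi = 0.8
    ll, _, _ = _flat_spec_loglik(h, phi, 1.0 - 1e-12)
    expected = 0.0
    prev = 4
    for c in h.counts:
        expected += math.log(float(comb(prev, c)) * phi ** c * (1 - phi) ** (prev - c))
        prev = c
    assert ll == pytest.approx(expected, abs=1e-6)


def test_zero_survival_is_absorbing():
    # phi = 0 exactly (logit -800 underflows to 0): a positive count at
    # any later occasion is impossible
    h = BroodHistory("b1", 2013, 3, [0, 0, 1, 0, 0])
    spec = BroodModelSpec("intercept", "intercept")
    params = np.array([-800.0, expit(0.9)])
    assert brood_likelihood([h], spec, params) == -math.inf


def test_likelihood_invariant_to_brood_order(rng):
    truth = SimulationTruth.from_table(seed=0)
    broods = simulate_broods(truth, rng)
    spec = BroodModelSpec("year", "T")
    k = 6 + 2
    params = rng.normal(0, 0.5, size=k)
    a = brood_likelihood(broods, spec, params)
    shuffled = list(broods)
    rng.shuffle(shuffled)
    b = brood_likelihood(shuffled, spec, params,
                         years=tuple(sorted({h.year for h in broods})))
    assert a == pytest.approx(b, abs=1e-9)


def test_54day_survival_monotone_in_interval_phi(rng, sim_cohorts):
    _, _, broods = sim_cohorts
    fit = fit_brood_model(broods, BroodModelSpec("intercept", "T"))
    base = fit.chick_survival_54d()
    bumped = fit.phi.copy()
    bumped[:, 2] = np.minimum(bumped[:, 2] + 0.05, 1.0)
    for i, y in enumerate(fit.years):
        assert float(np.prod(bumped[i])) > base[y]


def test_recovery_of_54day_survival(rng):
    """60 broods, interval phi 0.8, increasing detection: recover 0.8^5."""
    truth_s = 0.8 ** 5
    truth = SimulationTruth.from_table(seed=0)
    params = {y: dict(truth.params[y], S_chick=truth_s) for y in (2013,)}
    t = SimulationTruth(years=(2013,), params=params,
                        n_females={2013: {"SY": 0, "ASY": 0}},
                        n_broods={2013: 60}, mean_brood_size=5.0)
    broods = simulate_broods(t, rng)
    fit = fit_brood_model(broods, BroodModelSpec("intercept", "T"))
    s54 = fit.chick_survival_54d()[2013]
    n_chicks = sum(h.initial_count for h in broods)
    mc_se = math.sqrt(truth_s * (1 - truth_s) / n_chicks)
    assert abs(s54 - truth_s) < 3 * mc_se


def test_detection_trend_sign_recovery(rng):
    """Increasing detection in truth yields a positive fitted T slope."""
    truth = SimulationTruth.from_table(seed=0)
    params = {2013: dict(truth.params[2013], S_chick=0.33)}
    positives = 0
    n_rep = 50
    for _ in range(n_rep):
        t = SimulationTruth(years=(2013,), params=params,
                            n_females={2013: {"SY": 0, "ASY": 0}},
                            n_broods={2013: 40},
                            rho=(0.3, 0.45, 0.6, 0.75, 0.9))
        broods = simulate_broods(t, rng)
        fit = fit_brood_model(broods, BroodModelSpec("intercept", "T"))
        # rho params follow the phi block: [phi_int, rho_int, rho_T]
        positives += fit.coefficients[-1] > 0
    assert positives >= 0.9 * n_rep


def test_all_counts_at_initial_flags_boundary():
    h = BroodHistory("b1", 2013, 3, [3, 3, 3, 3, 3])
    fit = fit_brood_model([h], BroodModelSpec("intercept", "intercept"))
    assert fit.boundary


def test_two_stage_selection_structure(sim_cohorts):
    _, _, broods = sim_cohorts
    stage1, stage2 = two_stage_selection(
        broods, rho_formulas=("T", "intercept"), phi_formulas=("year", "intercept")
    )
    assert len(stage1) == 2 and len(stage2) == 2
    for stage in (stage1, stage2):
        assert sum(f.akaike_weight for f in stage) == pytest.approx(1.0, abs=1e-12)
        assert stage[0].delta_aicc == 0.0
    assert stage2[0].spec.rho_formula == stage1[0].spec.rho_formula
    # detection and survival estimates live on the probability scale
    assert np.all((stage2[0].rho >= 0) & (stage2[0].rho <= 1))
    assert np.all((stage2[0].phi >= 0) & (stage2[0].phi <= 1))
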