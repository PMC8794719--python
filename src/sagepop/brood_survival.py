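"""Chick survival from repeated brood counts with imperfect detection.

A brood starts at a known size (eggs hatched, the initial count) and is
flushed five times through 54 days post-hatch.  The true number of
chicks alive is latent; each interval thins it binomially by apparent
survival phi, and each flush observes a binomial count with detection
probability rho:

    A_0 = initial count
    A_t | A_{t-1} ~ Binomial(A_{t-1}, phi_t)
    y_t | A_t     ~ Binomial(A_t, rho_t)

The likelihood marginalizes the latent counts exactly with a forward
dynamic program over A_t in [0, A_{t-1}] -- no approximation is needed
at sage-grouse brood sizes.  phi and rho carry logit-linear structures
over year, a linear trend (T) and count-interval (day) covariates;
model selection follows a two-stage protocol (detection structure first
with year-varying survival, then survival structure under the best
detection model).  54-day chick survival per year is the product of the
five interval survivals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import comb, expit

from .core_types_io import BROOD_OCCASIONS, BroodHistory, ValidationError

logger = logging.getLogger("sagepop")

__all__ = [
    "BroodModelSpec",
    "BroodFit",
    "brood_likelihood",
    "fit_brood_model",
    "two_stage_selection",
    "RHO_MODEL_SET",
    "PHI_MODEL_SET",
]

# Default two-stage model sets: detection structures evaluated under
# phi(year), then survival structures under the winning rho.
RHO_MODEL_SET = ("T", "day", "year + T", "year + day", "intercept", "year")
PHI_MODEL_SET = ("year + T", "year", "year + day", "intercept")


@dataclass(frozen=True)
class BroodModelSpec:
    """Logit-linear structures for survival (phi) and detection (rho).

    Formulas use terms ``intercept``, ``year``, ``T`` (linear trend
    scaled to [0, 1] over the five count intervals) and ``day``
    (count-interval categorical, reference interval 1).
    """

    phi_formula: str = "year"
    rho_formula: str = "T"

    @property
    def name(self) -> str:
        return f"phi({self.phi_formula}) rho({self.rho_formula})"


def _terms(formula: str) -> list[str]:
    out = []
    for raw in formula.split("+"):
        t = raw.strip().lower()
        if t and t != "intercept":
            out.append(t)
    return out


def _design(formula: str, years: tuple[int, ...]) -> tuple[np.ndarray, list[str]]:
    """Design matrix over the (year, interval) grid, row-major by year."""
    rows = [(y, t) for y in years for t in range(1, BROOD_OCCASIONS + 1)]
    cols: list[tuple[np.ndarray, str]] = [
        (np.ones(len(rows)), "intercept")
    ]
    for term in _terms(formula):
        if term == "year":
            for y in years[1:]:
                cols.append(
                    (np.array([1.0 if r[0] == y else 0.0 for r in rows]), f"year[{y}]")
                )
        elif term == "t":
            cols.append(
                (
                    np.array([(r[1] - 1.0) / (BROOD_OCCASIONS - 1.0) for r in rows]),
                    "T",
                )
            )
        elif term == "day":
            for d in range(2, BROOD_OCCASIONS + 1):
                cols.append(
                    (np.array([1.0 if r[1] == d else 0.0 for r in rows]), f"day[{d}]")
                )
        else:
            raise ValidationError(f"unknown brood design term {term!r}")
    X = np.column_stack([c for c, _ in cols])
    return X, [n for _, n in cols]


def _rates_grid(
    spec: BroodModelSpec, years: tuple[int, ...], params: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(phi, rho) arrays of shape (n_years, 5) from the parameter vector."""
    Xp, np_names = _design(spec.phi_formula, years)
    Xr, nr_names = _design(spec.rho_formula, years)
    kp = Xp.shape[1]
    if len(params) != kp + Xr.shape[1]:
        raise ValidationError(
            f"expected {kp + Xr.shape[1]} parameters, got {len(params)}"
        )
    phi = expit(Xp @ params[:kp]).reshape(len(years), BROOD_OCCASIONS)
    rho = expit(Xr @ params[kp:]).reshape(len(years), BROOD_OCCASIONS)
    return phi, rho


class _BroodData:
    """Pre-indexed brood histories for fast repeated likelihood evaluation.

    Broods are batched by year so each year's survival transition matrix
    is built once per evaluation and applied to all its broods with one
    matrix product.  States run over 0..max(initial count).
    """

    def __init__(self, histories: Sequence[BroodHistory], years: tuple[int, ...]):
        self.years = years
        self.n_max = max(h.initial_count for h in histories)
        a = np.arange(self.n_max + 1)
        self.a = a
        self.comb_aa = comb(a[:, None], a[None, :])  # C(b, a), zero where a > b
        self.lower = a[None, :] <= a[:, None]
        by_year: dict[int, list[BroodHistory]] = {y: [] for y in years}
        for h in histories:
            by_year[h.year].append(h)
        self.groups = []
        for i, y in enumerate(years):
            hs = by_year[y]
            if not hs:
                continue
            f0 = np.zeros((len(hs), self.n_max + 1))
            for j, h in enumerate(hs):
                f0[j, h.initial_count] = 1.0
            counts = np.array([h.counts for h in hs])  # (B, 5)
            self.groups.append((i, f0, counts))

    def loglik(self, phi: np.ndarray, rho: np.ndarray) -> float:
        a = self.a
        total = 0.0
        for i, f0, counts in self.groups:
            f = f0.copy()
            for t in range(BROOD_OCCASIONS):
                p, r = phi[i, t], rho[i, t]
                trans = np.where(
                    self.lower,
                    self.comb_aa
                    * p ** a[None, :]
                    * (1.0 - p) ** np.maximum(a[:, None] - a[None, :], 0),
                    0.0,
                )
                f = f @ trans
                y = counts[:, t][:, None]  # (B, 1)
                obs = np.where(
                    a[None, :] >= y,
                    comb(a[None, :], y)
                    * r ** y
                    * (1.0 - r) ** np.maximum(a[None, :] - y, 0),
                    0.0,
                )
                f = f * obs
            marg = f.sum(axis=1)
            if np.any(marg <= 0.0):
                return -math.inf
            total += float(np.sum(np.log(marg)))
        return total


def brood_likelihood(
    histories: Sequence[BroodHistory],
    spec: BroodModelSpec,
    params: np.ndarray,
    years: tuple[int, ...] | None = None,
) -> float:
    """Joint log-likelihood of the brood count histories.

    Exact marginalization over latent alive counts (forward DP); brood
    contributions sum, so the value is invariant to brood order.
    """
    if not histories:
        raise ValidationError("no broods")
    years = years or tuple(sorted({h.year for h in histories}))
    phi, rho = _rates_grid(spec, years, np.asarray(params, dtype=float))
    return _BroodData(histories, years).loglik(phi, rho)


@dataclass
class BroodFit:
    """A fitted brood survival/detection model."""

    spec: BroodModelSpec
    years: tuple[int, ...]
    coefficients: np.ndarray
    log_likelihood: float
    K: int
    n_effective: int
    aicc: float
    phi: np.ndarray  # (n_years, 5) interval survival
    rho: np.ndarray  # (n_years, 5) detection
    converged: bool
    boundary: bool
    delta_aicc: float = math.nan
    akaike_weight: float = math.nan

    def chick_survival_54d(self) -> dict[int, float]:
        """54-day survival per year: product of the 5 interval phis."""
        return {y: float(np.prod(self.phi[i])) for i, y in enumerate(self.years)}


def fit_brood_model(
    histories: Sequence[BroodHistory],
    spec: BroodModelSpec,
) -> BroodFit:
    """Maximum-likelihood fit by quasi-Newton on the logit scale.

    Deterministic: zero-initialized coefficients, L-BFGS-B with numeric
    gradients.  A coefficient running to the boundary (|logit| > 10,
    e.g. all counts equal to the initial count) is flagged rather than
    treated as an error.
    """
    if not histories:
        raise ValidationError("no broods to fit")
    years = tuple(sorted({h.year for h in histories}))
    kp = _design(spec.phi_formula, years)[0].shape[1]
    kr = _design(spec.rho_formula, years)[0].shape[1]
    K = kp + kr
    data = _BroodData(histories, years)

    def nll(params: np.ndarray) -> float:
        phi, rho = _rates_grid(spec, years, params)
        ll = data.loglik(phi, rho)
        return -ll if math.isfinite(ll) else 1e12

    res = minimize(
        nll,
        np.zeros(K),
        method="L-BFGS-B",
        options={"maxiter": 1000, "ftol": 1e-12, "gtol": 1e-8},
    )
    if not res.success and res.fun >= 1e11:
        raise ValidationError(f"brood fit failed for {spec.name}: {res.message}")
    boundary = bool(np.max(np.abs(res.x)) > 10.0)
    if boundary:
        logger.warning("brood model %s: boundary estimate flagged", spec.name)
    logL = -float(res.fun)
    phi, rho = _rates_grid(spec, years, res.x)
    n_eff = len(histories) * BROOD_OCCASIONS  # count observations
    denom = n_eff - K - 1
    aicc = (
        -2.0 * logL + 2.0 * K + 2.0 * K * (K + 1) / denom
        if denom > 0
        else math.inf
    )
    return BroodFit(
        spec=spec,
        years=years,
        coefficients=res.x,
        log_likelihood=logL,
        K=K,
        n_effective=n_eff,
        aicc=aicc,
        phi=phi,
        rho=rho,
        converged=bool(res.success),
        boundary=boundary,
    )


def _rank(fits: list[BroodFit]) -> list[BroodFit]:
    ranked = sorted(fits, key=lambda f: f.aicc)
    best = ranked[0].aicc
    w = np.exp(-0.5 * np.array([f.aicc - best for f in ranked]))
    w = w / w.sum()
    for f, wi in zip(ranked, w):
        f.delta_aicc = f.aicc - best
        f.akaike_weight = float(wi)
    return ranked


def two_stage_selection(
    histories: Sequence[BroodHistory],
    rho_formulas: Sequence[str] = RHO_MODEL_SET,
    phi_formulas: Sequence[str] = PHI_MODEL_SET,
) -> tuple[list[BroodFit], list[BroodFit]]:
    """Two-stage model selection over detection then survival structure.

    Stage 1 fits every detection structure with year-varying survival
    and ranks by AICc; stage 2 re-fits every survival structure under
    the winning detection model.  Returns (stage1_ranked, stage2_ranked);
    the head of stage 2 is the overall selected model.
    """
    stage1 = _rank(
        [
            fit_brood_model(histories, BroodModelSpec("year", rho))
            for rho in rho_formulas
        ]
    )
    best_rho = stage1[0].spec.rho_formula
    stage2 = _rank(
        [
            fit_brood_model(histories, BroodModelSpec(phi, best_rho))
            for phi in phi_formulas
        ]
    )
    return stage1, stage2
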