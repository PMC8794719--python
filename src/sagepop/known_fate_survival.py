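"""Known-fate survival engine with staggered entry and censoring.

Telemetered animals whose fate is known in every monitored interval
(no detection parameter) contribute a Bernoulli term per interval:

    logL = sum over monitored intervals [ y log s + (1 - y) log(1 - s) ]

with interval survival s = logistic(x' beta) under a design built from
temporal and age covariates.  Animals enter the risk set at capture
(staggered entry) and leave at death or censoring; unmonitored intervals
contribute nothing.  The same engine serves daily nest survival over the
27-day incubation window and monthly female survival over the
March--February year.

Model sets are ranked by AICc, weighted, and model-averaged; interval
survivals multiply into window products (27-day nest survival, 4-month
seasonal and 12-month annual female survival) with delta-method SEs.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .core_types_io import (
    FEMALE_WINDOW_MONTHS,
    NEST_WINDOW_DAYS,
    FemaleHistory,
    NestHistory,
    ValidationError,
    season_of_month,
)
from .rate_estimators import delta_method_product

logger = logging.getLogger("sagepop")

__all__ = [
    "DesignSpec",
    "SurvivalModelFit",
    "IntervalSurvival",
    "expand_nest_histories",
    "expand_female_histories",
    "fit_known_fate",
    "rank_models",
    "model_average",
    "derive_window_products",
    "window_product",
    "NEST_MODEL_SET",
    "FEMALE_MODEL_SET",
]

# Default model sets (names are the formula strings).  The saturated
# year-by-day interactions are omitted: with desk-scale samples their
# AICc penalty terms are undefined (n_eff - K - 1 <= 0).
NEST_MODEL_SET = (
    "intercept",
    "year",
    "year + julian",
    "year + T",
    "day",
    "year + day",
)

FEMALE_MODEL_SET = (
    "year + age + winter",
    "year + age + season",
    "year + age",
    "year + age + breeding",
    "year + age + fall",
    "year + age + month",
    "year * age",
    "intercept",
)

WINDOWS = {"nest27": NEST_WINDOW_DAYS, "season4": 4, "annual12": FEMALE_WINDOW_MONTHS}


@dataclass(frozen=True)
class DesignSpec:
    """A survival model formula over interval records.

    Terms (separated by ``+``): ``intercept`` (always present), ``year``,
    ``age``, ``season``, ``month``, ``day``, ``T`` (linear trend scaled
    to [0, 1] across the window), ``julian`` (incubation start day,
    scaled), and the single-season indicators ``winter`` / ``breeding``
    / ``fall``.  ``a * b`` expands to main effects plus the ``a:b``
    product block.  Categorical terms use reference-level (drop-first)
    coding.
    """

    formula: str

    @property
    def terms(self) -> list[str]:
        out = []
        for raw in self.formula.split("+"):
            t = raw.strip().lower()
            if not t or t == "intercept":
                continue
            if "*" in t:
                a, b = (s.strip() for s in t.split("*", 1))
                out.extend([a, b, f"{a}:{b}"])
            else:
                out.append(t)
        return out


# ---------------------------------------------------------------------------
# Interval records
# ---------------------------------------------------------------------------

def expand_nest_histories(histories: Sequence[NestHistory]) -> pd.DataFrame:
    """Exposure-day records: one row per monitored nest-day."""
    rows = []
    for h in histories:
        for day, survived in h.exposure():
            rows.append(
                {
                    "id": h.nest_id,
                    "year": h.year,
                    "age": h.age_class,
                    "interval": day,
                    "survived": survived,
                    "julian": h.incubation_start,
                }
            )
    df = pd.DataFrame(
        rows, columns=["id", "year", "age", "interval", "survived", "julian"]
    )
    df.attrs["window"] = NEST_WINDOW_DAYS
    return df


def expand_female_histories(histories: Sequence[FemaleHistory]) -> pd.DataFrame:
    """Bird-month records: one row per monitored female-month."""
    rows = []
    for h in histories:
        for month, survived in h.exposure():
            rows.append(
                {
                    "id": h.female_id,
                    "year": h.year,
                    "age": h.age_class,
                    "interval": month,
                    "survived": survived,
                    "julian": np.nan,
                }
            )
    df = pd.DataFrame(
        rows, columns=["id", "year", "age", "interval", "survived", "julian"]
    )
    df.attrs["window"] = FEMALE_WINDOW_MONTHS
    return df


def _data_token(records: pd.DataFrame) -> str:
    key = pd.util.hash_pandas_object(
        records[["id", "year", "age", "interval", "survived"]], index=False
    ).values
    return hashlib.sha1(key.tobytes()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------

@dataclass
class _DesignMeta:
    window: int
    years: tuple[int, ...]
    julian_range: tuple[float, float]


def _term_columns(
    term: str, rec: pd.DataFrame, meta: _DesignMeta
) -> tuple[np.ndarray, list[str]]:
    n = len(rec)
    if term == "year":
        cols = [
            ((rec["year"] == y).to_numpy(float), f"year[{y}]")
            for y in meta.years[1:]
        ]
    elif term == "age":
        cols = [((rec["age"] == "ASY").to_numpy(float), "age[ASY]")]
    elif term == "season":
        seas = rec["interval"].map(season_of_month)
        cols = [
            ((seas == s).to_numpy(float), f"season[{s}]")
            for s in ("fall", "winter")
        ]
    elif term in ("winter", "breeding", "fall"):
        seas = rec["interval"].map(season_of_month)
        cols = [((seas == term).to_numpy(float), f"{term}[1]")]
    elif term == "month":
        cols = [
            ((rec["interval"] == m).to_numpy(float), f"month[{m}]")
            for m in range(2, FEMALE_WINDOW_MONTHS + 1)
        ]
    elif term == "day":
        cols = [
            ((rec["interval"] == d).to_numpy(float), f"day[{d}]")
            for d in range(2, NEST_WINDOW_DAYS + 1)
        ]
    elif term == "t":
        tvals = (rec["interval"].to_numpy(float) - 1.0) / (meta.window - 1.0)
        cols = [(tvals, "T")]
    elif term == "julian":
        lo, hi = meta.julian_range
        span = hi - lo if hi > lo else 1.0
        cols = [(((rec["julian"].to_numpy(float)) - lo) / span, "julian")]
    else:
        raise ValidationError(f"unknown design term {term!r}")
    if not cols:
        return np.empty((n, 0)), []
    mat = np.column_stack([c for c, _ in cols])
    return mat, [name for _, name in cols]


def _build_design(
    rec: pd.DataFrame, spec: DesignSpec, meta: _DesignMeta
) -> tuple[np.ndarray, list[str]]:
    X = [np.ones((len(rec), 1))]
    names = ["intercept"]
    for term in spec.terms:
        if ":" in term:
            a, b = term.split(":", 1)
            Xa, na = _term_columns(a, rec, meta)
            Xb, nb = _term_columns(b, rec, meta)
            prod = np.einsum("ni,nj->nij", Xa, Xb).reshape(len(rec), -1)
            X.append(prod)
            names.extend(f"{x}:{y}" for x in na for y in nb)
        else:
            Xt, nt = _term_columns(term, rec, meta)
            X.append(Xt)
            names.extend(nt)
    return np.hstack(X), names


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

RIDGE_PRIOR_VAR = 100.0  # logit-scale prior variance of the separation fallback
SEPARATION_BOUND = 10.0  # |beta| beyond this flags (quasi-)separation


@dataclass
class SurvivalModelFit:
    """A fitted known-fate model plus model-set bookkeeping."""

    design: DesignSpec
    coefficients: np.ndarray
    coef_names: list[str]
    log_likelihood: float
    K: int
    n_effective: int
    aicc: float
    vcov: np.ndarray
    meta: _DesignMeta
    data_token: str
    converged: bool
    separation: bool
    penalized: bool
    delta_aicc: float = math.nan
    akaike_weight: float = math.nan

    def design_rows(self, rec: pd.DataFrame) -> np.ndarray:
        X, names = _build_design(rec, self.design, self.meta)
        if names != self.coef_names:
            raise ValidationError("prediction design mismatch with fit")
        return X

    def interval_survival(
        self, year: int, age: str | None = None, julian: float | None = None
    ) -> "IntervalSurvival":
        """Fitted per-interval survival for one year/age over the window.

        ``julian`` defaults to the midpoint of the observed range; it
        only matters for designs that include the covariate.
        """
        meta = self.meta
        if julian is None:
            julian = 0.5 * (meta.julian_range[0] + meta.julian_range[1])
        rec = pd.DataFrame(
            {
                "id": "pred",
                "year": year,
                "age": age or "ASY",
                "interval": np.arange(1, meta.window + 1),
                "survived": 1,
                "julian": julian,
            }
        )
        X = self.design_rows(rec)
        eta = X @ self.coefficients
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = (p * (1.0 - p))[:, None] * X
        var = np.einsum("ij,jk,ik->i", grad, self.vcov, grad)
        return IntervalSurvival(
            window=meta.window,
            year=year,
            age=age,
            p=p,
            se=np.sqrt(np.maximum(var, 0.0)),
            design_rows=X,
            fit=self,
        )


@dataclass
class IntervalSurvival:
    """Per-interval survival probabilities with SEs for one year/age."""

    window: int
    year: int
    age: str | None
    p: np.ndarray
    se: np.ndarray
    design_rows: np.ndarray | None = None
    fit: SurvivalModelFit | None = None


def _nll_grad(beta, X, y, ridge_prec):
    eta = X @ beta
    # numerically stable Bernoulli-logit negative log-likelihood
    nll = float(np.sum(np.logaddexp(0.0, eta) - y * eta))
    p = 1.0 / (1.0 + np.exp(-eta))
    grad = X.T @ (p - y)
    if ridge_prec > 0:
        nll += 0.5 * ridge_prec * float(beta @ beta)
        grad = grad + ridge_prec * beta
    return nll, grad


def fit_known_fate(
    records: pd.DataFrame | Sequence[NestHistory] | Sequence[FemaleHistory],
    design: DesignSpec | str,
) -> SurvivalModelFit:
    """Maximum-likelihood fit of a known-fate design.

    Accepts either an interval-record frame from the expanders or a raw
    history list (expanded automatically).  Optimization is
    deterministic quasi-Newton (BFGS) from zero-initialized logit
    coefficients.  Complete or quasi-complete separation (a coefficient
    running past +-10 on the logit scale) triggers a weak ridge
    refit (prior variance 100) with a logged flag instead of failure.
    """
    if isinstance(design, str):
        design = DesignSpec(design)
    if not isinstance(records, pd.DataFrame):
        seq = list(records)
        if not seq:
            raise ValidationError("no histories to fit")
        if isinstance(seq[0], NestHistory):
            records = expand_nest_histories(seq)
        else:
            records = expand_female_histories(seq)
    if len(records) == 0:
        raise ValidationError("no monitored intervals to fit")
    window = records.attrs.get("window", int(records["interval"].max()))
    jul = records["julian"].to_numpy(float)
    jul = jul[np.isfinite(jul)]
    meta = _DesignMeta(
        window=window,
        years=tuple(sorted(records["year"].unique())),
        julian_range=(float(jul.min()), float(jul.max())) if len(jul) else (0.0, 1.0),
    )
    X, names = _build_design(records, design, meta)
    y = records["survived"].to_numpy(float)
    n, K = X.shape

    def solve(ridge_prec: float):
        res = minimize(
            _nll_grad,
            np.zeros(K),
            args=(X, y, ridge_prec),
            jac=True,
            method="BFGS",
            options={"gtol": 1e-8, "maxiter": 500},
        )
        return res

    res = solve(0.0)
    separation = bool(np.max(np.abs(res.x)) > SEPARATION_BOUND) or not np.all(
        np.isfinite(res.x)
    )
    penalized = False
    if separation:
        logger.warning(
            "design %r: separation detected; refitting with ridge penalty",
            design.formula,
        )
        res = solve(1.0 / RIDGE_PRIOR_VAR)
        penalized = True
    beta = res.x
    # unpenalized log-likelihood at the solution
    nll, _ = _nll_grad(beta, X, y, 0.0)
    logL = -nll
    p = 1.0 / (1.0 + np.exp(-(X @ beta)))
    W = p * (1.0 - p)
    info = (X * W[:, None]).T @ X
    if penalized:
        info = info + np.eye(K) / RIDGE_PRIOR_VAR
    try:
        vcov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        vcov = np.linalg.pinv(info)
    denom = n - K - 1
    if denom <= 0:
        logger.warning(
            "design %r: AICc undefined (n_eff=%d, K=%d); set to inf",
            design.formula, n, K,
        )
        aicc = math.inf
    else:
        aicc = -2.0 * logL + 2.0 * K + 2.0 * K * (K + 1) / denom
    if not (res.success or separation or penalized):
        # BFGS can stop on precision loss at a boundary; accept if the
        # gradient is small, otherwise raise with diagnostics.
        _, g = _nll_grad(beta, X, y, 0.0)
        if np.max(np.abs(g)) > 1e-3:
            raise ValidationError(
                f"known-fate fit failed for {design.formula!r}: {res.message}"
            )
    return SurvivalModelFit(
        design=design,
        coefficients=beta,
        coef_names=names,
        log_likelihood=logL,
        K=K,
        n_effective=n,
        aicc=aicc,
        vcov=vcov,
        meta=meta,
        data_token=_data_token(records),
        converged=bool(res.success),
        separation=separation,
        penalized=penalized,
    )


def rank_models(model_set: Sequence[SurvivalModelFit]) -> list[SurvivalModelFit]:
    """Sort fits by AICc and attach delta-AICc and Akaike weights.

    All fits must come from the identical data (token check): AICc is
    only comparable within one dataset.
    """
    if not model_set:
        raise ValidationError("empty model set")
    tokens = {f.data_token for f in model_set}
    if len(tokens) > 1:
        raise ValidationError("model set mixes fits from different data")
    ranked = sorted(model_set, key=lambda f: f.aicc)
    best = ranked[0].aicc
    deltas = np.array([f.aicc - best for f in ranked])
    w = np.exp(-0.5 * deltas)
    w = w / w.sum()
    for f, d, wi in zip(ranked, deltas, w):
        f.delta_aicc = float(d)
        f.akaike_weight = float(wi)
    return ranked


def model_average(
    ranked: Sequence[SurvivalModelFit],
    year: int,
    age: str | None = None,
    julian: float | None = None,
) -> IntervalSurvival:
    """Model-averaged per-interval survival with unconditional variance.

    point = sum_i w_i theta_i ;  var = sum_i w_i (var_i + (theta_i - point)^2).
    """
    if not ranked:
        raise ValidationError("empty model set")
    if any(math.isnan(f.akaike_weight) for f in ranked):
        raise ValidationError("model set not ranked; call rank_models first")
    per_model = [f.interval_survival(year, age, julian) for f in ranked]
    w = np.array([f.akaike_weight for f in ranked])
    P = np.vstack([m.p for m in per_model])
    V = np.vstack([m.se ** 2 for m in per_model])
    point = w @ P
    var = w @ (V + (P - point) ** 2)
    return IntervalSurvival(
        window=per_model[0].window,
        year=year,
        age=age,
        p=point,
        se=np.sqrt(var),
    )


def derive_window_products(
    interval: IntervalSurvival,
    window: Literal["nest27", "season4", "annual12"],
    months: Sequence[int] | None = None,
) -> tuple[float, float]:
    """Product of per-interval survival over a declared window.

    nest27 multiplies all 27 daily survivals; annual12 all 12 monthly
    survivals; season4 the 4 months given in ``months``.  The SE comes
    from the delta method on the per-interval (mean, SE) pairs.
    """
    size = WINDOWS[window]
    if window == "season4":
        if months is None or len(months) != 4:
            raise ValidationError("season4 window needs its 4 month indices")
        idx = [m - 1 for m in months]
    else:
        if interval.window != size:
            raise ValidationError(
                f"window {window} needs {size} intervals, have {interval.window}"
            )
        idx = list(range(size))
    pairs = [(float(interval.p[i]), float(interval.se[i])) for i in idx]
    if any(p == 0.0 for p, _ in pairs):
        return 0.0, 0.0
    return delta_method_product(pairs)


def window_product(
    fit: SurvivalModelFit,
    year: int,
    age: str | None = None,
    julian: float | None = None,
) -> tuple[float, float]:
    """Full-window survival product for one fit, with the delta-method SE
    propagated exactly through the coefficient covariance."""
    iv = fit.interval_survival(year, age, julian)
    P = float(np.prod(iv.p))
    if P == 0.0:
        return 0.0, 0.0
    grad_beta = P * ((1.0 - iv.p)[:, None] * iv.design_rows).sum(axis=0)
    var = float(grad_beta @ fit.vcov @ grad_beta)
    return P, math.sqrt(max(var, 0.0))
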