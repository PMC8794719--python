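"""Stochastic 2-age pre-birth-pulse matrix model for annual lambda.

The annual projection matrix for yearling (SY) and adult (ASY) females is

    A = [[F_SY * S_juv, F_ASY * S_juv],
         [S_SY,         S_ASY       ]]

in pre-birth-pulse form (the census sits just before the March birth
pulse, so fecundity terms carry offspring through juvenile survival to
census age).  Age-specific fecundity combines first nests and re-nests:

    F_j = [NI1*CS1*NS1 + (1 - NS1)*NI2*CS2*NS2] * H * 0.5 * S_chick

Annual lambda is the dominant eigenvalue.  Uncertainty comes from a
parametric bootstrap: lower-level rates are resampled (beta distributions
moment-matched to mean/SE for probabilities, truncated normals for clutch
sizes), the matrix is rebuilt per replicate, and the 95% CI is the
2.5/97.5 percentile of the replicate eigenvalues.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .core_types_io import AnnualVitalRates, ValidationError
from .rate_estimators import ClutchAdjustment, JuvenileDerivation, clutch_size_renest

logger = logging.getLogger("sagepop")

__all__ = [
    "PARAM_NAMES",
    "PROBABILITY_PARAMS",
    "FecundityInputs",
    "fecundity",
    "ProjectionMatrix",
    "dominant_eigen",
    "params_from_rates",
    "build_matrix",
    "BootstrapConfig",
    "LambdaResult",
    "beta_moment_match",
    "bootstrap_lambda",
    "MultiYearSummary",
    "multi_year_summary",
]

SEX_RATIO = 0.5  # proportion of offspring that are female

# Lower-level parameters of the annual matrix, in a fixed order shared
# with the LTRE module.
PARAM_NAMES = (
    "NI1_SY", "NI1_ASY", "NI2",
    "CS1_SY", "CS1_ASY", "CS2_SY", "CS2_ASY",
    "H",
    "NS1_SY", "NS1_ASY", "NS2",
    "S_chick", "S_juv", "S_SY", "S_ASY",
)
PROBABILITY_PARAMS = frozenset(p for p in PARAM_NAMES if not p.startswith("CS"))


@dataclass(frozen=True)
class FecundityInputs:
    """Lower-level rates entering one age class's fecundity."""

    ni1: float
    cs1: float
    ns1: float
    ni2: float
    cs2: float
    ns2: float
    h: float
    s_chick: float


def fecundity(inputs: FecundityInputs):
    """Female offspring per female at the birth pulse (54 days old).

    Accepts scalars or equally-shaped arrays in ``inputs`` fields, so the
    same expression serves the point estimate and the bootstrap.
    """
    first = inputs.ni1 * inputs.cs1 * inputs.ns1
    renest = (1.0 - inputs.ns1) * inputs.ni2 * inputs.cs2 * inputs.ns2
    return (first + renest) * inputs.h * SEX_RATIO * inputs.s_chick


@dataclass
class ProjectionMatrix:
    """A 2x2 annual matrix with its eigen-structure.

    ``w`` is the right eigenvector (stable age distribution, summing to
    1) and ``v`` the left eigenvector (reproductive values), scaled so
    that v . w = 1.
    """

    a: np.ndarray
    lam: float
    w: np.ndarray
    v: np.ndarray
    params: dict[str, float] = field(default_factory=dict)

    @property
    def f_sy(self) -> float:
        return self.a[0, 0] / self.params["S_juv"] if self.params else math.nan

    @property
    def f_asy(self) -> float:
        return self.a[0, 1] / self.params["S_juv"] if self.params else math.nan


def dominant_eigen(a11, a12, a21, a22):
    """Dominant eigenvalue of a nonnegative 2x2 matrix, closed form.

    lambda = (tr + sqrt((a11 - a22)^2 + 4 a12 a21)) / 2.  Vectorizes over
    equally-shaped array entries.
    """
    disc = (a11 - a22) ** 2 + 4.0 * a12 * a21
    return 0.5 * (a11 + a22 + np.sqrt(disc))


def _eigenvectors(a: np.ndarray, lam: float) -> tuple[np.ndarray, np.ndarray]:
    a11, a12 = a[0]
    a21, a22 = a[1]
    if a12 > 0:
        w = np.array([a12, lam - a11])
    elif abs(lam - a11) < 1e-14:
        w = np.array([1.0, 0.0])
    else:
        w = np.array([0.0, 1.0])
    if a21 > 0:
        v = np.array([a21, lam - a11])
    elif abs(lam - a11) < 1e-14:
        v = np.array([1.0, 0.0])
    else:
        v = np.array([0.0, 1.0])
    if w.sum() <= 0:
        w = np.array([0.5, 0.5])
    w = w / w.sum()
    denom = float(v @ w)
    if abs(denom) < 1e-300:
        raise ValidationError("defective matrix: left/right eigenvectors orthogonal")
    v = v / denom
    return w, v


SjuvMode = Literal["table", "derived"]
Cs2Mode = Literal["table", "offset"]


def params_from_rates(
    rates: AnnualVitalRates,
    sjuv_mode: SjuvMode = "derived",
    cs2_mode: Cs2Mode = "table",
    clutch_adj: ClutchAdjustment | None = None,
    juv: JuvenileDerivation | None = None,
) -> dict[str, float]:
    """Flatten one year's vital rates into the matrix parameter vector.

    ``sjuv_mode='table'`` takes juvenile survival from the table row;
    ``'derived'`` recomputes it as 0.7 * S_ASY^(7/12).  ``cs2_mode``
    likewise switches re-nest clutch size between the tabled estimate and
    the first-nest-minus-offset rule; a missing CS2 row always falls back
    to the offset rule.
    """
    clutch_adj = clutch_adj or ClutchAdjustment()
    missing = rates.missing_matrix_rates()
    if missing:
        raise ValidationError(
            f"year {rates.year}: missing matrix rates "
            + ", ".join(f"{k.rate_name}/{k.age_class}" for k in missing)
        )
    p: dict[str, float] = {}
    p["NI1_SY"] = rates.require("NI1", "SY").mean
    p["NI1_ASY"] = rates.require("NI1", "ASY").mean
    p["NI2"] = rates.require("NI2").mean
    p["CS1_SY"] = rates.require("CS1", "SY").mean
    p["CS1_ASY"] = rates.require("CS1", "ASY").mean
    for age in ("SY", "ASY"):
        tabled = rates.get("CS2", age)
        if cs2_mode == "table" and tabled is not None:
            p[f"CS2_{age}"] = tabled.mean
        else:
            p[f"CS2_{age}"] = clutch_size_renest(
                p[f"CS1_{age}"], age, clutch_adj
            )
    p["H"] = rates.require("H").mean
    p["NS1_SY"] = rates.require("NS1", "SY").mean
    p["NS1_ASY"] = rates.require("NS1", "ASY").mean
    p["NS2"] = rates.require("NS2").mean
    p["S_chick"] = rates.require("S_chick").mean
    p["S_SY"] = rates.require("S_annual", "SY").mean
    p["S_ASY"] = rates.require("S_annual", "ASY").mean
    if sjuv_mode == "derived":
        from .rate_estimators import derive_juvenile_survival

        p["S_juv"], _ = derive_juvenile_survival(p["S_ASY"], juv)
    else:
        p["S_juv"] = rates.require("S_juv").mean
    return p


def matrix_from_params(params: dict[str, float]) -> ProjectionMatrix:
    """Assemble the 2x2 matrix and its eigen-structure from parameters."""
    f_sy = fecundity(FecundityInputs(
        ni1=params["NI1_SY"], cs1=params["CS1_SY"], ns1=params["NS1_SY"],
        ni2=params["NI2"], cs2=params["CS2_SY"], ns2=params["NS2"],
        h=params["H"], s_chick=params["S_chick"],
    ))
    f_asy = fecundity(FecundityInputs(
        ni1=params["NI1_ASY"], cs1=params["CS1_ASY"], ns1=params["NS1_ASY"],
        ni2=params["NI2"], cs2=params["CS2_ASY"], ns2=params["NS2"],
        h=params["H"], s_chick=params["S_chick"],
    ))
    a = np.array([
        [f_sy * params["S_juv"], f_asy * params["S_juv"]],
        [params["S_SY"], params["S_ASY"]],
    ])
    if np.any(a < 0):
        raise ValidationError("negative matrix entry")
    lam = float(dominant_eigen(a[0, 0], a[0, 1], a[1, 0], a[1, 1]))
    w, v = _eigenvectors(a, lam)
    return ProjectionMatrix(a=a, lam=lam, w=w, v=v, params=dict(params))


def build_matrix(
    rates: AnnualVitalRates,
    sjuv_mode: SjuvMode = "derived",
    cs2_mode: Cs2Mode = "table",
) -> ProjectionMatrix:
    """Annual projection matrix from one year's vital-rate table."""
    return matrix_from_params(
        params_from_rates(rates, sjuv_mode=sjuv_mode, cs2_mode=cs2_mode)
    )


# ---------------------------------------------------------------------------
# Parametric bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootstrapConfig:
    """Resampling rules for the lambda bootstrap.

    Probability-scale rates draw from beta distributions moment-matched
    to (mean, SE); clutch sizes from normals truncated to [1, 15].
    Hatchability is held fixed by default (its SE is negligible and it
    enters every year identically).  ``sjuv_mode='derived'`` recomputes
    juvenile survival from each adult-survival draw, keeping the two
    rates consistent within a replicate; ``'table'`` draws it as an
    independent beta from the tabled mean/SE.
    """

    n_replicates: int = 10_000
    sjuv_mode: SjuvMode = "derived"
    cs2_mode: Cs2Mode = "table"
    resample_h: bool = False
    cs_lo: float = 1.0
    cs_hi: float = 15.0


def beta_moment_match(mean: float, var: float) -> tuple[float, float]:
    """Beta shape parameters with the given mean and variance.

    Requires var < mean(1-mean); infeasible variances are clipped to
    0.95 * mean(1-mean) (maximal proper dispersion at that mean) with a
    logged warning.
    """
    if not 0.0 < mean < 1.0:
        raise ValidationError(f"beta mean {mean} outside (0, 1)")
    vmax = mean * (1.0 - mean)
    if var >= vmax:
        logger.warning(
            "beta moment-match infeasible (m=%.3f, v=%.4f); clipping variance",
            mean, var,
        )
        var = 0.95 * vmax
    nu = vmax / var - 1.0
    return mean * nu, (1.0 - mean) * nu


@dataclass
class LambdaResult:
    """Annual lambda with its bootstrap distribution."""

    year: int
    lambda_point: float
    replicates: np.ndarray
    matrix: ProjectionMatrix

    @property
    def boot_mean(self) -> float:
        return float(np.mean(self.replicates))

    @property
    def ci(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.replicates, [2.5, 97.5])
        return float(lo), float(hi)

    @property
    def classification(self) -> str:
        lo, hi = self.ci
        if hi < 1.0:
            return "decreasing"
        if lo > 1.0:
            return "increasing"
        if lo == hi == 1.0:
            return "stable"
        return "uncertain"


def _draw_param(
    name: str,
    est_mean: float,
    est_se: float,
    n: int,
    rng: np.random.Generator,
    cfg: BootstrapConfig,
) -> np.ndarray:
    """Bootstrap draws for one lower-level rate."""
    if est_se == 0.0:
        return np.full(n, est_mean)
    if name.startswith("CS"):
        a = (cfg.cs_lo - est_mean) / est_se
        b = (cfg.cs_hi - est_mean) / est_se
        return stats.truncnorm.rvs(
            a, b, loc=est_mean, scale=est_se, size=n, random_state=rng
        )
    # probability-scale: beta; degenerate means (0 or 1) are held fixed
    if est_mean <= 0.0 or est_mean >= 1.0:
        return np.full(n, est_mean)
    alpha, beta = beta_moment_match(est_mean, est_se ** 2)
    return rng.beta(alpha, beta, size=n)


def bootstrap_lambda(
    rates: AnnualVitalRates,
    cfg: BootstrapConfig,
    rng: np.random.Generator,
) -> LambdaResult:
    """Parametric bootstrap of one year's lambda.

    Each replicate redraws every stochastic lower-level rate, rebuilds
    both fecundities and the matrix, and records the dominant eigenvalue
    (closed form, vectorized across replicates).  Zero-SE rates are held
    at their point value, so an all-zero-SE year collapses to a
    degenerate bootstrap.
    """
    point = build_matrix(rates, sjuv_mode=cfg.sjuv_mode, cs2_mode=cfg.cs2_mode)
    R = cfg.n_replicates
    draws: dict[str, np.ndarray] = {}

    def draw(name: str, rate_name: str, age: str) -> np.ndarray:
        est = rates.require(rate_name, age)
        return _draw_param(name, est.mean, est.se, R, rng, cfg)

    draws["NI1_SY"] = draw("NI1_SY", "NI1", "SY")
    draws["NI1_ASY"] = draw("NI1_ASY", "NI1", "ASY")
    draws["NI2"] = draw("NI2", "NI2", "pooled")
    draws["CS1_SY"] = draw("CS1_SY", "CS1", "SY")
    draws["CS1_ASY"] = draw("CS1_ASY", "CS1", "ASY")
    adj = ClutchAdjustment()
    for age in ("SY", "ASY"):
        tabled = rates.get("CS2", age)
        if cfg.cs2_mode == "table" and tabled is not None:
            draws[f"CS2_{age}"] = _draw_param(
                f"CS2_{age}", tabled.mean, tabled.se, R, rng, cfg
            )
        else:
            cs2 = draws[f"CS1_{age}"] - adj.offset(age)
            n_floor = int(np.sum(cs2 <= 0))
            if n_floor:
                logger.warning(
                    "year %d: floored %d non-positive CS2_%s draws",
                    rates.year, n_floor, age,
                )
            draws[f"CS2_{age}"] = np.maximum(cs2, 0.1)
    h_est = rates.require("H")
    if cfg.resample_h and h_est.se > 0:
        draws["H"] = _draw_param("H", h_est.mean, h_est.se, R, rng, cfg)
    else:
        draws["H"] = np.full(R, h_est.mean)
    draws["NS1_SY"] = draw("NS1_SY", "NS1", "SY")
    draws["NS1_ASY"] = draw("NS1_ASY", "NS1", "ASY")
    draws["NS2"] = draw("NS2", "NS2", "pooled")
    draws["S_chick"] = draw("S_chick", "S_chick", "pooled")
    draws["S_SY"] = draw("S_SY", "S_annual", "SY")
    draws["S_ASY"] = draw("S_ASY", "S_annual", "ASY")
    if cfg.sjuv_mode == "derived":
        juv = JuvenileDerivation()
        draws["S_juv"] = juv.ratio * draws["S_ASY"] ** juv.exponent
    else:
        draws["S_juv"] = draw("S_juv", "S_juv", "pooled")

    f_sy = fecundity(FecundityInputs(
        ni1=draws["NI1_SY"], cs1=draws["CS1_SY"], ns1=draws["NS1_SY"],
        ni2=draws["NI2"], cs2=draws["CS2_SY"], ns2=draws["NS2"],
        h=draws["H"], s_chick=draws["S_chick"],
    ))
    f_asy = fecundity(FecundityInputs(
        ni1=draws["NI1_ASY"], cs1=draws["CS1_ASY"], ns1=draws["NS1_ASY"],
        ni2=draws["NI2"], cs2=draws["CS2_ASY"], ns2=draws["NS2"],
        h=draws["H"], s_chick=draws["S_chick"],
    ))
    lam = dominant_eigen(
        f_sy * draws["S_juv"], f_asy * draws["S_juv"],
        draws["S_SY"], draws["S_ASY"],
    )
    return LambdaResult(
        year=rates.year,
        lambda_point=point.lam,
        replicates=np.asarray(lam, dtype=float),
        matrix=point,
    )


@dataclass
class MultiYearSummary:
    """Geometric-mean lambda over a span of years.

    The point pathway is the geometric mean of annual point estimates;
    the CI pathway pairs bootstrap replicates across years by index
    (independent annual draws) and takes percentiles of the per-replicate
    geometric means.
    """

    years: tuple[int, ...]
    geo_mean_point: float
    geo_mean_boot_mean: float
    ci: tuple[float, float]


def multi_year_summary(results: Sequence[LambdaResult]) -> MultiYearSummary:
    if not results:
        raise ValidationError("no annual results to summarize")
    lams = np.array([r.lambda_point for r in results])
    if np.any(lams == 0):
        logger.warning("geometric mean over a zero lambda is 0")
        geo_point = 0.0
    else:
        geo_point = float(np.exp(np.mean(np.log(lams))))
    reps = np.vstack([r.replicates for r in results])
    with np.errstate(divide="ignore"):
        geo_reps = np.exp(np.mean(np.log(np.maximum(reps, 1e-300)), axis=0))
    lo, hi = np.percentile(geo_reps, [2.5, 97.5])
    return MultiYearSummary(
        years=tuple(r.year for r in results),
        geo_mean_point=geo_point,
        geo_mean_boot_mean=float(np.mean(geo_reps)),
        ci=(float(lo), float(hi)),
    )
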