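"""Closed-form vital-rate estimators and variance utilities.

Covers the rates that need no likelihood machinery: nest-initiation
proportions pooled over years, re-nest clutch sizes via fixed
age-specific offsets from a range-wide meta-analysis, hatchability,
juvenile survival derived by scaling adult survival, the additive
GPS-transmitter survival-bias correction, and the delta method for
variances of products.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_types_io import ValidationError

logger = logging.getLogger("sagepop")

__all__ = [
    "ProportionEstimate",
    "ClutchAdjustment",
    "JuvenileDerivation",
    "GpsBiasAdjustment",
    "pooled_proportion",
    "reconstruct_successes",
    "clutch_size_renest",
    "hatchability",
    "derive_juvenile_survival",
    "adjust_gps_bias",
    "delta_method_product",
]


@dataclass(frozen=True)
class ProportionEstimate:
    """A sample proportion with its binomial variance p(1-p)/n."""

    successes: int
    trials: int

    def __post_init__(self) -> None:
        if not 0 <= self.successes <= self.trials:
            raise ValidationError(
                f"successes {self.successes} outside [0, {self.trials}]"
            )

    @property
    def p(self) -> float:
        return self.successes / self.trials

    @property
    def var(self) -> float:
        p = self.p
        return p * (1.0 - p) / self.trials

    @property
    def se(self) -> float:
        return math.sqrt(self.var)


@dataclass(frozen=True)
class ClutchAdjustment:
    """Fixed first-nest-to-re-nest clutch offsets (eggs).

    The offsets come from a meta-analysis of clutch sizes across the
    species' range; the SDs attach to the small re-nest samples behind
    them (yearling n = 8, adult n = 9).
    """

    sy_offset: float = 1.39
    asy_offset: float = 1.63
    sy_sd: float = 0.40
    asy_sd: float = 0.30

    def offset(self, age_class: str) -> float:
        if age_class == "SY":
            return self.sy_offset
        if age_class == "ASY":
            return self.asy_offset
        raise ValidationError(f"no clutch offset for age class {age_class!r}")

    def sd(self, age_class: str) -> float:
        return self.sy_sd if age_class == "SY" else self.asy_sd


@dataclass(frozen=True)
class JuvenileDerivation:
    """Scaling of annual adult survival to the 7-month juvenile window.

    ratio = 0.53/0.83 (juvenile vs adult survival over the same 7 months
    in a Colorado reference population); exponent = 7/12 rescales annual
    adult survival to 7 months.
    """

    ratio: float = 0.7
    exponent: float = 7.0 / 12.0
    default_se: float = 0.07


@dataclass(frozen=True)
class GpsBiasAdjustment:
    """Additive correction for lower survival under GPS vs VHF collars."""

    delta: float = 0.05


def pooled_proportion(
    per_year: Sequence[tuple[int, int]],
) -> ProportionEstimate:
    """Pool (successes, trials) pairs across years into one proportion.

    The pooled estimate is total successes over total trials, i.e. the
    sample-size-weighted mean of the annual proportions, with variance
    pq/n on the pooled counts.  With a single pair this is the plain
    single-year estimate.
    """
    successes = sum(s for s, _ in per_year)
    trials = sum(t for _, t in per_year)
    if trials < 1:
        raise ValidationError("pooled proportion undefined: no trials")
    return ProportionEstimate(successes=successes, trials=trials)


def reconstruct_successes(p: float, n: int) -> int:
    """Integer success count behind a printed proportion: round(p * n).

    Published tables print rounded proportions; recovering the integer
    numerator before pooling reproduces the underlying pooled rates
    exactly, which averaging the rounded proportions does not.
    """
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"proportion {p} outside [0, 1]")
    return int(round(p * n))


def clutch_size_renest(
    cs1_mean: float, age_class: str, adj: ClutchAdjustment | None = None
) -> float:
    """Re-nest clutch size: first-nest clutch minus the age offset."""
    adj = adj or ClutchAdjustment()
    offset = adj.offset(age_class)
    cs2 = cs1_mean - offset
    if cs2 <= 0:
        raise ValidationError(
            f"degenerate re-nest clutch: {cs1_mean} - {offset} <= 0"
        )
    return cs2


def hatchability(hatched_eggs: int, laid_eggs: int) -> ProportionEstimate:
    """Eggs hatched per egg laid, pooled over successful nests."""
    if laid_eggs < 1:
        raise ValidationError("hatchability undefined: no eggs laid")
    if hatched_eggs > laid_eggs:
        raise ValidationError(
            f"hatched {hatched_eggs} exceeds laid {laid_eggs}"
        )
    return ProportionEstimate(successes=hatched_eggs, trials=laid_eggs)


def derive_juvenile_survival(
    s_asy_annual: float,
    deriv: JuvenileDerivation | None = None,
) -> tuple[float, float]:
    """Juvenile survival derived from annual adult survival.

    Adult survival is rescaled to the ~7-month juvenile window
    (54 days post-hatch to first breeding) by raising it to 7/12, then
    multiplied by the juvenile:adult ratio 0.7.  Returns (mean, se);
    the SE is a fixed constant carried from the reference study rather
    than propagated, mirroring how the derived rate is tabulated.
    """
    deriv = deriv or JuvenileDerivation()
    if not 0.0 < s_asy_annual <= 1.0:
        raise ValidationError(f"adult survival {s_asy_annual} outside (0, 1]")
    return deriv.ratio * s_asy_annual ** deriv.exponent, deriv.default_se


def adjust_gps_bias(
    s_annual: float, adj: GpsBiasAdjustment | None = None
) -> float:
    """Add the GPS-vs-VHF survival bias, capping at 1.

    The additive constant shifts the point estimate only; SEs are
    unchanged by an additive correction.
    """
    adj = adj or GpsBiasAdjustment()
    if not 0.0 <= s_annual <= 1.0:
        raise ValidationError(f"survival {s_annual} outside [0, 1]")
    return min(s_annual + adj.delta, 1.0)


def delta_method_product(
    estimates: Sequence[tuple[float, float]],
    cov: np.ndarray | None = None,
) -> tuple[float, float]:
    """Delta-method mean and SE of a product of estimates.

    For P = prod(m_i),  var(P) ~= P^2 * sum_ij cov_ij / (m_i m_j).
    ``estimates`` is a sequence of (mean, se); ``cov`` defaults to the
    diagonal matrix of the given variances (independence).
    """
    means = np.array([m for m, _ in estimates], dtype=float)
    ses = np.array([s for _, s in estimates], dtype=float)
    if np.any(means <= 0):
        raise ValidationError("delta-method product requires positive means")
    if cov is None:
        cov = np.diag(ses ** 2)
    cov = np.asarray(cov, dtype=float)
    if cov.shape != (len(means), len(means)):
        raise ValidationError(f"covariance shape {cov.shape} mismatched")
    prod = float(np.prod(means))
    rel = cov / np.outer(means, means)
    var = prod ** 2 * float(rel.sum())
    return prod, math.sqrt(max(var, 0.0))
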