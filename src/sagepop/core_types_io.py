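"""Domain types and CSV readers/writers for the demographic pipeline.

The analysis tracks female greater sage-grouse through a March--February
demographic year.  Three kinds of encounter data feed the likelihood
engines:

* **nests** -- daily fate over a 27-day incubation window;
* **females** -- monthly fate with staggered entry and right-censoring;
* **broods** -- an initial chick count (eggs hatched) plus five flush
  counts at roughly 10-day intervals through 54 days post-hatch.

Alongside these, an annual vital-rate table (one row per year, rate and
age class, with mean, SE and sample size) is the input to the matrix
model.  All four are stored as plain long-format CSV so runs are
diff-able and every file round-trips exactly through the writers here.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

logger = logging.getLogger("sagepop")

__all__ = [
    "ValidationError",
    "ParseError",
    "RateKey",
    "RateEstimate",
    "AnnualVitalRates",
    "NestHistory",
    "FemaleHistory",
    "BroodHistory",
    "read_vital_rate_table",
    "write_vital_rate_table",
    "load_packaged_vital_rates",
    "read_encounter_histories",
    "write_encounter_histories",
    "export_mark_strings",
    "MATRIX_RATE_NAMES",
    "NEST_WINDOW_DAYS",
    "FEMALE_WINDOW_MONTHS",
    "BROOD_OCCASIONS",
    "season_of_month",
]

# Fixed study design windows.
NEST_WINDOW_DAYS = 27          # incubation period, days
FEMALE_WINDOW_MONTHS = 12      # March (index 1) .. February (index 12)
BROOD_OCCASIONS = 5            # flush counts at days 14, 24, 34, 44, 54
BROOD_OCCASION_DAYS = (14, 24, 34, 44, 54)

AGE_CLASSES = ("SY", "ASY", "pooled")

RATE_NAMES = (
    "NI1", "NI2", "CS1", "CS2", "H", "NS1", "NS2",
    "S_chick", "S_juv", "S_month", "S_season", "S_annual",
    "S_breed", "S_fall", "S_winter",
)

# Rates estimated pooled across age classes (small samples).
POOLED_ONLY = frozenset({"NI2", "NS2", "H", "S_chick", "S_juv"})

# Probability-scale rates must lie in [0, 1]; clutch sizes are egg counts.
COUNT_SCALE = frozenset({"CS1", "CS2"})

# Rate/age combinations the 2x2 matrix model consumes.  CS2 may be absent
# for an age/year, in which case the re-nest clutch falls back to
# CS1 minus the age-specific offset (see rate_estimators.clutch_size_renest).
MATRIX_RATE_NAMES = (
    ("NI1", "SY"), ("NI1", "ASY"), ("NI2", "pooled"),
    ("CS1", "SY"), ("CS1", "ASY"),
    ("H", "pooled"),
    ("NS1", "SY"), ("NS1", "ASY"), ("NS2", "pooled"),
    ("S_chick", "pooled"), ("S_juv", "pooled"),
    ("S_annual", "SY"), ("S_annual", "ASY"),
)


class ValidationError(ValueError):
    """An input violates a domain invariant."""


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


def season_of_month(month_index: int) -> str:
    """Season of a demographic-year month (1 = March).

    Winter spans December--March (indices 10-12 and 1), breeding
    April--July (2-5) and fall August--November (6-9).
    """
    if not 1 <= month_index <= 12:
        raise ValidationError(f"month index {month_index} outside 1..12")
    if month_index == 1 or month_index >= 10:
        return "winter"
    if month_index <= 5:
        return "breeding"
    return "fall"


# ---------------------------------------------------------------------------
# Vital-rate table
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class RateKey:
    """Identifies a vital rate: name plus age class."""

    rate_name: str
    age_class: str = "pooled"

    def __post_init__(self) -> None:
        if self.rate_name not in RATE_NAMES:
            raise ValidationError(f"unknown rate name {self.rate_name!r}")
        if self.age_class not in AGE_CLASSES:
            raise ValidationError(f"unknown age class {self.age_class!r}")
        if self.rate_name in POOLED_ONLY and self.age_class != "pooled":
            raise ValidationError(
                f"{self.rate_name} is estimated pooled across ages, "
                f"got age_class={self.age_class!r}"
            )


@dataclass(frozen=True)
class RateEstimate:
    """A vital-rate point estimate with its SE and sample size."""

    key: RateKey
    year: int
    mean: float
    se: float
    n: int

    def __post_init__(self) -> None:
        if not math.isfinite(self.mean) or not math.isfinite(self.se):
            raise ValidationError(f"{self.key}: non-finite mean or se")
        if self.se < 0:
            raise ValidationError(f"{self.key}: negative se {self.se}")
        if self.n < 0:
            raise ValidationError(f"{self.key}: negative n {self.n}")
        if self.key.rate_name in COUNT_SCALE:
            if self.mean <= 0:
                raise ValidationError(
                    f"{self.key}: clutch size must be positive, got {self.mean}"
                )
        elif not 0.0 <= self.mean <= 1.0:
            raise ValidationError(
                f"{self.key} ({self.year}): probability {self.mean} outside [0, 1]"
            )

    @property
    def var(self) -> float:
        return self.se ** 2


@dataclass
class AnnualVitalRates:
    """All vital-rate estimates for one demographic year."""

    year: int
    rates: dict[RateKey, RateEstimate] = field(default_factory=dict)

    def get(self, rate_name: str, age_class: str = "pooled") -> RateEstimate | None:
        return self.rates.get(RateKey(rate_name, age_class))

    def require(self, rate_name: str, age_class: str = "pooled") -> RateEstimate:
        est = self.get(rate_name, age_class)
        if est is None:
            raise ValidationError(
                f"year {self.year}: required rate {rate_name}/{age_class} missing"
            )
        return est

    def add(self, est: RateEstimate) -> None:
        if est.year != self.year:
            raise ValidationError(
                f"estimate year {est.year} != container year {self.year}"
            )
        self.rates[est.key] = est

    def missing_matrix_rates(self) -> list[RateKey]:
        """Required matrix inputs absent from this year (CS2 excluded: it
        has a documented fallback)."""
        return [
            RateKey(name, age)
            for name, age in MATRIX_RATE_NAMES
            if RateKey(name, age) not in self.rates
        ]


def read_vital_rate_table(path: str | Path) -> list[AnnualVitalRates]:
    """Read a long-format vital-rate CSV into per-year containers.

    Expects columns ``year,rate_name,age_class,mean,se,n``.  Rows are
    validated against the :class:`RateEstimate` invariants; the error for
    a bad row names its line number.  An empty table yields an empty list.
    """
    df = pd.read_csv(path, dtype=str)
    expected = {"year", "rate_name", "age_class", "mean", "se", "n"}
    if not expected.issubset(df.columns):
        raise ParseError(
            f"{path}: missing columns {sorted(expected - set(df.columns))}"
        )
    years: dict[int, AnnualVitalRates] = {}
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            year = int(row["year"])
            se = float(row["se"])
            if pd.isna(row["se"]):
                logger.warning("%s line %d: missing se treated as 0", path, line)
                se = 0.0
            est = RateEstimate(
                key=RateKey(str(row["rate_name"]), str(row["age_class"])),
                year=year,
                mean=float(row["mean"]),
                se=se,
                n=int(float(row["n"])),
            )
        except ValidationError:
            raise
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path} line {line}: {exc}") from exc
        years.setdefault(year, AnnualVitalRates(year=year)).add(est)
    return [years[y] for y in sorted(years)]


def write_vital_rate_table(
    rates: Sequence[AnnualVitalRates], path: str | Path
) -> None:
    rows = []
    for avr in rates:
        for key in sorted(avr.rates):
            est = avr.rates[key]
            rows.append(
                {
                    "year": avr.year,
                    "rate_name": key.rate_name,
                    "age_class": key.age_class,
                    "mean": est.mean,
                    "se": est.se,
                    "n": est.n,
                }
            )
    pd.DataFrame(
        rows, columns=["year", "rate_name", "age_class", "mean", "se", "n"]
    ).to_csv(path, index=False)


def load_packaged_vital_rates() -> list[AnnualVitalRates]:
    """The packaged 2013-2018 Trout Creek Mountains vital-rate table."""
    ref = resources.files("sagepop").joinpath("data/trout_creek_vital_rates.csv")
    with resources.as_file(ref) as p:
        return read_vital_rate_table(p)


# ---------------------------------------------------------------------------
# Encounter histories
# ---------------------------------------------------------------------------

NEST_STATES = ("active", "failed", "hatched", "censored")
FEMALE_STATES = ("alive", "dead", "censored")
TERMINAL_NEST = frozenset({"failed", "hatched", "censored"})


@dataclass
class NestHistory:
    """Daily fate of one nest over the 27-day incubation window.

    ``day_states[k]`` is the nest's state at the end of exposure day
    ``k + 1``; the sequence stops at (and includes) the first terminal
    state.  A nest still active on day 27 hatched by design.
    """

    nest_id: str
    female_id: str
    age_class: str
    attempt: Literal["first", "renest"]
    year: int
    incubation_start: int  # ordinal day of year
    day_states: list[str]

    def __post_init__(self) -> None:
        if self.age_class not in ("SY", "ASY"):
            raise ValidationError(f"nest {self.nest_id}: bad age {self.age_class}")
        if self.attempt not in ("first", "renest"):
            raise ValidationError(f"nest {self.nest_id}: bad attempt {self.attempt}")
        if not self.day_states:
            raise ValidationError(f"nest {self.nest_id}: empty history")
        if len(self.day_states) > NEST_WINDOW_DAYS:
            raise ValidationError(
                f"nest {self.nest_id}: {len(self.day_states)} days > {NEST_WINDOW_DAYS}"
            )
        for k, s in enumerate(self.day_states):
            if s not in NEST_STATES:
                raise ValidationError(f"nest {self.nest_id}: bad state {s!r}")
            if s in TERMINAL_NEST and k != len(self.day_states) - 1:
                raise ValidationError(
                    f"nest {self.nest_id}: state after terminal {s!r} on day {k + 1}"
                )

    @property
    def fate(self) -> str:
        last = self.day_states[-1]
        if last == "active":  # survived full window
            return "hatched"
        return last

    def exposure(self) -> list[tuple[int, int]]:
        """(day_index, survived) pairs; censored days contribute nothing."""
        out = []
        for k, s in enumerate(self.day_states):
            if s == "censored":
                break
            out.append((k + 1, 0 if s == "failed" else 1))
        return out


@dataclass
class FemaleHistory:
    """Monthly fate of one telemetered female over a demographic year.

    Month index 1 = March.  ``month_states[k]`` is the state at the end
    of month ``entry_month + k``.  Entry is staggered (capture month);
    censoring truncates the record.
    """

    female_id: str
    age_class: str
    year: int
    entry_month: int
    month_states: list[str]

    def __post_init__(self) -> None:
        if self.age_class not in ("SY", "ASY"):
            raise ValidationError(f"female {self.female_id}: bad age {self.age_class}")
        if not 1 <= self.entry_month <= FEMALE_WINDOW_MONTHS:
            raise ValidationError(
                f"female {self.female_id}: entry month {self.entry_month}"
            )
        if not self.month_states:
            raise ValidationError(f"female {self.female_id}: empty history")
        if self.entry_month - 1 + len(self.month_states) > FEMALE_WINDOW_MONTHS:
            raise ValidationError(
                f"female {self.female_id}: history runs past February"
            )
        for k, s in enumerate(self.month_states):
            if s not in FEMALE_STATES:
                raise ValidationError(f"female {self.female_id}: bad state {s!r}")
            if s in ("dead", "censored") and k != len(self.month_states) - 1:
                raise ValidationError(
                    f"female {self.female_id}: state after terminal {s!r}"
                )

    @property
    def fate(self) -> str:
        last = self.month_states[-1]
        return "alive" if last == "alive" else last

    def exposure(self) -> list[tuple[int, int]]:
        """(month_index, survived) pairs for monitored intervals."""
        out = []
        for k, s in enumerate(self.month_states):
            if s == "censored":
                break
            out.append((self.entry_month + k, 0 if s == "dead" else 1))
        return out


@dataclass
class BroodHistory:
    """Initial chick count plus five flush counts for one brood."""

    brood_id: str
    year: int
    initial_count: int
    counts: list[int]

    def __post_init__(self) -> None:
        if self.initial_count < 1:
            raise ValidationError(f"brood {self.brood_id}: initial count < 1")
        if len(self.counts) != BROOD_OCCASIONS:
            raise ValidationError(
                f"brood {self.brood_id}: need {BROOD_OCCASIONS} counts, "
                f"got {len(self.counts)}"
            )
        for t, c in enumerate(self.counts):
            if c < 0 or c > self.initial_count:
                raise ValidationError(
                    f"brood {self.brood_id}: count {c} at occasion {t + 1} "
                    f"outside [0, {self.initial_count}]"
                )


Dialect = Literal["nest", "female", "brood"]


def read_encounter_histories(path: str | Path, dialect: Dialect) -> list:
    """Read one of the three long-format encounter CSVs.

    Dialects and their schemas::

        nest   : nest_id,female_id,age_class,attempt,year,start_doy,day_index,state
        female : female_id,age_class,year,month_index,state
        brood  : brood_id,year,occasion_index,count   (occasion 0 = initial count)

    Rows are grouped by individual and ordered by their time index; the
    resulting objects are validated against the type invariants above.
    For females whose records span demographic years, a yearling alive at
    the start of the following March re-enters as an adult; the age
    transition is applied only to confirmed-alive birds (a February
    censoring leaves the later-year age as recorded).
    """
    df = pd.read_csv(path, dtype=str)
    if dialect == "nest":
        return _read_nests(df, path)
    if dialect == "female":
        return _read_females(df, path)
    if dialect == "brood":
        return _read_broods(df, path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_nests(df: pd.DataFrame, path) -> list[NestHistory]:
    out = []
    if df.empty:
        return out
    for (nest_id,), grp in df.groupby(["nest_id"], sort=True):
        grp = grp.sort_values("day_index", key=lambda s: s.astype(int))
        first = grp.iloc[0]
        try:
            out.append(
                NestHistory(
                    nest_id=str(nest_id),
                    female_id=str(first["female_id"]),
                    age_class=str(first["age_class"]),
                    attempt=str(first["attempt"]),
                    year=int(first["year"]),
                    incubation_start=int(first["start_doy"]),
                    day_states=[str(s) for s in grp["state"]],
                )
            )
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path} nest {nest_id}: {exc}") from exc
    return out


def _read_females(df: pd.DataFrame, path) -> list[FemaleHistory]:
    out = []
    if df.empty:
        return out
    for (female_id, year), grp in df.groupby(["female_id", "year"], sort=True):
        grp = grp.sort_values("month_index", key=lambda s: s.astype(int))
        months = grp["month_index"].astype(int).tolist()
        if months != list(range(months[0], months[0] + len(months))):
            raise ParseError(
                f"{path} female {female_id} year {year}: non-contiguous months"
            )
        try:
            out.append(
                FemaleHistory(
                    female_id=str(female_id),
                    age_class=str(grp.iloc[0]["age_class"]),
                    year=int(year),
                    entry_month=months[0],
                    month_states=[str(s) for s in grp["state"]],
                )
            )
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path} female {female_id}: {exc}") from exc
    _apply_age_transition(out)
    return sorted(out, key=lambda h: (h.year, h.female_id))


def _apply_age_transition(histories: list[FemaleHistory]) -> None:
    """A yearling alive at the end of February is an adult next March."""
    by_female: dict[str, list[FemaleHistory]] = {}
    for h in histories:
        by_female.setdefault(h.female_id, []).append(h)
    for fid, hs in by_female.items():
        hs.sort(key=lambda h: h.year)
        for prev, nxt in zip(hs, hs[1:]):
            survived_full_year = (
                prev.fate == "alive"
                and prev.entry_month - 1 + len(prev.month_states) == FEMALE_WINDOW_MONTHS
            )
            if nxt.year == prev.year + 1 and survived_full_year and nxt.age_class == "SY":
                logger.info("female %s: SY -> ASY transition applied in %d", fid, nxt.year)
                nxt.age_class = "ASY"


def _read_broods(df: pd.DataFrame, path) -> list[BroodHistory]:
    out = []
    if df.empty:
        return out
    for (brood_id,), grp in df.groupby(["brood_id"], sort=True):
        grp = grp.sort_values("occasion_index", key=lambda s: s.astype(int))
        occ = grp["occasion_index"].astype(int).tolist()
        if occ != list(range(0, BROOD_OCCASIONS + 1)):
            raise ParseError(
                f"{path} brood {brood_id}: occasions must be 0..{BROOD_OCCASIONS}"
            )
        counts = grp["count"].astype(int).tolist()
        try:
            out.append(
                BroodHistory(
                    brood_id=str(brood_id),
                    year=int(grp.iloc[0]["year"]),
                    initial_count=counts[0],
                    counts=counts[1:],
                )
            )
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path} brood {brood_id}: {exc}") from exc
    return out


def write_encounter_histories(histories: Iterable, path: str | Path, dialect: Dialect) -> None:
    """Write histories in the long-format schema for ``dialect``."""
    rows = []
    if dialect == "nest":
        cols = ["nest_id", "female_id", "age_class", "attempt", "year",
                "start_doy", "day_index", "state"]
        for h in histories:
            for k, s in enumerate(h.day_states):
                rows.append([h.nest_id, h.female_id, h.age_class, h.attempt,
                             h.year, h.incubation_start, k + 1, s])
    elif dialect == "female":
        cols = ["female_id", "age_class", "year", "month_index", "state"]
        for h in histories:
            for k, s in enumerate(h.month_states):
                rows.append([h.female_id, h.age_class, h.year, h.entry_month + k, s])
    elif dialect == "brood":
        cols = ["brood_id", "year", "occasion_index", "count"]
        for h in histories:
            rows.append([h.brood_id, h.year, 0, h.initial_count])
            for t, c in enumerate(h.counts):
                rows.append([h.brood_id, h.year, t + 1, c])
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def export_mark_strings(histories: Sequence[FemaleHistory | NestHistory]) -> list[str]:
    """Known-fate 'LDLD' encounter strings, one per individual.

    Interoperability export only (never read back): each monitored
    interval contributes ``10`` if the animal survived it, ``11`` if it
    died; unmonitored or censored intervals contribute ``00``.
    """
    out = []
    for h in histories:
        n_intervals = (
            FEMALE_WINDOW_MONTHS if isinstance(h, FemaleHistory) else NEST_WINDOW_DAYS
        )
        cells = ["00"] * n_intervals
        for idx, survived in h.exposure():
            cells[idx - 1] = "10" if survived else "11"
        ident = h.female_id if isinstance(h, FemaleHistory) else h.nest_id
        out.append(f"{ident} {''.join(cells)}")
    return out
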