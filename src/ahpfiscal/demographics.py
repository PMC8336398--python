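"""Life tables, conditional survival and discounted expected work years.

All lifetime streams in the model are weighted by the probability of being
alive at each age, conditional on being alive at the model start age
(diagnosis), and discounted to that age. Ages are whole model years and
cashflows fall at the start of each year, so the discount factor for age
``a`` is ``(1 + r) ** -(a - base_age)``; ages before the base age carry a
factor of 1 (earnings accrued before the comparison start are summed
undiscounted rather than compounded upward).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LifeTable",
    "AgeSchedule",
    "load_life_table",
    "load_age_profiles",
    "conditional_survival",
    "discount_factors",
    "expected_work_years",
]


class InputFormatError(ValueError):
    """Malformed input table (missing column, bad value, gap in ages)."""


def _as_int_ages(ages) -> np.ndarray:
    a = np.asarray(ages)
    if a.ndim != 1 or a.size == 0:
        raise InputFormatError("ages must be a non-empty 1-d sequence")
    ai = a.astype(int)
    if not np.all(ai == a):
        raise InputFormatError("ages must be whole years")
    return ai


@dataclass(frozen=True)
class LifeTable:
    """Closed single-year life table: annual death probabilities ``qx`` by age.

    The final age must have ``qx == 1`` so that every projection terminates.
    """

    ages: np.ndarray
    qx: np.ndarray

    def __post_init__(self):
        ages = _as_int_ages(self.ages)
        qx = np.asarray(self.qx, dtype=float)
        if len(ages) != len(qx):
            raise InputFormatError("ages and qx lengths differ")
        gaps = np.flatnonzero(np.diff(ages) != 1)
        if gaps.size:
            raise InputFormatError(
                f"ages must be contiguous; gap after age {ages[gaps[0]]}"
            )
        bad = np.flatnonzero((qx < 0) | (qx > 1) | ~np.isfinite(qx))
        if bad.size:
            raise InputFormatError(
                f"qx out of [0, 1] at age {ages[bad[0]]} (value {qx[bad[0]]!r})"
            )
        if qx[-1] != 1.0:
            raise InputFormatError(
                f"table must be closed: qx at terminal age {ages[-1]} is "
                f"{qx[-1]!r}, expected 1.0"
            )
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "qx", qx)

    @property
    def min_age(self) -> int:
        return int(self.ages[0])

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    def q(self, age: int) -> float:
        """Annual death probability at ``age``."""
        if age < self.min_age or age > self.max_age:
            raise InputFormatError(f"age {age} outside life table range")
        return float(self.qx[age - self.min_age])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "qx": self.qx})


@dataclass(frozen=True)
class AgeSchedule:
    """A value per age over a contiguous window (earnings, rates, costs...)."""

    ages: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        ages = _as_int_ages(self.ages)
        values = np.asarray(self.values, dtype=float)
        if len(ages) != len(values):
            raise InputFormatError("ages and values lengths differ")
        if np.any(np.diff(ages) != 1):
            raise InputFormatError("schedule ages must be contiguous")
        if not np.all(np.isfinite(values)):
            raise InputFormatError("schedule values must be finite")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "values", values)

    @property
    def min_age(self) -> int:
        return int(self.ages[0])

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    def at(self, age: int, default: float | None = None) -> float:
        if age < self.min_age or age > self.max_age:
            if default is not None:
                return float(default)
            raise KeyError(f"schedule has no value for age {age}")
        return float(self.values[age - self.min_age])

    def window(self, lo: int, hi: int) -> "AgeSchedule":
        """Restrict to ages ``lo..hi`` inclusive; both must be covered."""
        if lo < self.min_age or hi > self.max_age or lo > hi:
            raise KeyError(f"window {lo}..{hi} not covered by schedule")
        i, j = lo - self.min_age, hi - self.min_age + 1
        return AgeSchedule(self.ages[i:j], self.values[i:j])

    def scaled(self, factor: float) -> "AgeSchedule":
        return AgeSchedule(self.ages, self.values * factor)

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=pd.Index(self.ages, name="age"))


def load_life_table(path) -> LifeTable:
    """Read a life-table CSV with header ``age,qx``.

    Rows violating the table invariants are reported with the offending age.
    """
    df = pd.read_csv(path)
    for col in ("age", "qx"):
        if col not in df.columns:
            raise InputFormatError(f"life table is missing column {col!r}")
    return LifeTable(df["age"].to_numpy(), df["qx"].to_numpy())


PROFILE_COLUMNS = ("gross_earnings", "activity_rate", "disability_rate", "gp_health_cost")


def load_age_profiles(path) -> dict[str, AgeSchedule]:
    """Read the age-profile CSV.

    Header ``age,gross_earnings,activity_rate,disability_rate,gp_health_cost``
    (an optional ``consumption`` column is accepted — see fiscal module).
    Returns one schedule per column keyed by column name.
    """
    df = pd.read_csv(path)
    if "age" not in df.columns:
        raise InputFormatError("profile table is missing column 'age'")
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise InputFormatError(f"profile table is missing columns {missing}")
    ages = df["age"].to_numpy()
    out = {}
    for col in df.columns:
        if col == "age":
            continue
        out[col] = AgeSchedule(ages, df[col].to_numpy())
    for rate_col in ("activity_rate", "disability_rate"):
        v = out[rate_col].values
        bad = np.flatnonzero((v < 0) | (v > 1))
        if bad.size:
            raise InputFormatError(
                f"{rate_col} outside [0, 1] at age {ages[bad[0]]}"
            )
    return out


def conditional_survival(lt: LifeTable, base_age: int, horizon_age: int) -> AgeSchedule:
    """P(alive at start of age a | alive at base_age) for a in base..horizon.

    S(base_age) = 1 and S(a + 1) = S(a) * (1 - qx(a)).
    """
    if base_age < lt.min_age or horizon_age > lt.max_age:
        raise InputFormatError(
            f"ages {base_age}..{horizon_age} outside life table range "
            f"{lt.min_age}..{lt.max_age}"
        )
    if base_age >= horizon_age:
        raise InputFormatError("base_age must be below horizon_age")
    ages = np.arange(base_age, horizon_age + 1)
    q = lt.qx[base_age - lt.min_age : horizon_age - lt.min_age]
    s = np.empty(len(ages))
    s[0] = 1.0
    s[1:] = np.cumprod(1.0 - q)
    return AgeSchedule(ages, s)


def discount_factors(ages, rate: float, base_age: int) -> np.ndarray:
    """Start-of-year discount factors (1+r)^-(a-base); 1 for a < base."""
    t = np.maximum(np.asarray(ages, dtype=float) - base_age, 0.0)
    return (1.0 + rate) ** -t


def expected_work_years(
    activity: AgeSchedule,
    survival: AgeSchedule,
    discount_rate: float,
    entry_age: int,
    retirement_age: int,
    base_age: int,
) -> float:
    """Discounted, survival-weighted expected years in work.

    Sums ``activity(a) * S(a) * d(a)`` over ages ``entry_age`` to
    ``retirement_age - 1``. Survival before the conditioning age is 1 (being
    alive at the base age implies having been alive earlier), so the survival
    schedule only needs to cover ages from ``base_age`` up.
    """
    if entry_age >= retirement_age:
        raise ValueError("entry_age must be below retirement_age")
    ages = np.arange(entry_age, retirement_age)
    if entry_age < activity.min_age or retirement_age - 1 > activity.max_age:
        raise ValueError(
            f"activity schedule {activity.min_age}..{activity.max_age} does not "
            f"cover work ages {entry_age}..{retirement_age - 1}"
        )
    if retirement_age - 1 > survival.max_age:
        raise ValueError("survival schedule does not reach retirement")
    act = np.array([activity.at(a) for a in ages])
    if np.any((act < 0) | (act > 1)):
        raise ValueError("activity values must lie in [0, 1]")
    surv = np.array([survival.at(a, default=1.0) for a in ages])
    d = discount_factors(ages, discount_rate, base_age)
    return float(np.sum(act * surv * d))
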