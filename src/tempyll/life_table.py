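"""Daily years-of-life-lost (YLL) construction from death records.

Each death contributes its residual life expectancy — looked up by sex and
completed age in a reference life table — and the daily YLL series is the
sum of those contributions per calendar day.  The reference table used for
a multi-year study period is the elementwise average of the tables at the
period's ends.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LifeTable",
    "DeathRecord",
    "average_life_tables",
    "yll_for_death",
    "daily_yll",
    "read_life_table",
    "synthetic_life_table",
]

SEXES = ("male", "female")


@dataclass(frozen=True)
class LifeTable:
    """Residual life expectancy e(age, sex), ages 0..top in completed years.

    ``entries`` maps each sex to a vector of life expectancies indexed by
    age; both sexes must cover the identical age range, e must be
    non-negative and non-increasing in age.
    """

    entries: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if set(self.entries) != set(SEXES):
            raise ValueError(f"life table must have exactly the sexes {SEXES}")
        lengths = {s: len(self.entries[s]) for s in SEXES}
        if len(set(lengths.values())) != 1:
            raise ValueError(f"sexes cover different age ranges: {lengths}")
        clean = {}
        for s in SEXES:
            e = np.asarray(self.entries[s], dtype=float)
            if e.size == 0:
                raise ValueError("empty life table")
            if np.any(e < 0):
                raise ValueError(f"negative life expectancy for sex={s}")
            if np.any(np.diff(e) > 1e-9):
                age = int(np.argmax(np.diff(e) > 1e-9))
                raise ValueError(
                    f"life expectancy increases with age for sex={s} at age {age}->{age + 1}"
                )
            clean[s] = e
        object.__setattr__(self, "entries", clean)

    @property
    def top_age(self) -> int:
        return len(self.entries["male"]) - 1

    def expectancy(self, sex: str, age: float) -> float:
        """e(sex, age); non-integer ages floor to completed years, ages above
        the top band clamp to the top band."""
        if sex not in SEXES:
            raise ValueError(f"unknown sex code {sex!r}; expected one of {SEXES}")
        if age < 0:
            raise ValueError(f"negative age {age}")
        a = min(int(math.floor(age)), self.top_age)
        return float(self.entries[sex][a])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"sex": s, "age": a, "e": self.entries[s][a]}
            for s in SEXES
            for a in range(self.top_age + 1)
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class DeathRecord:
    """One death: calendar date, completed age, sex, optional subgroup labels."""

    date: pd.Timestamp
    age_at_death: float
    sex: str
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.age_at_death < 0:
            raise ValueError("age_at_death must be >= 0")
        object.__setattr__(self, "date", pd.Timestamp(self.date).normalize())


def average_life_tables(table_a: LifeTable, table_b: LifeTable) -> LifeTable:
    """Elementwise mean of two life tables covering the same (sex, age) grid."""
    if table_a.top_age != table_b.top_age:
        raise ValueError(
            f"life tables cover different age ranges: 0..{table_a.top_age} vs 0..{table_b.top_age}"
        )
    return LifeTable(
        entries={s: (table_a.entries[s] + table_b.entries[s]) / 2.0 for s in SEXES}
    )


def yll_for_death(record: DeathRecord, lt: LifeTable) -> float:
    """Years of life lost for one death: e(age_at_death, sex) from ``lt``."""
    return lt.expectancy(record.sex, record.age_at_death)


def daily_yll(records, lt: LifeTable, window) -> pd.Series:
    """Sum per-death YLL into a daily series over ``window = (start, end)``.

    Every calendar day in the window gets a value; days with no deaths are 0.
    Records dated outside the window raise with the offending dates listed.
    """
    start, end = (pd.Timestamp(window[0]), pd.Timestamp(window[1]))
    idx = pd.date_range(start, end, freq="D")
    out = pd.Series(0.0, index=idx, name="yll")
    bad = sorted({str(r.date.date()) for r in records if not (start <= r.date <= end)})
    if bad:
        raise ValueError(f"death records outside the window {start.date()}..{end.date()}: {bad}")
    for r in records:
        out.loc[r.date] += yll_for_death(r, lt)
    return out


def read_life_table(path) -> LifeTable:
    """Read a life table CSV.

    Accepts ``sex,age,e2010,e2019`` (averaged on read) or a pre-averaged
    ``sex,age,e``.  Every age 0..top must be present for both sexes.
    """
    df = pd.read_csv(path, comment="#")
    cols = set(df.columns)
    if {"sex", "age", "e"} <= cols:
        value = df["e"].astype(float)
    elif {"sex", "age", "e2010", "e2019"} <= cols:
        value = (df["e2010"].astype(float) + df["e2019"].astype(float)) / 2.0
    else:
        raise ValueError(
            f"life table must have columns sex,age,e or sex,age,e2010,e2019; got {sorted(cols)}"
        )
    df = df.assign(_e=value)
    entries = {}
    for s in SEXES:
        sub = df[df["sex"] == s].sort_values("age")
        ages = sub["age"].to_numpy()
        if len(ages) == 0 or not np.array_equal(ages, np.arange(ages.max() + 1)):
            raise ValueError(f"life table ages for sex={s} must be contiguous from 0")
        entries[s] = sub["_e"].to_numpy()
    return LifeTable(entries=entries)


def synthetic_life_table(year: int = 2010, top_age: int = 100) -> LifeTable:
    """Synthetic sex-by-age life table from a Gompertz mortality law.

    A stand-in reference table (the national table is supplied by the
    user in real analyses): hazard mu(a) = A * exp(B * a), with A chosen
    per sex and calendar year to give plausible life expectancy at birth
    (male ~72.5 / female ~77.5 in 2010, about three years higher in 2019),
    survival integrated on a fine grid.  Deterministic.
    """
    e0_targets = {
        ("male", 2010): 72.5,
        ("female", 2010): 77.5,
        ("male", 2019): 75.5,
        ("female", 2019): 80.5,
    }
    B = 0.09
    grid = np.linspace(0.0, 110.0, 2201)  # 0.05-year steps

    def e_curve(A: float) -> np.ndarray:
        S = np.exp(-A / B * (np.exp(B * grid) - 1.0))
        # residual expectancy at each age via trapezoidal tail integration
        tail = np.concatenate(
            [np.cumsum(((S[1:] + S[:-1]) / 2.0 * np.diff(grid))[::-1])[::-1], [0.0]]
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            e = np.where(S > 0, tail / S, 0.0)
        return np.interp(np.arange(top_age + 1, dtype=float), grid, e)

    entries = {}
    for sex in SEXES:
        target = e0_targets.get((sex, year))
        if target is None:
            raise ValueError(f"no synthetic calibration for year {year}")
        from scipy.optimize import brentq

        A = brentq(lambda a: e_curve(a)[0] - target, 1e-6, 1e-2, xtol=1e-12)
        e = e_curve(A)
        entries[sex] = np.maximum.accumulate(e[::-1])[::-1]  # guard monotonicity
    return LifeTable(entries=entries)
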