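"""Age-dependent background mortality.

The cohort model needs an annual death probability q(x) for every integer
age. Published Korean national life tables are the natural source; because
redistributing them is impractical, the package ships a Gompertz–Makeham
parametric table calibrated so that remaining life expectancy at the cohort
start age (38 y) is ~48 years, in line with recent Korean unisex tables. A
real life table can be supplied as a two-column CSV (``age,qx``) and is used
identically.

Mortality applies in every living state — treatment choice and disease
severity do not modify it — and death is absorbing with zero cost and zero
utility. Annual probabilities are converted to per-cycle probabilities by
the constant-rate rule ``1 - (1 - q)**cycle_years``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_MAKEHAM_A = 1.0e-4
DEFAULT_GOMPERTZ_B = 1.0e-5
DEFAULT_GOMPERTZ_C = 0.10
TERMINAL_AGE = 110


@dataclass(frozen=True)
class LifeTable:
    """Annual death probabilities ``qx`` for contiguous integer ``ages``;
    q = 1 at the terminal age."""

    ages: np.ndarray
    qx: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        qx = np.asarray(self.qx, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "qx", qx)
        if ages.size == 0:
            raise ValueError("life table is empty")
        if ages.size != qx.size:
            raise ValueError("age and qx columns differ in length")
        if not np.all(np.diff(ages) == 1):
            raise ValueError("ages must be contiguous integers")
        if np.any((qx < 0) | (qx > 1)):
            raise ValueError("death probabilities must lie in [0, 1]")
        if qx[-1] != 1.0:
            raise ValueError("terminal age must have q = 1")
        adult = qx[ages >= 30]
        if adult.size > 1 and np.any(np.diff(adult) < -1e-12):
            raise ValueError("q must be non-decreasing from age 30 upward")

    @property
    def terminal_age(self) -> int:
        return int(self.ages[-1])

    def q_annual(self, age: float) -> float:
        """Annual death probability for the year of age containing ``age``
        (integer-age lookup by floor)."""
        year = math.floor(age)
        if year < self.ages[0]:
            raise ValueError(f"age {age} below table start {self.ages[0]}")
        if year >= self.terminal_age:
            return 1.0
        return float(self.qx[year - int(self.ages[0])])

    def survival(self, from_age: int) -> np.ndarray:
        """S(k) = P(alive k whole years after ``from_age``); S(0) = 1."""
        i = int(from_age) - int(self.ages[0])
        if i < 0:
            raise ValueError("from_age below table start")
        return np.concatenate([[1.0], np.cumprod(1.0 - self.qx[i:])])

    def life_expectancy(self, age: int) -> float:
        """Curtate remaining life expectancy plus the standard half-year."""
        s = self.survival(age)
        return float(s[1:].sum() + 0.5)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "qx": self.qx})

    def save_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def synthetic_lifetable(
    makeham_a: float = DEFAULT_MAKEHAM_A,
    gompertz_b: float = DEFAULT_GOMPERTZ_B,
    gompertz_c: float = DEFAULT_GOMPERTZ_C,
    terminal_age: int = TERMINAL_AGE,
) -> LifeTable:
    """Synthetic unisex life table from the Gompertz–Makeham hazard
    mu(x) = a + b*exp(c*x), so q(x) = 1 - exp(-mu(x)), capped at 1 and
    forced to 1 at the terminal age.

    The defaults give a remaining life expectancy at age 38 of about 48
    years, consistent with contemporary Korean unisex life tables.
    """
    if makeham_a < 0:
        raise ValueError("makeham_a must be >= 0")
    if gompertz_b <= 0 or gompertz_c <= 0:
        raise ValueError("gompertz_b and gompertz_c must be > 0")
    ages = np.arange(0, terminal_age + 1)
    hazard = makeham_a + gompertz_b * np.exp(gompertz_c * ages)
    qx = 1.0 - np.exp(-hazard)
    qx = np.clip(qx, 0.0, 1.0)
    qx[-1] = 1.0
    return LifeTable(ages=ages, qx=qx)


def load_lifetable(path: str | Path) -> LifeTable:
    """Read a two-column CSV life table with header ``age,qx``."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"life table {path} is empty") from exc
    missing = {"age", "qx"} - set(df.columns)
    if missing:
        raise ValueError(f"life table {path} lacks column(s) {sorted(missing)}")
    age = pd.to_numeric(df["age"], errors="coerce")
    qx = pd.to_numeric(df["qx"], errors="coerce")
    if age.isna().any() or qx.isna().any():
        raise ValueError(f"life table {path} contains non-numeric rows")
    if (age != age.round()).any():
        raise ValueError(f"life table {path} ages must be integers")
    return LifeTable(ages=age.to_numpy(dtype=int), qx=qx.to_numpy(dtype=float))


def annual_to_cycle_prob(q_annual: float, cycle_years: float) -> float:
    """Constant-rate conversion of an annual probability to a cycle
    probability: 1 - (1 - q)^cycle_years."""
    if not 0.0 <= q_annual <= 1.0:
        raise ValueError("q_annual must lie in [0, 1]")
    return 1.0 - (1.0 - q_annual) ** cycle_years


def cycle_death_prob(table: LifeTable, age: float, cycle_years: float) -> float:
    """Per-cycle death probability at fractional ``age`` (annual q looked up
    by integer age, constant hazard within the year)."""
    if age > table.terminal_age:
        raise ValueError(f"age {age} beyond terminal age {table.terminal_age}")
    return annual_to_cycle_prob(table.q_annual(age), cycle_years)
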