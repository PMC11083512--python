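"""Drug-price schedules under the Korean EPED rule.

"Equal pricing for equivalent drugs" (EPED) mandatorily cuts a drug's
reimbursement ceiling when its first generic or biosimilar enters:

* **biologic** — a one-time cut to 70% of the pre-entry price;
* **chemical** — a step-wise cut: the originator keeps 70% for the first
  year after entry, then all products drop to 53.5%. (The first generic's
  own 59.5% year-one price is recorded for completeness but never applied:
  patients are assumed not to switch products.)

A policy configuration is turned into a per-cycle unit-price schedule. The
cut applies from the first cycle whose *start time* is at or after the entry
time T*; the cycle straddling T* is not prorated, keeping schedules
piecewise-constant per cycle.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

POLICY_KINDS = ("none", "biologic", "chemical")


@dataclass(frozen=True)
class PolicyConfig:
    """EPED policy setting: what kind of cut, and when generic entry occurs."""

    policy_kind: str = "biologic"
    time_to_entry: float = 10.3  # years from evaluation to first entry (T*)
    biologic_factor: float = 0.70
    chemical_factor_year1: float = 0.70
    chemical_factor_after: float = 0.535
    first_generic_factor_year1: float = 0.595  # recorded, unused (no switching)

    def __post_init__(self) -> None:
        if self.policy_kind not in POLICY_KINDS:
            raise ValueError(f"policy_kind must be one of {POLICY_KINDS}")
        if self.time_to_entry < 0:
            raise ValueError("time_to_entry must be >= 0")
        for name in (
            "biologic_factor",
            "chemical_factor_year1",
            "chemical_factor_after",
            "first_generic_factor_year1",
        ):
            f = getattr(self, name)
            if not 0.0 < f <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")


NO_POLICY = PolicyConfig(policy_kind="none")


@dataclass(frozen=True)
class PriceSchedule:
    """Per-cycle unit price and the underlying multiplier path m_t."""

    prices: np.ndarray
    multipliers: np.ndarray
    cycle_years: float
    policy: PolicyConfig

    def __post_init__(self) -> None:
        p = np.asarray(self.prices, dtype=float)
        m = np.asarray(self.multipliers, dtype=float)
        object.__setattr__(self, "prices", p)
        object.__setattr__(self, "multipliers", m)
        if p.size != m.size:
            raise ValueError("prices and multipliers differ in length")
        if np.any(p < 0):
            raise ValueError("prices must be non-negative")
        if np.any(np.diff(m) > 1e-12):
            raise ValueError("multipliers must be non-increasing over cycles")

    def __len__(self) -> int:
        return int(self.prices.size)

    @property
    def start_times(self) -> np.ndarray:
        return np.arange(len(self)) * self.cycle_years

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": np.arange(len(self)),
                "start_time_years": self.start_times,
                "multiplier": self.multipliers,
                "price": self.prices,
            }
        )

    def save_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def build_schedule(
    policy: PolicyConfig, unit_price: float, n_cycles: int, cycle_years: float
) -> PriceSchedule:
    """Per-cycle price path implied by an EPED policy.

    The multiplier of cycle t (start time t*cycle_years) is 1 before T*;
    from the first cycle starting at or after T* it is the biologic factor
    (``biologic``) or the chemical year-one factor for start times in
    [T*, T* + 1 y) and the chemical post-year-one factor thereafter
    (``chemical``); a ``none`` policy is the identity schedule.
    """
    if unit_price < 0:
        raise ValueError("unit price must be non-negative")
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    t_start = np.arange(n_cycles) * cycle_years
    m = np.ones(n_cycles)
    if policy.policy_kind == "biologic":
        m[t_start >= policy.time_to_entry] = policy.biologic_factor
    elif policy.policy_kind == "chemical":
        year1 = (t_start >= policy.time_to_entry) & (t_start < policy.time_to_entry + 1.0)
        m[year1] = policy.chemical_factor_year1
        m[t_start >= policy.time_to_entry + 1.0] = policy.chemical_factor_after
    return PriceSchedule(
        prices=unit_price * m, multipliers=m, cycle_years=cycle_years, policy=policy
    )
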