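"""Decision-tree-linked semi-Markov cohort model for one treatment arm.

A cohort of moderate-to-severe atopic-dermatitis patients aged 38 enters a
16-week decision-tree phase (cycle 0). At its end, week-16 EASI-75 response
is ascertained: in the dupilumab arm responders enter dupilumab maintenance
("response") and everyone else enters supportive-care treatment
("no_response"); in the SC arm responders enter an SC-response state that
relapses to no_response at a per-cycle rate. From cycle 1 onward, dupilumab
responders discontinue at a rate converted from the annual probability, and
every living state faces age-specific background mortality. no_response is
absorbing apart from death; death is absorbing with zero cost and utility.

Within a cycle, costs and QALYs accrue on the cycle-start occupancy (no
half-cycle correction); transitions are applied at the cycle end, with death
and treatment exit acting as independent competing risks (multiplicative
survival). During cycle 0 the whole cohort accrues the no-response utility
and healthcare cost — response status is unknown until week 16 — and the
dupilumab arm accrues a full cycle of drug (one extra 300 mg unit covers the
600 mg loading dose) plus the one-time injection-site-reaction cost.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .eped_pricing import PriceSchedule
from .mortality import LifeTable, annual_to_cycle_prob
from .parameters import ModelParameters

ARMS = ("dupilumab_sc", "sc_only")

_OCC_TOL = 1e-10


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle occupancies and undiscounted accruals for one arm.

    ``occ_response`` is dupilumab maintenance in the dupilumab arm and the
    SC-response state in the SC arm; ``occ_initial`` is the decision-tree
    phase and is non-zero only in cycle 0.
    """

    arm: str
    time_years: np.ndarray
    age: np.ndarray
    occ_initial: np.ndarray
    occ_response: np.ndarray
    occ_noresponse: np.ndarray
    occ_dead: np.ndarray
    drug_units: np.ndarray
    drug_cost: np.ndarray
    healthcare_cost: np.ndarray
    ae_cost: np.ndarray
    qaly: np.ndarray

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"arm must be one of {ARMS}")
        occ = self.occ_initial + self.occ_response + self.occ_noresponse + self.occ_dead
        if np.any(np.abs(occ - 1.0) > _OCC_TOL):
            raise AssertionError("state occupancies do not sum to 1")
        for a in (self.occ_initial, self.occ_response, self.occ_noresponse, self.occ_dead):
            if np.any(a < -_OCC_TOL):
                raise AssertionError("negative state occupancy")
        if np.any(np.diff(self.occ_dead) < -_OCC_TOL):
            raise AssertionError("dead occupancy must be non-decreasing")
        if self.arm == "sc_only" and np.any(self.drug_units != 0):
            raise AssertionError("SC arm must dispense no drug")

    @property
    def n_cycles(self) -> int:
        return int(self.time_years.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": np.arange(self.n_cycles),
                "time_years": self.time_years,
                "age": self.age,
                "occ_initial": self.occ_initial,
                "occ_response": self.occ_response,
                "occ_noresponse": self.occ_noresponse,
                "occ_dead": self.occ_dead,
                "drug_units": self.drug_units,
                "drug_cost": self.drug_cost,
                "healthcare_cost": self.healthcare_cost,
                "ae_cost": self.ae_cost,
                "qaly": self.qaly,
            }
        )

    def save_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _arm_inputs(params: ModelParameters, arm: str):
    """(response prob, per-cycle exit prob from response, response utility,
    no-response utility) for one arm."""
    if arm == "dupilumab_sc":
        exit_prob = annual_to_cycle_prob(params.p_discontinue_annual, params.cycle_years)
        return (
            params.p_response_dup,
            exit_prob,
            params.utility_dup_response,
            params.utility_dup_noresponse,
        )
    return (
        params.p_response_sc,
        params.p_relapse_cycle,
        params.utility_sc_response,
        params.utility_sc_noresponse,
    )


def run_decision_tree(
    params: ModelParameters, arm: str, lifetable: LifeTable | None = None
) -> dict[str, float]:
    """State distribution entering cycle 1, after the 16-week decision tree.

    Survivors of one cycle of background mortality (none if ``lifetable`` is
    omitted) split by the arm's week-16 response probability into the
    response and no_response states.
    """
    if arm not in ARMS:
        raise ValueError(f"arm must be one of {ARMS}")
    p_resp = _arm_inputs(params, arm)[0]
    if lifetable is None:
        q = 0.0
    else:
        from .mortality import cycle_death_prob

        q = cycle_death_prob(lifetable, params.start_age, params.cycle_years)
    alive = 1.0 - q
    return {
        "response": alive * p_resp,
        "no_response": alive * (1.0 - p_resp),
        "dead": q,
    }


def run_cohort(
    params: ModelParameters,
    arm: str,
    schedule: PriceSchedule,
    lifetable: LifeTable,
) -> CohortTrace:
    """Run the cohort over the full horizon and return its trace.

    ``schedule`` must cover at least ``params.n_cycles`` cycles; only the
    dupilumab arm draws on it (the comparator has no drug cost).
    """
    if arm not in ARMS:
        raise ValueError(f"arm must be one of {ARMS}")
    n = params.n_cycles
    if n < 1:
        raise ValueError("horizon must contain at least one cycle")
    if len(schedule) < n:
        raise ValueError(f"price schedule covers {len(schedule)} < {n} cycles")
    cy = params.cycle_years
    p_resp, p_exit, u_resp, u_noresp = _arm_inputs(params, arm)

    time = np.arange(n) * cy
    age = params.start_age + time

    # annual death prob by the integer age at each cycle start -> cycle prob
    lt_start = int(lifetable.ages[0])
    idx = np.clip(np.floor(age).astype(int) - lt_start, 0, lifetable.qx.size - 1)
    over = np.floor(age).astype(int) >= lifetable.terminal_age
    q_annual = np.where(over, 1.0, lifetable.qx[idx])
    if np.floor(age[0]) < lt_start:
        raise ValueError("cohort start age below life-table range")
    q_cycle = 1.0 - (1.0 - q_annual) ** cy  # death during cycle t

    # survival to the start of cycle t: alive_0 = 1, alive_{t+1} = alive_t (1 - q_t)
    alive = np.concatenate([[1.0], np.cumprod(1.0 - q_cycle[:-1])])

    # response-state occupancy: entered at cycle 1 by the week-16 split, then
    # decays by the per-cycle exit probability (discontinuation or relapse)
    # alongside mortality: resp_t = alive_t * p_resp * (1 - p_exit)^(t-1)
    occ_initial = np.zeros(n)
    occ_initial[0] = 1.0
    occ_response = np.zeros(n)
    if n > 1:
        t_idx = np.arange(1, n)
        occ_response[1:] = alive[1:] * p_resp * (1.0 - p_exit) ** (t_idx - 1)
    occ_noresponse = alive - occ_initial - occ_response
    occ_dead = 1.0 - alive

    # --- accruals (undiscounted), on cycle-start occupancy ---
    units_per_cycle = params.doses_per_year * cy
    drug_units = np.zeros(n)
    if arm == "dupilumab_sc":
        drug_units[0] = units_per_cycle + params.loading_extra_units
        drug_units[1:] = occ_response[1:] * units_per_cycle
    drug_cost = drug_units * schedule.prices[:n]

    healthcare_cost = (
        occ_initial * params.cost_cycle_noresponse
        + occ_response * params.cost_cycle_response
        + occ_noresponse * params.cost_cycle_noresponse
    )

    qaly = (
        occ_initial * u_noresp + occ_response * u_resp + occ_noresponse * u_noresp
    ) * cy

    # adverse events: one-time injection-site reaction in the decision-tree
    # cycle; conjunctivitis recurs every maintenance cycle, at on-treatment
    # rates for dupilumab responders and supportive-care rates otherwise
    rates_on = params.ae_rates_dup if arm == "dupilumab_sc" else params.ae_rates_sc
    conj_on = sum(
        rates_on[k] * params.ae_annual_costs[k]
        for k in ("allergic_conj", "infectious_conj")
    )
    conj_off = sum(
        params.ae_rates_sc[k] * params.ae_annual_costs[k]
        for k in ("allergic_conj", "infectious_conj")
    )
    ae_cost = (occ_response * conj_on + occ_noresponse * conj_off) * cy
    ae_cost[0] = rates_on["injection_site"] * params.ae_annual_costs["injection_site"]

    return CohortTrace(
        arm=arm,
        time_years=time,
        age=age,
        occ_initial=occ_initial,
        occ_response=occ_response,
        occ_noresponse=occ_noresponse,
        occ_dead=occ_dead,
        drug_units=drug_units,
        drug_cost=drug_cost,
        healthcare_cost=healthcare_cost,
        ae_cost=ae_cost,
        qaly=qaly,
    )
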