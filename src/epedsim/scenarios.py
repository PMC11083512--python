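"""Scenario engine: how the EPED effect shifts under alternative settings.

Each scenario overrides a small set of inputs — the time to generic entry,
the chemical vs biologic cut, the discount rate, the time horizon, or the
response criterion — and reports the pre- and post-EPED ICER, the absolute
and percentage ICER change, and (optionally) the change in acceptability at
the 1-GDP willingness-to-pay threshold from a PSA.

Shorter horizons are hard truncations of the cycle loop with no terminal-
state valuation. The relaxed EASI-50 response criterion is supported only
when its week-16 response probabilities are supplied explicitly: they come
from trial data, not from any default, and omitting them is an error.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import pandas as pd

from .eped_pricing import NO_POLICY, PolicyConfig
from .mortality import LifeTable
from .parameters import WTP_THRESHOLDS, ModelParameters


class MissingScenarioInputError(ValueError):
    """A scenario needs an input that must be supplied explicitly."""


@dataclass(frozen=True)
class Scenario:
    """Named bundle of parameter and policy overrides."""

    name: str
    param_overrides: dict[str, Any] = field(default_factory=dict)
    policy_overrides: dict[str, Any] = field(default_factory=dict)
    requires: tuple[str, ...] = ()  # parameter overrides that must be present

    def resolve(
        self, base_params: ModelParameters, base_policy: PolicyConfig
    ) -> tuple[ModelParameters, PolicyConfig]:
        missing = [k for k in self.requires if k not in self.param_overrides]
        if missing:
            raise MissingScenarioInputError(
                f"scenario {self.name!r} needs explicit value(s) for {missing}; "
                "supply them in the scenario/config (they have no default)"
            )
        params = base_params.replace(**self.param_overrides) if self.param_overrides else base_params
        policy = (
            dataclasses.replace(base_policy, **self.policy_overrides)
            if self.policy_overrides
            else base_policy
        )
        return params, policy


def default_scenarios(
    easi50_p_response_dup: float | None = None,
    easi50_p_response_sc: float | None = None,
) -> list[Scenario]:
    """The standard scenario grid: entry at 5/7/12 years, a chemical-type
    cut, 30- and 20-year horizons, a 3% discount rate, and — when its
    response probabilities are supplied — the EASI-50 criterion."""
    scenarios = [
        Scenario("base_10.3y_biologic"),
        Scenario("time_to_eped_5y", policy_overrides={"time_to_entry": 5.0}),
        Scenario("time_to_eped_7y", policy_overrides={"time_to_entry": 7.0}),
        Scenario("time_to_eped_12y", policy_overrides={"time_to_entry": 12.0}),
        Scenario("chemical_based", policy_overrides={"policy_kind": "chemical"}),
        Scenario("horizon_30y", param_overrides={"horizon_years": 30.0}),
        Scenario("horizon_20y", param_overrides={"horizon_years": 20.0}),
        Scenario("discount_3pct", param_overrides={"discount_annual": 0.03}),
    ]
    easi50_overrides: dict[str, Any] = {}
    if easi50_p_response_dup is not None:
        easi50_overrides["p_response_dup"] = easi50_p_response_dup
    if easi50_p_response_sc is not None:
        easi50_overrides["p_response_sc"] = easi50_p_response_sc
    scenarios.append(
        Scenario(
            "easi50_response",
            param_overrides=easi50_overrides,
            requires=("p_response_dup", "p_response_sc"),
        )
    )
    return scenarios


def run_scenarios(
    base_params: ModelParameters,
    scenarios: list[Scenario],
    lifetable: LifeTable,
    base_policy: PolicyConfig | None = None,
    psa_draws: int = 0,
    seed: int = 0,
    skip_missing: bool = False,
) -> pd.DataFrame:
    """Evaluate every scenario; one row per scenario.

    With ``psa_draws`` > 0 each row also carries pre/post acceptability at
    the 1-GDP threshold. ``skip_missing`` drops scenarios whose required
    inputs were not supplied instead of raising.
    """
    from .economics import evaluate
    from .psa import run_psa

    if not scenarios:
        raise ValueError("scenario list must be non-empty")
    if base_policy is None:
        base_policy = PolicyConfig(policy_kind="biologic")
    wtp_1gdp = WTP_THRESHOLDS["1gdp"]
    rows = []
    for sc in scenarios:
        try:
            params, policy = sc.resolve(base_params, base_policy)
        except MissingScenarioInputError:
            if skip_missing:
                continue
            raise
        pre = evaluate(params, NO_POLICY, lifetable)
        post = evaluate(params, policy, lifetable)
        row: dict[str, Any] = {
            "scenario": sc.name,
            "pre_eped_icer": pre.icer,
            "post_eped_icer": post.icer,
            "icer_change": post.icer - pre.icer,
            "icer_change_pct": 100.0 * (post.icer - pre.icer) / pre.icer,
        }
        if psa_draws > 0:
            psa = run_psa(params, policy, lifetable, n_draws=psa_draws, seed=seed)
            row["acceptability_pre"] = 100.0 * psa.acceptability_at(wtp_1gdp, "pre")
            row["acceptability_post"] = 100.0 * psa.acceptability_at(wtp_1gdp, "post")
            row["acceptability_change"] = row["acceptability_post"] - row["acceptability_pre"]
        rows.append(row)
    return pd.DataFrame(rows)
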