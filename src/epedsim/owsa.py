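"""One-way sensitivity analysis (tornado diagram).

Each distributed input is moved in turn to the 2.5th and 97.5th percentile
of its sampling distribution — a 95% interval — with everything else at the
base case, and the model outcome is recomputed at both ends. The default
outcome is the change in the ICER induced by the EPED price cut (post-EPED
ICER minus pre-EPED ICER); the plain post-EPED ICER is available as an
alternative target. Bars are sorted by descending width, ties broken
alphabetically by parameter name.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .eped_pricing import NO_POLICY, PolicyConfig
from .mortality import LifeTable
from .parameters import ModelParameters

OUTCOME_TARGETS = ("icer_change", "icer")


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low_input: float
    high_input: float
    outcome_low: float
    outcome_high: float
    clamped: bool = False  # a percentile fell outside the valid range

    @property
    def width(self) -> float:
        return abs(self.outcome_high - self.outcome_low)


def _outcome(
    params: ModelParameters,
    policy: PolicyConfig,
    lifetable: LifeTable,
    target: str,
) -> float:
    from .economics import evaluate

    post = evaluate(params, policy, lifetable).icer
    if target == "icer":
        return post
    pre = evaluate(params, NO_POLICY, lifetable).icer
    return post - pre


def run_owsa(
    params: ModelParameters,
    policy: PolicyConfig,
    lifetable: LifeTable,
    target: str = "icer_change",
) -> list[TornadoEntry]:
    """Tornado entries for every input with a non-degenerate distribution
    registry entry (degenerate inputs yield zero-width bars)."""
    if target not in OUTCOME_TARGETS:
        raise ValueError(f"target must be one of {OUTCOME_TARGETS}")
    entries: list[TornadoEntry] = []
    is_utility = lambda name: name.startswith("utility")
    for name, spec in params.distributions.items():
        lo_in, hi_in = spec.ppf(0.025, truncate=False), spec.ppf(0.975, truncate=False)
        clamped = False
        if is_utility(name):
            # utilities outside [0, 1] are invalid; clamp and flag
            for bound in (lo_in, hi_in):
                if not 0.0 <= bound <= 1.0:
                    clamped = True
            lo_in = min(max(lo_in, 0.0), 1.0)
            hi_in = min(max(hi_in, 0.0), 1.0)
        out_lo = _outcome(params.replace(**{name: lo_in}), policy, lifetable, target)
        out_hi = _outcome(params.replace(**{name: hi_in}), policy, lifetable, target)
        entries.append(
            TornadoEntry(
                parameter=name,
                low_input=lo_in,
                high_input=hi_in,
                outcome_low=out_lo,
                outcome_high=out_hi,
                clamped=clamped,
            )
        )
    entries.sort(key=lambda e: (-e.width, e.parameter))
    return entries


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": [e.parameter for e in entries],
            "low_input": [e.low_input for e in entries],
            "high_input": [e.high_input for e in entries],
            "outcome_low": [e.outcome_low for e in entries],
            "outcome_high": [e.outcome_high for e in entries],
            "width": [e.width for e in entries],
            "clamped": [e.clamped for e in entries],
        }
    )
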