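"""Probabilistic sensitivity analysis.

Each Monte Carlo draw replaces every input that carries a distribution
(Beta by event counts for probabilities, Gamma by mean/SE for costs and
utilities, utilities truncated to [0, 1]); the unit price, dosing, discount
rate and time structure are decision quantities and stay fixed. Both policy
settings (no EPED, EPED) are evaluated on the *same* sampled parameter set
— common random numbers — which matches a paired cost-effectiveness scatter
and sharpens the estimated acceptability change; an unpaired variant is
available. The cost-effectiveness acceptability curve (CEAC) reports, per
willingness-to-pay value w, the fraction of draws with positive net
monetary benefit w*dQ - dC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .eped_pricing import NO_POLICY, PolicyConfig
from .mortality import LifeTable
from .parameters import WTP_THRESHOLDS, ModelParameters

#: default CEAC grid: 0..100M KRW in 1M steps, with the named thresholds
#: inserted exactly.
def default_wtp_grid() -> np.ndarray:
    grid = np.arange(0.0, 100_000_001.0, 1_000_000.0)
    return np.unique(np.concatenate([grid, list(WTP_THRESHOLDS.values())]))


def sample(params: ModelParameters, rng: np.random.Generator) -> ModelParameters:
    """One parameter-set draw from the attached distribution registry."""
    draws = {name: spec.sample(rng) for name, spec in params.distributions.items()}
    return params.replace(**draws)


@dataclass
class PSAOutput:
    """Per-draw incremental results plus the acceptability summaries."""

    draws: pd.DataFrame  # columns: draw, dc_pre, dq_pre, dc_post, dq_post
    wtp_grid: np.ndarray
    ceac_pre: np.ndarray
    ceac_post: np.ndarray
    seed: int
    paired: bool
    acceptability: dict[str, dict[str, float]] = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return len(self.draws)

    def acceptability_at(self, wtp: float, policy: str = "post") -> float:
        dc = self.draws[f"dc_{policy}"].to_numpy()
        dq = self.draws[f"dq_{policy}"].to_numpy()
        return float(np.mean(wtp * dq - dc > 0.0))

    def ceac_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "wtp": self.wtp_grid,
                "p_cost_effective_pre_eped": self.ceac_pre,
                "p_cost_effective_post_eped": self.ceac_post,
            }
        )

    def save_csv(self, scatter_path: str | Path, ceac_path: str | Path) -> None:
        self.draws.to_csv(scatter_path, index=False)
        self.ceac_frame().to_csv(ceac_path, index=False)


def _ceac(dc: np.ndarray, dq: np.ndarray, grid: np.ndarray) -> np.ndarray:
    nmb = grid[None, :] * dq[:, None] - dc[:, None]
    return (nmb > 0.0).mean(axis=0)


def run_psa(
    params: ModelParameters,
    policy: PolicyConfig,
    lifetable: LifeTable,
    n_draws: int = 1000,
    seed: int = 0,
    paired: bool = True,
    wtp_grid: np.ndarray | None = None,
) -> PSAOutput:
    """Monte Carlo PSA of the no-EPED vs EPED policy pair.

    With ``paired`` (default) each draw's parameter set is shared between
    the two policy evaluations; otherwise the post-EPED column uses an
    independent stream of draws.
    """
    from .cohort_model import run_cohort
    from .economics import evaluate
    from .eped_pricing import build_schedule

    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if wtp_grid is None:
        wtp_grid = default_wtp_grid()
    rng = np.random.default_rng(seed)
    rng_post = np.random.default_rng(seed + 1) if not paired else None

    records = []
    for i in range(n_draws):
        p = sample(params, rng)
        schedule = build_schedule(NO_POLICY, p.unit_price, p.n_cycles, p.cycle_years)
        sc_trace = run_cohort(p, "sc_only", schedule, lifetable)
        pre = evaluate(p, NO_POLICY, lifetable, comparator_trace=sc_trace)
        if paired:
            post = evaluate(p, policy, lifetable, comparator_trace=sc_trace)
        else:
            p2 = sample(params, rng_post)
            post = evaluate(p2, policy, lifetable)
        records.append(
            {
                "draw": i,
                "dc_pre": pre.incremental_cost,
                "dq_pre": pre.incremental_qaly,
                "dc_post": post.incremental_cost,
                "dq_post": post.incremental_qaly,
            }
        )
    draws = pd.DataFrame.from_records(records)

    ceac_pre = _ceac(draws["dc_pre"].to_numpy(), draws["dq_pre"].to_numpy(), wtp_grid)
    ceac_post = _ceac(draws["dc_post"].to_numpy(), draws["dq_post"].to_numpy(), wtp_grid)
    out = PSAOutput(
        draws=draws,
        wtp_grid=wtp_grid,
        ceac_pre=ceac_pre,
        ceac_post=ceac_post,
        seed=seed,
        paired=paired,
    )
    out.acceptability = {
        policy_label: {
            name: out.acceptability_at(wtp, policy_label)
            for name, wtp in WTP_THRESHOLDS.items()
        }
        for policy_label in ("pre", "post")
    }
    return out
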