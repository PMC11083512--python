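"""Model inputs for the dupilumab-vs-supportive-care cost-utility model.

All monetary amounts are 2021 Korean won (KRW). Probabilities that refer to a
"cycle" are per 4-month (16-week) model cycle unless the field name says
annual. Each uncertain input carries a :class:`DistributionSpec` used by the
probabilistic sensitivity analysis: Beta distributions parameterised by event
counts for probabilities, Gamma distributions parameterised by mean and
standard error for costs and utilities (utilities are truncated to [0, 1] at
sampling time).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

AE_KINDS = ("injection_site", "allergic_conj", "infectious_conj")

#: 2021 Korean willingness-to-pay thresholds (KRW per QALY): 1 GDP per capita
#: and the HIRA-accepted medians by drug class.
WTP_THRESHOLDS: dict[str, float] = {
    "1gdp": 40_052_159.0,
    "anticancer": 45_320_000.0,
    "rare_disease": 38_400_000.0,
    "general": 17_170_000.0,
}


@dataclass(frozen=True)
class DistributionSpec:
    """Sampling distribution of one model input.

    ``kind`` is one of ``beta`` (event counts ``alpha``/``beta``), ``gamma``
    (natural-scale ``mean``/``se``; shape = mean^2/SE^2, scale = SE^2/mean)
    or ``fixed`` (degenerate at ``mean``).
    """

    kind: str
    alpha: float | None = None
    beta: float | None = None
    mean: float | None = None
    se: float | None = None
    truncate_unit: bool = False  # clip draws to [0, 1] (utilities)

    def __post_init__(self) -> None:
        if self.kind not in ("beta", "gamma", "fixed"):
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        if self.kind == "beta":
            if self.alpha is None or self.beta is None or self.alpha <= 0 or self.beta <= 0:
                raise ValueError("beta distribution needs alpha>0 and beta>0")
        if self.kind == "gamma":
            if self.mean is None or self.se is None or self.mean <= 0 or self.se <= 0:
                raise ValueError("gamma distribution needs mean>0 and se>0")

    @property
    def implied_mean(self) -> float:
        if self.kind == "beta":
            return self.alpha / (self.alpha + self.beta)
        return float(self.mean)

    def gamma_shape_scale(self) -> tuple[float, float]:
        if self.kind != "gamma":
            raise ValueError("not a gamma distribution")
        shape = self.mean**2 / self.se**2
        scale = self.se**2 / self.mean
        return shape, scale

    def ppf(self, q: float, truncate: bool = True) -> float:
        """Quantile of the distribution (used by the one-way SA); pass
        ``truncate=False`` for the raw, un-clipped quantile."""
        from scipy import stats

        if self.kind == "fixed":
            return float(self.mean)
        if self.kind == "beta":
            return float(stats.beta.ppf(q, self.alpha, self.beta))
        shape, scale = self.gamma_shape_scale()
        x = float(stats.gamma.ppf(q, shape, scale=scale))
        if truncate and self.truncate_unit:
            x = min(max(x, 0.0), 1.0)
        return x

    def sample(self, rng) -> float:
        if self.kind == "fixed":
            return float(self.mean)
        if self.kind == "beta":
            return float(rng.beta(self.alpha, self.beta))
        shape, scale = self.gamma_shape_scale()
        x = float(rng.gamma(shape, scale))
        if self.truncate_unit:
            x = min(max(x, 0.0), 1.0)
        return x


@dataclass
class ModelParameters:
    """Every behavioural input of the cost-utility model (base case: Table-of-
    record values for the Korean setting).

    Cohort metadata (``frac_male``, ``frac_severe``) is descriptive only:
    mortality is unisex and disease severity enters solely through the two
    per-cycle healthcare-cost levels.
    """

    # week-16 treatment response (EASI-75)
    p_response_dup: float = 0.477
    p_response_sc: float = 0.133
    # exits from the response states
    p_discontinue_annual: float = 0.063
    p_relapse_cycle: float = 0.367
    # adverse events, per 16-week period
    ae_rates_dup: dict[str, float] = field(
        default_factory=lambda: {
            "injection_site": 0.110,
            "allergic_conj": 0.030,
            "infectious_conj": 0.043,
        }
    )
    ae_rates_sc: dict[str, float] = field(
        default_factory=lambda: {
            "injection_site": 0.0,
            "allergic_conj": 0.009,
            "infectious_conj": 0.007,
        }
    )
    ae_annual_costs: dict[str, float] = field(
        default_factory=lambda: {
            "injection_site": 39_512.0,
            "allergic_conj": 25_129.0,
            "infectious_conj": 22_524.0,
        }
    )
    # healthcare cost per 4-month cycle by state (KRW)
    cost_cycle_noresponse: float = 1_058_567.0
    cost_cycle_response: float = 522_041.0
    # EQ-5D utilities by arm and state
    utility_dup_noresponse: float = 0.63
    utility_dup_response: float = 0.89
    utility_sc_noresponse: float = 0.61
    utility_sc_response: float = 0.86
    # dupilumab dosing and price (300 mg units)
    unit_price: float = 710_000.0
    doses_per_year: float = 26.0
    loading_extra_units: float = 1.0
    # cohort and time structure
    start_age: float = 38.0
    horizon_years: float = 63.0
    cycle_years: float = 1.0 / 3.0
    discount_annual: float = 0.045
    # descriptive cohort metadata (not a model dimension)
    frac_male: float = 0.54
    frac_severe: float = 0.48
    # PSA distribution registry, keyed by (possibly dotted) field name
    distributions: dict[str, DistributionSpec] = field(default_factory=dict)

    # -- accessors -------------------------------------------------------

    @property
    def n_cycles(self) -> int:
        n = self.horizon_years / self.cycle_years
        return int(round(n))

    def get(self, name: str) -> float:
        """Read a scalar parameter, supporting dotted map keys
        (``ae_rates_dup.allergic_conj``)."""
        if "." in name:
            head, key = name.split(".", 1)
            return getattr(self, head)[key]
        return getattr(self, name)

    def replace(self, **overrides: Any) -> "ModelParameters":
        """Copy with flat or dotted overrides applied."""
        new = dataclasses.replace(self)
        new.ae_rates_dup = dict(self.ae_rates_dup)
        new.ae_rates_sc = dict(self.ae_rates_sc)
        new.ae_annual_costs = dict(self.ae_annual_costs)
        new.distributions = dict(self.distributions)
        for name, value in overrides.items():
            if "." in name:
                head, key = name.split(".", 1)
                getattr(new, head)[key] = value
            elif hasattr(new, name):
                setattr(new, name, value)
            else:
                raise KeyError(f"unknown parameter {name!r}")
        return new

    # -- serialisation ---------------------------------------------------

    _SCALAR_FIELDS = (
        "p_response_dup",
        "p_response_sc",
        "p_discontinue_annual",
        "p_relapse_cycle",
        "cost_cycle_noresponse",
        "cost_cycle_response",
        "utility_dup_noresponse",
        "utility_dup_response",
        "utility_sc_noresponse",
        "utility_sc_response",
        "unit_price",
        "doses_per_year",
        "loading_extra_units",
        "start_age",
        "horizon_years",
        "cycle_years",
        "discount_annual",
        "frac_male",
        "frac_severe",
    )

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {f: getattr(self, f) for f in self._SCALAR_FIELDS}
        out["ae_rates_dup"] = dict(self.ae_rates_dup)
        out["ae_rates_sc"] = dict(self.ae_rates_sc)
        out["ae_annual_costs"] = dict(self.ae_annual_costs)
        return out

    def save_config(self, path: str | Path) -> None:
        path = Path(path)
        data = self.to_dict()
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(data, sort_keys=True))
        else:
            path.write_text(json.dumps(data, indent=2, sort_keys=True))


def _base_distributions() -> dict[str, DistributionSpec]:
    beta = lambda a, b: DistributionSpec("beta", alpha=a, beta=b)
    gamma = lambda m, s: DistributionSpec("gamma", mean=m, se=s)
    util = lambda m, s: DistributionSpec("gamma", mean=m, se=s, truncate_unit=True)
    d = {
        "p_response_dup": beta(218, 239),
        "p_response_sc": beta(61, 399),
        "p_discontinue_annual": beta(24, 357),
        "p_relapse_cycle": beta(40, 69),
        "ae_rates_dup.injection_site": beta(51, 414),
        "ae_rates_dup.allergic_conj": beta(14, 451),
        "ae_rates_dup.infectious_conj": beta(20, 445),
        "ae_rates_sc.injection_site": DistributionSpec("fixed", mean=0.0),
        "ae_rates_sc.allergic_conj": beta(4, 452),
        "ae_rates_sc.infectious_conj": beta(3, 453),
        "cost_cycle_noresponse": gamma(1_058_567.0, 395_690.0),
        "cost_cycle_response": gamma(522_041.0, 135_946.0),
        "utility_dup_noresponse": util(0.63, 0.015),
        "utility_dup_response": util(0.89, 0.024),
        "utility_sc_noresponse": util(0.61, 0.016),
        "utility_sc_response": util(0.86, 0.046),
    }
    # adverse-event treatment costs: SE assumed 10% of the mean
    for kind, mean in (
        ("injection_site", 39_512.0),
        ("allergic_conj", 25_129.0),
        ("infectious_conj", 22_524.0),
    ):
        d[f"ae_annual_costs.{kind}"] = gamma(mean, 0.10 * mean)
    return d


def base_case() -> ModelParameters:
    """The published base case with its full PSA distribution registry.

    Unit price, dosing, discount rate and time structure are decision /
    design quantities and carry no sampling distribution.
    """
    return ModelParameters(distributions=_base_distributions())


def load_config(path: str | Path, base: ModelParameters | None = None) -> ModelParameters:
    """Read a YAML/JSON config of flat keys; any subset overrides the base
    case. Map-valued fields may be given whole or via dotted keys."""
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping of parameter names")
    params = base if base is not None else base_case()
    flat: dict[str, Any] = {}
    for key, value in data.items():
        if isinstance(value, dict):
            for sub, v in value.items():
                flat[f"{key}.{sub}"] = v
        else:
            flat[key] = value
    return params.replace(**flat)


def validate(params: ModelParameters) -> list[str]:
    """Check every type invariant; returns a human-readable violation list
    (empty iff valid). Reporting, not raising."""
    v: list[str] = []

    def prob(name: str) -> None:
        x = params.get(name)
        if not (0.0 <= x <= 1.0):
            v.append(f"{name}: probability {x} outside [0, 1]")

    def nonneg(name: str) -> None:
        if params.get(name) < 0:
            v.append(f"{name}: cost {params.get(name)} is negative")

    for name in ("p_response_dup", "p_response_sc", "p_discontinue_annual", "p_relapse_cycle"):
        prob(name)
    for arm in ("ae_rates_dup", "ae_rates_sc"):
        for kind in AE_KINDS:
            prob(f"{arm}.{kind}")
    for name in ("cost_cycle_noresponse", "cost_cycle_response", "unit_price"):
        nonneg(name)
    for kind in AE_KINDS:
        nonneg(f"ae_annual_costs.{kind}")
    for name in (
        "utility_dup_noresponse",
        "utility_dup_response",
        "utility_sc_noresponse",
        "utility_sc_response",
    ):
        x = params.get(name)
        if not (0.0 <= x <= 1.0):
            v.append(f"{name}: utility {x} outside [0, 1]")
    if params.cycle_years <= 0:
        v.append(f"cycle_years: {params.cycle_years} must be positive")
    else:
        n = params.horizon_years / params.cycle_years
        if params.horizon_years <= 0 or abs(n - round(n)) > 1e-9 or round(n) < 1:
            v.append(
                f"horizon_years: {params.horizon_years} is not a positive integer "
                f"multiple of cycle_years {params.cycle_years}"
            )
    if params.discount_annual <= -1:
        v.append(f"discount_annual: {params.discount_annual} must exceed -1")
    if params.doses_per_year < 0 or params.loading_extra_units < 0:
        v.append("dosing: doses_per_year and loading_extra_units must be >= 0")
    for name, spec in params.distributions.items():
        if spec.kind == "beta":
            try:
                target = params.get(name)
            except (AttributeError, KeyError):
                v.append(f"distributions[{name}]: no matching parameter field")
                continue
            if not math.isclose(spec.implied_mean, target, abs_tol=0.01):
                v.append(
                    f"distributions[{name}]: beta mean {spec.implied_mean:.4f} "
                    f"differs from base value {target} by more than 0.01"
                )
    return v
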