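import numpy as np
import pytest

from epedsim import LifeTable, PolicyConfig, base_case, synthetic_lifetable


@pytest.fixture(scope="session")
def params():
    return base_case()


@pytest.fixture(scope="session")
def lifetable():
    return synthetic_lifetable()


@pytest.fixture(scope="session")
def policy():
    return PolicyConfig(policy_kind="biologic", time_to_entry=10.3)


@pytest.fixture(scope="session")
def zero_mortality():
    """Life table with no death before the terminal age 110."""
    ages = np.arange(0, 111)
    qx = np.zeros(111)
    qx[-1] = 1.0
    return LifeTable(ages=ages, qx=qx)


@pytest.fixture()
def symmetric_params(params):
    """Arms made indistinguishable: equal response, utilities, exit rates,
    adverse events, and a free drug."""
    from epedsim import annual_to_cycle_prob

    relapse = annual_to_cycle_prob(params.p_discontinue_annual, params.cycle_years)
    return params.replace(
        p_response_sc=params.p_response_dup,
        p_relapse_cycle=relapse,
        utility_sc_response=params.utility_dup_response,
        utility_sc_noresponse=params.utility_dup_noresponse,
        unit_price=0.0,
        **{f"ae_rates_sc.{k}": v for k, v in params.ae_rates_dup.items()},
    )
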