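import numpy as np
import pytest

from epedsim import (
    NO_POLICY,
    PolicyConfig,
    build_schedule,
    run_cohort,
    run_decision_tree,
)


def _schedule(params, policy=NO_POLICY):
    return build_schedule(policy, params.unit_price, params.n_cycles, params.cycle_years)


def test_decision_tree_split_dupilumab(params):
    dist = run_decision_tree(params, "dupilumab_sc")
    assert dist["response"] == pytest.approx(0.477)
    assert dist["no_response"] == pytest.approx(0.523)
    assert dist["dead"] == 0.0


def test_decision_tree_split_sc(params):
    dist = run_decision_tree(params, "sc_only")
    assert dist["response"] == pytest.approx(0.133)


def test_decision_tree_zero_response(params):
    dist = run_decision_tree(params.replace(p_response_dup=0.0), "dupilumab_sc")
    assert dist["response"] == 0.0
    assert dist["no_response"] == pytest.approx(1.0)


def test_decision_tree_applies_one_cycle_of_mortality(params, lifetable):
    dist = run_decision_tree(params, "dupilumab_sc", lifetable)
    q = 1 - (1 - lifetable.q_annual(38)) ** params.cycle_years
    assert dist["dead"] == pytest.approx(q)
    assert dist["response"] == pytest.approx(0.477 * (1 - q))


@pytest.mark.parametrize("arm", ["dupilumab_sc", "sc_only"])
def test_occupancy_conservation_and_dead_monotone(params, lifetable, arm):
    trace = run_cohort(params, arm, _schedule(params), lifetable)
    total = trace.occ_initial + trace.occ_response + trace.occ_noresponse + trace.occ_dead
    assert np.allclose(total, 1.0, atol=1e-10)
    assert np.all(np.diff(trace.occ_dead) >= -1e-12)


def test_sc_arm_never_dispenses_drug(params, lifetable):
    trace = run_cohort(params, "sc_only", _schedule(params), lifetable)
    assert np.all(trace.drug_units == 0)
    assert np.all(trace.drug_cost == 0)


def test_sc_arm_closed_form_qaly_no_mortality_no_relapse(params, zero_mortality):
    """With relapse and mortality off, SC occupancy is frozen after week 16,
    so every maintenance cycle's QALY has a closed form."""
    p = params.replace(p_relapse_cycle=0.0)
    trace = run_cohort(p, "sc_only", _schedule(p), zero_mortality)
    expected = (0.133 * 0.86 + 0.867 * 0.61) / 3
    assert np.allclose(trace.qaly[1:], expected)
    assert trace.qaly[0] == pytest.approx(0.61 / 3)


def test_dup_response_constant_without_exits(params, zero_mortality):
    p = params.replace(p_discontinue_annual=0.0)
    trace = run_cohort(p, "dupilumab_sc", _schedule(p), zero_mortality)
    assert np.allclose(trace.occ_response[1:], 0.477)


def test_total_qaly_equals_horizon_without_decrements(params, zero_mortality):
    p = params.replace(
        p_discontinue_annual=0.0,
        p_relapse_cycle=0.0,
        utility_dup_response=1.0,
        utility_dup_noresponse=1.0,
    )
    trace = run_cohort(p, "dupilumab_sc", _schedule(p), zero_mortality)
    assert trace.qaly.sum() == pytest.approx(p.horizon_years)


def test_sc_trace_invariant_to_price_schedule(params, lifetable):
    cut = build_schedule(
        PolicyConfig(policy_kind="chemical", time_to_entry=2.0),
        params.unit_price,
        params.n_cycles,
        params.cycle_years,
    )
    a = run_cohort(params, "sc_only", _schedule(params), lifetable)
    b = run_cohort(params, "sc_only", cut, lifetable)
    for name in ("occ_response", "occ_noresponse", "healthcare_cost", "ae_cost", "qaly"):
        assert np.array_equal(getattr(a, name), getattr(b, name))


def test_arm_symmetry(symmetric_params, lifetable):
    """With equal response, exits, utilities and adverse events, and a free
    drug, the two arms are clinically and economically identical."""
    sched = _schedule(symmetric_params)
    dup = run_cohort(symmetric_params, "dupilumab_sc", sched, lifetable)
    sc = run_cohort(symmetric_params, "sc_only", sched, lifetable)
    for name in (
        "occ_initial",
        "occ_response",
        "occ_noresponse",
        "occ_dead",
        "healthcare_cost",
        "ae_cost",
        "qaly",
        "drug_cost",  # unit price is zero
    ):
        assert np.allclose(getattr(dup, name), getattr(sc, name), atol=1e-12), name


def test_cycle0_accruals(params, lifetable):
    trace = run_cohort(params, "dupilumab_sc", _schedule(params), lifetable)
    # whole cohort on drug for the 16-week decision tree, +1 unit of loading
    assert trace.drug_units[0] == pytest.approx(26 / 3 + 1)
    assert trace.healthcare_cost[0] == pytest.approx(params.cost_cycle_noresponse)
    assert trace.qaly[0] == pytest.approx(0.63 / 3)
    # one-time injection-site reaction cost
    assert trace.ae_cost[0] == pytest.approx(0.110 * 39_512.0)


def test_short_schedule_rejected(params, lifetable):
    short = build_schedule(NO_POLICY, params.unit_price, 10, params.cycle_years)
    with pytest.raises(ValueError):
        run_cohort(params, "dupilumab_sc", short, lifetable)


def test_unknown_arm_rejected(params, lifetable):
    with pytest.raises(ValueError):
        run_cohort(params, "placebo", _schedule(params), lifetable)


def test_trace_export_columns(tmp_path, params, lifetable):
    trace = run_cohort(params, "dupilumab_sc", _schedule(params), lifetable)
    path = tmp_path / "trace.csv"
    trace.save_csv(path)
    header = path.read_text().splitlines()[0].split(",")
    assert {"cycle", "occ_response", "drug_units", "qaly"} <= set(header)
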