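import numpy as np
import pytest

from epedsim import (
    NO_POLICY,
    DegenerateComparisonError,
    PolicyConfig,
    WTP_THRESHOLDS,
    annual_drug_cost,
    build_schedule,
    discount_factor,
    evaluate,
    run_cohort,
    value_based_price,
    vbp_table,
)

BIOLOGIC = PolicyConfig(policy_kind="biologic", time_to_entry=10.3)


@pytest.mark.parametrize(
    "t, rate, cy, expected",
    [
        (0, 0.045, 1 / 3, 1.0),
        (3, 0.045, 1 / 3, 1 / 1.045),
        (7, 0.0, 1 / 3, 1.0),
        (6, 0.045, 1 / 3, 1.045**-2),
    ],
)
def test_discount_factor(t, rate, cy, expected):
    assert discount_factor(t, rate, cy) == pytest.approx(expected, rel=1e-12)


def test_discount_factor_rejects_bad_inputs():
    with pytest.raises(ValueError):
        discount_factor(1, -1.5, 1 / 3)
    with pytest.raises(ValueError):
        discount_factor(-1, 0.045, 1 / 3)


def test_annual_drug_cost(params):
    assert annual_drug_cost(params) == pytest.approx(18_460_000)
    assert annual_drug_cost(params.replace(unit_price=0.0)) == 0.0
    assert annual_drug_cost(params.replace(unit_price=497_000.0)) == pytest.approx(12_922_000)


def test_total_cost_decomposition(params, lifetable):
    res = evaluate(params, BIOLOGIC, lifetable)
    for arm in (res.intervention, res.comparator):
        assert arm.total_cost == pytest.approx(arm.drug_cost + arm.other_cost, abs=1.0)


def test_icer_times_dq_equals_dc(params, lifetable):
    res = evaluate(params, NO_POLICY, lifetable)
    assert res.icer * res.incremental_qaly == pytest.approx(res.incremental_cost, rel=1e-9)


def test_drug_cost_is_discounted_units_times_price(params, lifetable):
    """The reported drug cost must equal sum_t units_t * price_t * disc_t,
    recomputed from the raw trace."""
    sched = build_schedule(BIOLOGIC, params.unit_price, params.n_cycles, params.cycle_years)
    trace = run_cohort(params, "dupilumab_sc", sched, lifetable)
    disc = discount_factor(np.arange(trace.n_cycles), params.discount_annual, params.cycle_years)
    expected = float(np.sum(trace.drug_units * sched.prices * disc))
    res = evaluate(params, BIOLOGIC, lifetable)
    assert res.intervention.drug_cost == pytest.approx(expected, rel=1e-12)


def test_icer_affine_in_unit_price(params, lifetable):
    """Incremental cost is affine in the unit price, so results at two
    prices determine the result at any third."""
    p0, p1, p2 = 0.0, 710_000.0, 400_000.0
    r0 = evaluate(params.replace(unit_price=p0), NO_POLICY, lifetable)
    r1 = evaluate(params.replace(unit_price=p1), NO_POLICY, lifetable)
    r2 = evaluate(params.replace(unit_price=p2), NO_POLICY, lifetable)
    w = (p2 - p0) / (p1 - p0)
    predicted_dc = r0.incremental_cost + w * (r1.incremental_cost - r0.incremental_cost)
    assert r2.incremental_cost == pytest.approx(predicted_dc, rel=1e-9)
    assert r2.incremental_qaly == pytest.approx(r1.incremental_qaly, rel=1e-12)


def test_eped_saving_conservation_identity(params, lifetable):
    """Pre-minus-post drug cost equals (1 - factor) * price * discounted
    units dispensed after entry (the shaded savings area)."""
    pre = evaluate(params, NO_POLICY, lifetable)
    post = evaluate(params, BIOLOGIC, lifetable)
    saving = pre.intervention.drug_cost - post.intervention.drug_cost
    expected = 0.30 * params.unit_price * post.intervention.drug_units_after_entry
    assert saving == pytest.approx(expected, rel=1e-12)


def test_icer_monotone_in_entry_time_and_factor(params, lifetable):
    icers = [
        evaluate(params, PolicyConfig(policy_kind="biologic", time_to_entry=t), lifetable).icer
        for t in (3.0, 8.0, 10.3, 20.0)
    ]
    assert icers == sorted(icers)
    deep = PolicyConfig(policy_kind="biologic", biologic_factor=0.5)
    shallow = PolicyConfig(policy_kind="biologic", biologic_factor=0.9)
    assert evaluate(params, deep, lifetable).icer < evaluate(params, shallow, lifetable).icer


def test_vbp_closed_form_agrees_with_bisection(params, lifetable):
    p_star = value_based_price(
        params, NO_POLICY, lifetable, WTP_THRESHOLDS["1gdp"], check_bisection=True
    )
    assert p_star > 0


def test_vbp_fixed_point_at_current_icer(params, lifetable):
    icer = evaluate(params, NO_POLICY, lifetable).icer
    p_star = value_based_price(params, NO_POLICY, lifetable, icer)
    assert p_star == pytest.approx(params.unit_price, abs=1.0)


def test_vbp_ratio_invariant_across_thresholds(params, lifetable):
    """P*_post / P*_pre = U_pre / U_post exactly, whatever the threshold."""
    ratios = []
    for wtp in WTP_THRESHOLDS.values():
        pre = value_based_price(params, NO_POLICY, lifetable, wtp)
        post = value_based_price(params, BIOLOGIC, lifetable, wtp)
        ratios.append(post / pre)
    assert np.allclose(ratios, ratios[0], rtol=1e-12)


def test_vbp_table_structure(params, lifetable):
    df = vbp_table(params, lifetable)
    assert len(df) == len(WTP_THRESHOLDS)
    assert np.allclose(df["pct_change"], df["pct_change"].iloc[0], rtol=1e-9)
    assert np.allclose(
        df["diff_per_year"], df["diff_per_unit"] * params.doses_per_year, rtol=1e-12
    )
    # a threshold equal to the pre-EPED ICER returns the submitted price
    icer = evaluate(params, NO_POLICY, lifetable).icer
    row = vbp_table(params, lifetable, thresholds={"at_icer": icer}).iloc[0]
    assert row["vbp_pre_eped"] == pytest.approx(params.unit_price, abs=1.0)


def test_identical_arms_have_undefined_icer(symmetric_params, lifetable):
    res = evaluate(symmetric_params, NO_POLICY, lifetable)
    assert res.incremental_qaly == pytest.approx(0.0, abs=1e-12)
    assert res.incremental_cost == pytest.approx(0.0, abs=1e-6)
    with pytest.raises(DegenerateComparisonError):
        _ = res.icer


def test_vbp_rejects_nonpositive_wtp(params, lifetable):
    with pytest.raises(ValueError):
        value_based_price(params, NO_POLICY, lifetable, 0.0)
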