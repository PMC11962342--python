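"""Costing: category arithmetic, cumulative integration, perspectives."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import trialcea as t
from trialcea.costing import (
    PERIODS_PER_YEAR,
    CostBreakdown,
    unpaid_productivity_cost,
    wave_cost_frame,
)
from trialcea.schema import UnitCostTable


@pytest.fixture(scope="module")
def uc():
    return UnitCostTable(
        entries={
            "rtms_session": 100.0,
            "psychotherapy_session": 95.0,
            "gp_contact": 33.0,
            "mental_care_contact": 120.0,
            "other_care_contact": 40.0,
            "home_help_hour": 18.0,
            "medication_day": 0.5,
            "travel_trip": 5.0,
            "housekeeping_hour": 18.0,
        }
    )


def test_intervention_cost_bottom_up(uc):
    assert t.intervention_cost({"rtms_sessions": 0, "psychotherapy_sessions": 0}, uc) == 0.0
    total = t.intervention_cost({"rtms_sessions": 25, "psychotherapy_sessions": 10}, uc)
    assert total == pytest.approx(25 * 100 + 10 * 95)  # 3450 by hand


def test_intervention_cost_unknown_type_or_missing_price(uc):
    with pytest.raises(t.ConfigurationError, match="treatment type"):
        t.intervention_cost({"acupuncture": 3}, uc)
    bare = UnitCostTable(entries={"psychotherapy_session": 95.0})
    with pytest.raises(t.ConfigurationError, match="rtms_session"):
        t.intervention_cost({"rtms_sessions": 25}, bare)


def test_healthcare_cost_linear_combination(uc):
    assert t.healthcare_cost({"gp_contacts": 0, "medication_days": 0}, uc) == 0.0
    total = t.healthcare_cost({"gp_contacts": 2, "mental_care_contacts": 1}, uc)
    assert total == pytest.approx(2 * 33 + 120)  # 186 by hand
    with pytest.raises(t.TrialTableError):
        t.healthcare_cost({"gp_contacts": -1}, uc)


def test_cpi_factor_scales_once():
    uc_cpi = UnitCostTable(entries={"gp_contact": 100.0}, cpi_factor=1.10)
    assert t.healthcare_cost({"gp_contacts": 1}, uc_cpi) == pytest.approx(110.0)


def test_informal_cost_hours_at_housekeeping_rate(uc):
    assert t.informal_cost(0, 0, uc) == 0.0
    assert t.informal_cost(4, 0, uc) == pytest.approx(72.0)
    assert t.informal_cost(2, 3, uc) == pytest.approx(2 * 18 + 3 * 5)
    assert np.isnan(t.informal_cost(np.nan, 0, uc))  # missing, not zero


def test_productivity_cost_no_cap_below_friction_period():
    for method in ("friction", "human_capital"):
        cost = t.productivity_cost(3, 0, 20.0, 8.0, method=method)
        assert cost == pytest.approx(480.0)


def test_friction_caps_long_absence_human_capital_does_not():
    friction = t.productivity_cost(130, 0, 20.0, 8.0, "friction", friction_period_days=85)
    human = t.productivity_cost(130, 0, 20.0, 8.0, "human_capital", friction_period_days=85)
    assert friction == pytest.approx(85 * 160.0)   # 13,600 by hand
    assert human == pytest.approx(130 * 160.0)     # 20,800 by hand


def test_presenteeism_valued_uncapped():
    cost = t.productivity_cost(0, 200, 20.0, 8.0, "friction", friction_period_days=85)
    assert cost == pytest.approx(200 * 160.0)


def test_unemployed_paid_losses_are_an_error():
    with pytest.raises(t.TrialTableError, match="unemployed"):
        t.productivity_cost(1, 0, np.nan, 8.0, employed=False)
    assert t.productivity_cost(0, 0, np.nan, np.nan, employed=False) == 0.0


def test_unpaid_work_valued_at_shadow_price(uc):
    assert unpaid_productivity_cost(1, 1, 8.0, uc) == pytest.approx(2 * 18 * 8.0)
    assert unpaid_productivity_cost(0, 0, np.nan, uc) == 0.0


@given(
    days=st.floats(min_value=0, max_value=400),
    pres=st.floats(min_value=0, max_value=50),
    wage=st.floats(min_value=1, max_value=80),
    hours=st.floats(min_value=1, max_value=12),
)
@settings(max_examples=100, deadline=None)
def test_friction_never_exceeds_human_capital(days, pres, wage, hours):
    friction = t.productivity_cost(days, pres, wage, hours, "friction", 85.0)
    human = t.productivity_cost(days, pres, wage, hours, "human_capital", 85.0)
    assert friction <= human + 1e-9
    if days <= 85.0:
        assert friction == pytest.approx(human)


# ---------------------------------------------------------------------------
# cumulative integration


def test_constant_rate_integrates_to_13_04_windows():
    assert t.cumulative_costs([100.0, 100.0, 100.0], [0.0, 0.5, 1.0]) == pytest.approx(
        100.0 * PERIODS_PER_YEAR
    )


def test_triangular_rate_by_hand():
    # trapezoid mean rate 50 -> 13.04 * 50 = 652
    assert t.cumulative_costs([0.0, 100.0, 0.0], [0.0, 0.5, 1.0]) == pytest.approx(652.0)


def test_lump_sum_passes_through():
    assert t.cumulative_costs([0.0, 0.0, 0.0], [0.0, 0.5, 1.0], lump_sums=7010.0) == pytest.approx(
        7010.0
    )


def test_missing_wave_rate_makes_cumulative_missing():
    assert np.isnan(t.cumulative_costs([0.0, np.nan, 0.0], [0.0, 0.5, 1.0]))


# ---------------------------------------------------------------------------
# perspectives


def test_perspectives_select_categories():
    b = CostBreakdown(intervention=100.0, healthcare=200.0, informal=50.0, productivity=400.0)
    assert t.apply_perspective(b, "societal") == pytest.approx(750.0)
    assert t.apply_perspective(b, "healthcare") == pytest.approx(300.0)
    zero = CostBreakdown(0.0, 0.0, 0.0, 0.0)
    assert t.apply_perspective(zero, "societal") == 0.0
    assert t.apply_perspective(zero, "healthcare") == 0.0
    with pytest.raises(t.ConfigurationError):
        t.apply_perspective(b, "martian")


@given(
    vals=st.tuples(*[st.floats(min_value=0, max_value=1e5) for _ in range(4)])
)
@settings(max_examples=100, deadline=None)
def test_healthcare_total_never_exceeds_societal(vals):
    b = CostBreakdown(*vals)
    assert b.healthcare_total <= b.societal_total + 1e-9
    assert b.societal_total == pytest.approx(sum(vals))


def test_negative_category_rejected():
    with pytest.raises(t.TrialTableError):
        CostBreakdown(-1.0, 0.0, 0.0, 0.0)


# ---------------------------------------------------------------------------
# cohort frame


def test_wave_cost_frame_propagates_missing_blocks(trial_cohort_missing, unit_costs):
    wc = wave_cost_frame(trial_cohort_missing, unit_costs)
    follow = trial_cohort_missing[trial_cohort_missing["wave"] > 0]
    masked = follow[follow["utility"].isna()][["patient_id", "wave"]]
    merged = masked.merge(wc, on=["patient_id", "wave"])
    assert merged["healthcare"].isna().all()
    assert merged["productivity"].isna().all()
    # intervention lumps are administrative and never missing
    assert wc["intervention"].notna().all()


def test_wave_cost_frame_rejects_unemployed_paid_losses(trial_cohort_complete, unit_costs):
    df = trial_cohort_complete.copy()
    unemployed = df.index[(~df["employed"].astype(bool)) & (df["wave"] == 6)][0]
    df.loc[unemployed, "paid_absenteeism_days"] = 2.0
    with pytest.raises(t.TrialTableError, match="unemployed"):
        wave_cost_frame(df, unit_costs)


def test_category_additivity_on_cohort(trial_cohort_complete, unit_costs):
    wc = wave_cost_frame(trial_cohort_complete, unit_costs)
    total = wc["intervention"] + wc["healthcare"] + wc["informal"] + wc["productivity"]
    societal = wc[["intervention", "healthcare", "informal", "productivity"]].sum(axis=1)
    pd.testing.assert_series_equal(total, societal, check_names=False)
    assert (wc[["intervention", "healthcare", "informal", "productivity"]].fillna(0) >= 0).all().all()
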