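"""Tariff arithmetic, QALY area-under-curve and response/remission."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import trialcea as t
from trialcea.outcomes import TariffModel, patient_outcomes, resolve_utilities
from trialcea.schema import COLUMNS, RESOURCE_COLUMNS


@pytest.fixture(scope="module")
def tariff():
    return TariffModel.synthetic()


def test_full_health_state_has_no_decrements(tariff):
    assert t.utility_from_state("11111", tariff) == pytest.approx(1.0)


def test_single_decrement_subtracts(tariff):
    expected = 1.0 - tariff.decrements["mobility"][1]
    assert t.utility_from_state("21111", tariff) == pytest.approx(expected)
    assert t.utility_from_state([2, 1, 1, 1, 1], tariff) == pytest.approx(expected)


def test_worst_state_goes_below_zero(tariff):
    # level-5 decrements of the shipped tariff sum to 1.19 by hand
    assert t.utility_from_state("55555", tariff) == pytest.approx(1.0 - 1.19)
    assert t.utility_from_state("55555", tariff) < 0


def test_state_level_out_of_range_rejected(tariff):
    with pytest.raises(ValueError):
        t.utility_from_state("11116", tariff)
    with pytest.raises(ValueError):
        t.utility_from_state("1111", tariff)


def test_tariff_must_be_monotone():
    with pytest.raises(ValueError, match="non-decreasing"):
        TariffModel(
            dimensions=("a", "b", "c", "d", "e"),
            decrements={d: (0.0, 0.2, 0.1, 0.3, 0.4) for d in "abcde"},
        )


# ---------------------------------------------------------------------------
# QALY area under the curve


def test_constant_full_health_over_a_year_is_one_qaly():
    assert t.qaly_auc([1.0, 1.0, 1.0], [0.0, 0.5, 1.0]) == pytest.approx(1.0)


def test_six_month_trapezoid_by_hand():
    # (0.5 - 0) * (0.475 + 0.630) / 2 = 0.27625
    assert t.qaly_auc([0.475, 0.630], [0.0, 0.5]) == pytest.approx(0.27625)


def test_twelve_month_two_trapezoids_by_hand():
    # 0.27625 + 0.5 * (0.630 + 0.678) / 2 = 0.60325
    assert t.qaly_auc([0.475, 0.630, 0.678], [0.0, 0.5, 1.0]) == pytest.approx(0.60325)


def test_fewer_than_two_points_is_not_computable():
    assert np.isnan(t.qaly_auc([0.5, np.nan, np.nan], [0.0, 0.5, 1.0]))
    assert np.isnan(t.qaly_auc([np.nan, np.nan, np.nan], [0.0, 0.5, 1.0]))


def test_non_increasing_times_rejected():
    with pytest.raises(ValueError, match="strictly increasing"):
        t.qaly_auc([0.5, 0.5], [0.5, 0.5])


@given(
    u=st.lists(st.floats(min_value=-0.5, max_value=1.0), min_size=3, max_size=3),
    mid=st.floats(min_value=0.1, max_value=0.9),
)
@settings(max_examples=50, deadline=None)
def test_qaly_auc_additive_over_adjacent_intervals(u, mid):
    times = [0.0, mid, 1.0]
    whole = t.qaly_auc(u, times)
    parts = t.qaly_auc(u[:2], times[:2]) + t.qaly_auc(u[1:], times[1:])
    assert whole == pytest.approx(parts, abs=1e-12)


@given(c=st.floats(min_value=-0.5, max_value=1.0), T=st.floats(min_value=0.1, max_value=5.0))
@settings(max_examples=50, deadline=None)
def test_constant_utility_returns_c_times_T(c, T):
    assert t.qaly_auc([c, c], [0.0, T]) == pytest.approx(c * T, rel=1e-12, abs=1e-12)


# ---------------------------------------------------------------------------
# response / remission


@pytest.mark.parametrize(
    "baseline, followup, expected",
    [(20, 10, True), (20, 11, False), (21, 0, True), (20, 10.5, False)],
)
def test_response_boundary_at_half_reduction(baseline, followup, expected):
    assert t.classify_response(baseline, followup) is expected


@given(st.integers(min_value=1, max_value=50), st.integers(min_value=0, max_value=50),
       st.floats(min_value=0.1, max_value=10))
@settings(max_examples=50, deadline=None)
def test_response_invariant_to_positive_scaling(base, follow, scale):
    assert t.classify_response(base, follow) == t.classify_response(base * scale, follow * scale)


def test_response_requires_positive_baseline():
    with pytest.raises(ValueError):
        t.classify_response(0, 5)


def test_missing_followup_is_unknown_not_false():
    assert t.classify_response(20, np.nan) is None
    assert t.classify_remission(np.nan) is None


@pytest.mark.parametrize("score, expected", [(7, True), (8, False), (0, True)])
def test_remission_boundary_below_eight(score, expected):
    assert t.classify_remission(score) is expected


# ---------------------------------------------------------------------------
# cohort-level summaries


def _cohort_with_counts():
    """Arm sizes 48/41 with the printed response/remission counts at both
    follow-ups: intervention 16/11 then 13/12; control 11/9 then 10/7."""
    rows = []

    def add_patients(arm, n, h6_pattern, h12_pattern):
        # pattern: list of (count, score); remaining patients score 15
        for i in range(n):
            pid = f"{arm[:1]}{i:03d}"
            h6 = _score_for(i, h6_pattern)
            h12 = _score_for(i, h12_pattern)
            for wave, h in ((0, 20), (6, h6), (12, h12)):
                row = {c: 0.0 for c in RESOURCE_COLUMNS}
                row.update(
                    patient_id=pid, arm=arm, wave=wave, gender="female", employed=False,
                    wage_per_hour=np.nan, usual_hours_per_day=8.0, hdrs17=h,
                    utility=0.5, eq5d_state=pd.NA,
                )
                rows.append(row)

    def _score_for(i, pattern):
        seen = 0
        for count, score in pattern:
            if i < seen + count:
                return score
            seen += count
        return 15

    # score 5: response + remission; score 10: response only (>= 50% drop from 20)
    add_patients("intervention", 48, [(11, 5), (5, 10)], [(12, 5), (1, 10)])
    add_patients("control", 41, [(9, 5), (2, 10)], [(7, 5), (3, 10)])
    return pd.DataFrame(rows, columns=list(COLUMNS))


def test_cohort_rates_use_randomized_denominator():
    df = _cohort_with_counts()
    _, summary = t.cohort_outcomes(df)

    def rate(arm, wave, kind):
        row = summary[
            (summary["arm"] == arm) & (summary["wave"] == wave) & (summary["variable"] == kind)
        ].iloc[0]
        return row["count"], round(100 * row["rate"], 1)

    assert rate("intervention", 12, "response") == (13, 27.1)
    assert rate("intervention", 6, "response") == (16, 33.3)
    assert rate("intervention", 12, "remission") == (12, 25.0)
    assert rate("control", 12, "response") == (10, 24.4)
    assert rate("control", 12, "remission") == (7, 17.1)


def test_observed_denominator_counts_only_nonmissing():
    df = _cohort_with_counts()
    # mask 8 control follow-ups: denominators shrink, counts of positives shift
    ids = df[(df["arm"] == "control")]["patient_id"].unique()[-8:]
    df.loc[(df["wave"] == 12) & df["patient_id"].isin(ids), "hdrs17"] = np.nan
    _, summary = t.cohort_outcomes(df, denominator="observed")
    row = summary[
        (summary["arm"] == "control") & (summary["wave"] == 12) & (summary["variable"] == "response")
    ].iloc[0]
    assert row["n"] == 41 - 8
    assert row["n_missing"] == 8


def test_empty_arm_summary_has_no_division_by_zero():
    df = _cohort_with_counts()
    df = df[df["arm"] == "intervention"].copy()
    _, summary = t.cohort_outcomes(df)
    ctl = summary[(summary["arm"] == "control") & (summary["variable"] == "response")]
    assert np.isnan(ctl["rate"]).all()


def test_qaly_needs_every_involved_wave():
    df = _cohort_with_counts()
    pid = "i000"
    df.loc[(df["patient_id"] == pid) & (df["wave"] == 6), "utility"] = np.nan
    outcomes = patient_outcomes(df)
    row = outcomes[outcomes["patient_id"] == pid].iloc[0]
    assert np.isnan(row["qaly_6m"]) and np.isnan(row["qaly_12m"])
    other = outcomes[outcomes["patient_id"] == "i001"].iloc[0]
    assert other["qaly_12m"] == pytest.approx(0.5)


def test_eq5d_states_fill_missing_utilities_only(tariff, caplog):
    df = _cohort_with_counts().iloc[:3].copy()  # one patient, three waves
    df.loc[df["wave"] == 6, "utility"] = np.nan
    df.loc[df["wave"] == 6, "eq5d_state"] = "21111"
    df.loc[df["wave"] == 12, "eq5d_state"] = "55555"  # utility 0.5 present: wins
    out = resolve_utilities(df, tariff)
    assert out.loc[out["wave"] == 6, "utility"].iloc[0] == pytest.approx(
        1.0 - tariff.decrements["mobility"][1]
    )
    assert out.loc[out["wave"] == 12, "utility"].iloc[0] == 0.5
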