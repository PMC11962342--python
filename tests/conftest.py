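"""Shared fixtures: reference-trial cohorts and a truth-known recovery design."""
from __future__ import annotations

import numpy as np
import pytest

from trialcea import SimulationParams, UnitCostTable, apply_missingness, generate_cohort
from trialcea.costing import PERIODS_PER_YEAR
from trialcea.simulate import CostCategoryParams, MissingnessModel


@pytest.fixture(scope="session")
def unit_costs():
    return UnitCostTable.default()


@pytest.fixture(scope="session")
def trial_params():
    params = SimulationParams.default()
    params.seed = 11
    return params


@pytest.fixture(scope="session")
def trial_cohort_complete(trial_params):
    return generate_cohort(trial_params)


@pytest.fixture(scope="session")
def trial_cohort_missing(trial_params, trial_cohort_complete):
    return apply_missingness(trial_cohort_complete, trial_params)


def _category(means_by_arm, p_zero=0.3, cv=1.0):
    return CostCategoryParams(
        mean={a: list(m) for a, m in means_by_arm.items()},
        p_zero={a: [p_zero] * 3 for a in ("intervention", "control")},
        cv={a: [cv] * 3 for a in ("intervention", "control")},
    )


def _zero_category():
    zero = {a: [0.0] * 3 for a in ("intervention", "control")}
    return CostCategoryParams(mean=zero, p_zero={a: [1.0] * 3 for a in zero}, cv={a: [1.0] * 3 for a in zero})


TRUE_DELTA_QALY = 0.05
TRUE_DELTA_COST = -1000.0


def make_recovery_params(n_int: int, n_ctl: int, seed: int) -> SimulationParams:
    """Cohort with built-in incremental effects injected at follow-up only
    (arms share the baseline distribution, so the SUR baseline adjustment
    is unbiased): dQALY = +0.05 via equal utility gains of 1/15 at both
    follow-ups (trapezoid weight 0.75), dC = -1000 EUR via a healthcare
    rate offset of 1000/(0.75 x 13.04) per 4-week window at both
    follow-ups.  No intervention lumps, no missingness."""
    gain = 1.0 / 15.0
    ctl_rate = 200.0
    offset = TRUE_DELTA_COST / (0.75 * PERIODS_PER_YEAR)
    return SimulationParams(
        n_per_arm={"intervention": n_int, "control": n_ctl},
        female_prob=0.6,
        employment_prob=0.4,
        wage_mean_per_hour=20.0,
        wage_sd_per_hour=5.0,
        min_wage_per_hour=11.0,
        usual_hours_mean=7.6,
        usual_hours_sd=1.0,
        utility_mean={
            "intervention": [0.5, 0.5 + gain, 0.5 + gain],
            "control": [0.5, 0.5, 0.5],
        },
        utility_sd={a: [0.1] * 3 for a in ("intervention", "control")},
        hdrs_mean={a: [21.0, 10.0, 9.0] for a in ("intervention", "control")},
        hdrs_sd={a: [4.0] * 3 for a in ("intervention", "control")},
        healthcare_cost=_category(
            {
                "intervention": [ctl_rate, ctl_rate + offset, ctl_rate + offset],
                "control": [ctl_rate] * 3,
            }
        ),
        family_help_cost=_zero_category(),
        travel_cost=_zero_category(),
        paid_absenteeism_days=_zero_category(),
        paid_presenteeism_days=_zero_category(),
        unpaid_absenteeism_days=_zero_category(),
        unpaid_presenteeism_days=_zero_category(),
        rtms={a: {"p_treated": 0.0, "sessions": 25} for a in ("intervention", "control")},
        psychotherapy_sessions_mean={"intervention": 0.0, "control": 0.0},
        missingness=MissingnessModel(
            intercepts={0: -np.inf, 6: -np.inf, 12: -np.inf},
            arm_control={0: 0.0, 6: 0.0, 12: 0.0},
        ),
        seed=seed,
    )
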