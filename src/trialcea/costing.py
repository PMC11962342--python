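"""Four-category societal costing over a 12-month horizon.

Categories: (1) intervention (rTMS + psychotherapy sessions, costed
bottom-up as lump sums per elapsed period), (2) healthcare utilization
(contacts, home help, medication), (3) informal care (travel plus help
from family/friends valued at the housekeeping shadow price), and
(4) productivity losses (absenteeism/presenteeism, paid and unpaid).

Recurring categories are measured as euros per 4-week recall window at
waves 0, 6 and 12 months; 12-month cumulative costs integrate the
piecewise-linear per-window rate over the year (13.04 four-week periods
per year, the same linear-interpolation convention as the QALY
area-under-curve) and add intervention lump sums in the period they
occur.  The societal perspective sums all four categories; the
healthcare perspective keeps intervention + healthcare utilization
only.  No discounting is applied.

Productivity valuation: a lost day is worth wage x usual daily hours;
the friction-cost method caps the valued cumulative absence at the
friction period (time to replace a worker, default 85 working days)
while the human-capital method values the entire absence.  Presenteeism
enters as efficiency-equivalent lost days and is never capped.  Unpaid
(volunteer) work is valued at the housekeeping shadow price.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .schema import (
    RESOURCE_UNIT_KEYS,
    SESSION_COLUMNS,
    UNPAID_WORK_RATE_KEY,
    WAVES,
    WAVE_TIMES,
    ConfigurationError,
    TrialTableError,
    UnitCostTable,
)

#: 4-week recall periods per year; cumulative costs are rate integrals
#: over the year expressed in these periods
PERIODS_PER_YEAR = 13.04

HEALTHCARE_USE_COLUMNS = (
    "gp_contacts",
    "mental_care_contacts",
    "other_care_contacts",
    "home_help_hours",
    "medication_days",
)


@dataclass(frozen=True)
class CostBreakdown:
    """Euro costs of one patient x period, by category.

    Recurring categories cover the 4-week recall window; the
    intervention category is a lump sum for the elapsed period.
    """

    intervention: float
    healthcare: float
    informal: float
    productivity: float

    def __post_init__(self):
        for name in ("intervention", "healthcare", "informal", "productivity"):
            v = getattr(self, name)
            if not np.isnan(v) and v < 0:
                raise TrialTableError(f"negative {name} cost: {v}")

    @property
    def societal_total(self) -> float:
        return self.intervention + self.healthcare + self.informal + self.productivity

    @property
    def healthcare_total(self) -> float:
        return self.intervention + self.healthcare


def apply_perspective(breakdown: CostBreakdown, perspective: str) -> float:
    """Total under a perspective: societal = all four categories,
    healthcare = intervention + healthcare utilization only."""
    if perspective == "societal":
        return breakdown.societal_total
    if perspective == "healthcare":
        return breakdown.healthcare_total
    raise ConfigurationError(f"unknown perspective {perspective!r}")


def intervention_cost(sessions: Mapping[str, float], unit_costs: UnitCostTable) -> float:
    """Bottom-up intervention cost: session counts x unit prices.

    ``sessions`` maps session columns (``rtms_sessions``,
    ``psychotherapy_sessions``) to counts.  Unknown treatment types are
    a configuration error; missing counts propagate as NaN.
    """
    total = 0.0
    for kind, count in sessions.items():
        if kind not in SESSION_COLUMNS:
            raise ConfigurationError(f"unknown treatment type {kind!r}")
        if count is None or (isinstance(count, float) and np.isnan(count)):
            return float("nan")
        if count < 0:
            raise TrialTableError(f"negative session count for {kind}")
        if count > 0:  # a zero count never needs a price
            total += count * unit_costs.unit_cost(RESOURCE_UNIT_KEYS[kind])
    return total


def healthcare_cost(resource_use: Mapping[str, float], unit_costs: UnitCostTable) -> float:
    """Healthcare utilization euros: contacts/medication x unit prices."""
    total = 0.0
    for col, count in resource_use.items():
        if col not in HEALTHCARE_USE_COLUMNS:
            raise ConfigurationError(f"unknown healthcare resource {col!r}")
        if count is None or (isinstance(count, float) and np.isnan(count)):
            return float("nan")
        if count < 0:
            raise TrialTableError(f"negative count for {col}")
        total += count * unit_costs.unit_cost(RESOURCE_UNIT_KEYS[col])
    return total


def informal_cost(help_hours: float, travel_trips: float, unit_costs: UnitCostTable) -> float:
    """Informal care euros: family/friends help at the housekeeping
    shadow price plus travel.  Missing inputs propagate as NaN."""
    if _is_missing(help_hours) or _is_missing(travel_trips):
        return float("nan")
    if help_hours < 0 or travel_trips < 0:
        raise TrialTableError("informal-care quantities must be >= 0")
    return (
        help_hours * unit_costs.unit_cost("housekeeping_hour")
        + travel_trips * unit_costs.unit_cost("travel_trip")
    )


def productivity_cost(
    absent_days: float,
    presenteeism_days: float,
    wage_per_hour: float,
    usual_hours_per_day: float,
    method: str = "friction",
    friction_period_days: float = 85.0,
    employed: bool = True,
) -> float:
    """Paid-work productivity loss in euros.

    A lost day is valued at ``wage_per_hour x usual_hours_per_day``.
    Under the friction method the valued absence is capped at the
    friction period; the human-capital method values the entire
    absence.  Presenteeism days are efficiency-equivalent lost days and
    are not capped.
    """
    if method not in ("friction", "human_capital"):
        raise ConfigurationError(f"unknown productivity method {method!r}")
    if _is_missing(absent_days) or _is_missing(presenteeism_days):
        return float("nan")
    if absent_days < 0 or presenteeism_days < 0:
        raise TrialTableError("productivity day counts must be >= 0")
    if not employed:
        if absent_days > 0 or presenteeism_days > 0:
            raise TrialTableError("unemployed patient reports paid-work losses")
        return 0.0
    if _is_missing(wage_per_hour) or _is_missing(usual_hours_per_day):
        return float("nan") if (absent_days > 0 or presenteeism_days > 0) else 0.0
    day_value = wage_per_hour * usual_hours_per_day
    valued_absence = min(absent_days, friction_period_days) if method == "friction" else absent_days
    return valued_absence * day_value + presenteeism_days * day_value


def unpaid_productivity_cost(
    absent_days: float,
    presenteeism_days: float,
    usual_hours_per_day: float,
    unit_costs: UnitCostTable,
) -> float:
    """Unpaid (volunteer) work loss at the housekeeping shadow price."""
    if _is_missing(absent_days) or _is_missing(presenteeism_days):
        return float("nan")
    if absent_days < 0 or presenteeism_days < 0:
        raise TrialTableError("productivity day counts must be >= 0")
    if absent_days == 0 and presenteeism_days == 0:
        return 0.0
    if _is_missing(usual_hours_per_day):
        return float("nan")
    rate = unit_costs.unit_cost(UNPAID_WORK_RATE_KEY) * usual_hours_per_day
    return (absent_days + presenteeism_days) * rate


def cumulative_costs(
    per_wave_costs: Sequence[float],
    elapsed_times: Sequence[float],
    lump_sums: float = 0.0,
    periods_per_year: float = PERIODS_PER_YEAR,
) -> float:
    """Integrate a per-4-week cost rate over the follow-up year.

    The rate is piecewise linear through the wave measurements
    (trapezoid in time, matching the QALY convention); the integral in
    years is scaled by 13.04 periods/year.  Lump sums (intervention
    costs) are added as-is.  Any missing wave rate makes the cumulative
    cost missing — imputation happens upstream, never here.
    """
    r = np.asarray(per_wave_costs, dtype=float)
    t = np.asarray(elapsed_times, dtype=float)
    if r.shape != t.shape or len(r) < 2:
        raise ValueError("need matching rates and times at >= 2 waves")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.isnan(r).any():
        return float("nan")
    return float(np.trapezoid(r, t) * periods_per_year + lump_sums)


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and np.isnan(v)) or pd.isna(v)


# ---------------------------------------------------------------------------
# cohort-level frames


def wave_cost_frame(df: pd.DataFrame, unit_costs: UnitCostTable) -> pd.DataFrame:
    """Per patient x wave category euros from a long cohort table.

    Columns: ``intervention`` (lump euros for the elapsed period),
    ``healthcare``, ``informal`` (4-week window euros),
    ``paid_absenteeism_eur``, ``other_productivity_eur`` (presenteeism
    plus unpaid work), ``productivity`` (their sum), ``day_value``
    (euros per lost paid workday) and ``paid_absenteeism_days``.
    Missing resource blocks propagate to missing category euros.
    """
    emp = df["employed"].fillna(False).to_numpy(dtype=bool)
    bad = (~emp) & (
        (df["paid_absenteeism_days"].fillna(0) > 0)
        | (df["paid_presenteeism_days"].fillna(0) > 0)
    ).to_numpy()
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise TrialTableError(
            "unemployed patient reports paid-work losses",
            row=i + 2,
            column="paid_absenteeism_days",
        )

    uc = unit_costs.unit_cost
    out = df[["patient_id", "arm", "wave"]].copy()

    out["intervention"] = sum(
        df[c].to_numpy(dtype=float) * uc(RESOURCE_UNIT_KEYS[c]) for c in SESSION_COLUMNS
    )
    out["healthcare"] = sum(
        df[c].to_numpy(dtype=float) * uc(RESOURCE_UNIT_KEYS[c])
        for c in HEALTHCARE_USE_COLUMNS
    )
    out["informal"] = df["family_help_hours"].to_numpy(dtype=float) * uc(
        "housekeeping_hour"
    ) + df["travel_trips"].to_numpy(dtype=float) * uc("travel_trip")

    wage = df["wage_per_hour"].to_numpy(dtype=float)
    hours = df["usual_hours_per_day"].to_numpy(dtype=float)
    day_value = np.where(emp, wage * hours, 0.0)
    pabs = df["paid_absenteeism_days"].to_numpy(dtype=float)
    ppres = df["paid_presenteeism_days"].to_numpy(dtype=float)
    # zero days cost zero even when the wage is unrecorded
    pabs_eur = np.where(pabs == 0, 0.0, pabs * day_value)
    ppres_eur = np.where(ppres == 0, 0.0, ppres * day_value)

    unpaid_rate = uc(UNPAID_WORK_RATE_KEY) * hours
    uabs = df["unpaid_absenteeism_days"].to_numpy(dtype=float)
    upres = df["unpaid_presenteeism_days"].to_numpy(dtype=float)
    unpaid_eur = np.where(uabs + upres == 0, 0.0, (uabs + upres) * unpaid_rate)

    out["paid_absenteeism_eur"] = pabs_eur
    out["paid_absenteeism_days"] = pabs
    out["other_productivity_eur"] = ppres_eur + unpaid_eur
    out["productivity"] = out["paid_absenteeism_eur"] + out["other_productivity_eur"]
    out["day_value"] = day_value
    return out


def cost_summary(df: pd.DataFrame, unit_costs: UnitCostTable) -> pd.DataFrame:
    """Observed per-arm cost summary: category means/SDs per wave plus
    complete-case cumulative means (bootstrap CIs belong to inference)."""
    wc = wave_cost_frame(df, unit_costs)
    rows = []
    for arm in ("intervention", "control"):
        sub = wc[wc["arm"] == arm]
        for wave in WAVES:
            w = sub[sub["wave"] == wave]
            for cat in ("intervention", "healthcare", "informal", "productivity"):
                obs = w[cat].dropna()
                rows.append(
                    {
                        "arm": arm,
                        "wave": wave,
                        "category": cat,
                        "mean": obs.mean() if len(obs) else np.nan,
                        "sd": obs.std(ddof=1) if len(obs) > 1 else np.nan,
                        "n_missing": int(len(w) - len(obs)),
                        "n": int(len(w)),
                    }
                )
        # complete-case cumulative per category
        times = np.array([WAVE_TIMES[w] for w in WAVES])
        wide = {
            cat: sub.pivot(index="patient_id", columns="wave", values=cat)[list(WAVES)]
            for cat in ("healthcare", "informal", "productivity")
        }
        lump = sub.groupby("patient_id")["intervention"].sum()
        cums = {"intervention": lump}
        for cat, frame in wide.items():
            vals = frame.to_numpy(dtype=float)
            cum = np.where(
                np.isnan(vals).any(axis=1),
                np.nan,
                np.trapezoid(vals, times, axis=1) * PERIODS_PER_YEAR,
            )
            cums[cat] = pd.Series(cum, index=frame.index)
        for cat, series in cums.items():
            obs = series.dropna()
            rows.append(
                {
                    "arm": arm,
                    "wave": "cumulative",
                    "category": cat,
                    "mean": obs.mean() if len(obs) else np.nan,
                    "sd": obs.std(ddof=1) if len(obs) > 1 else np.nan,
                    "n_missing": int(series.isna().sum()),
                    "n": int(len(series)),
                }
            )
    return pd.DataFrame(rows)
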