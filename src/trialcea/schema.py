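"""Patient-level trial data model: wave-format table I/O and validation.

A cohort is stored *long*: one row per patient per assessment wave
(months 0, 6 and 12).  Clinical scores, the utility index and all
resource-use quantities live on the wave row; missing values stay
missing (pandas ``NA``/``NaN``) and are never silently zero-filled —
a reported cost of 0 and an unreturned questionnaire are different
facts.

The column dictionary for the delimited trial table is shipped in
``docs/column_dictionary.md``.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger(__name__)

ARMS = ("intervention", "control")
WAVES = (0, 6, 12)
#: assessment times in years; QALYs and cost integrals work in years
WAVE_TIMES = {0: 0.0, 6: 0.5, 12: 1.0}
GENDERS = ("female", "male")

#: resource-use quantities reported over the 4-week recall window
RECALL_RESOURCE_COLUMNS = (
    "gp_contacts",
    "mental_care_contacts",
    "other_care_contacts",
    "home_help_hours",
    "medication_days",
    "travel_trips",
    "family_help_hours",
    "paid_absenteeism_days",
    "paid_presenteeism_days",
    "unpaid_absenteeism_days",
    "unpaid_presenteeism_days",
)
#: treatment sessions accrued since the previous wave (lump quantities,
#: costed per elapsed period rather than integrated as a rate)
SESSION_COLUMNS = ("rtms_sessions", "psychotherapy_sessions")
RESOURCE_COLUMNS = SESSION_COLUMNS + RECALL_RESOURCE_COLUMNS

COLUMNS = (
    "patient_id",
    "arm",
    "wave",
    "gender",
    "employed",
    "wage_per_hour",
    "usual_hours_per_day",
    "hdrs17",
    "utility",
    "eq5d_state",
) + RESOURCE_COLUMNS

HDRS_MAX = 52


class TrialTableError(ValueError):
    """Malformed or invalid trial-table content, located by row/column."""

    def __init__(self, message: str, row=None, column: str | None = None):
        loc = []
        if row is not None:
            loc.append(f"row {row}")
        if column is not None:
            loc.append(f"column {column!r}")
        if loc:
            message = f"{message} ({', '.join(loc)})"
        super().__init__(message)
        self.row = row
        self.column = column


class ConfigurationError(ValueError):
    """Invalid analysis configuration or unit-cost table."""


@dataclass
class PatientWaveRecord:
    """One patient x one assessment wave.

    ``resource_use`` maps resource column names to quantities over the
    4-week recall window (sessions: since the previous wave).  ``None``
    marks a missing measurement.
    """

    patient_id: str
    arm: str
    wave: int
    gender: str | None = None
    employed: bool | None = None
    wage_per_hour: float | None = None
    usual_hours_per_day: float | None = None
    hdrs17: int | None = None
    utility: float | None = None
    eq5d_state: str | None = None
    resource_use: dict[str, float | None] = field(default_factory=dict)


def records_from_frame(df: pd.DataFrame) -> list[PatientWaveRecord]:
    """Materialise a validated long table as record objects."""
    out = []
    for _, row in df.iterrows():
        ru = {
            c: (None if pd.isna(row[c]) else float(row[c]))
            for c in RESOURCE_COLUMNS
        }
        out.append(
            PatientWaveRecord(
                patient_id=str(row["patient_id"]),
                arm=row["arm"],
                wave=int(row["wave"]),
                gender=None if pd.isna(row["gender"]) else row["gender"],
                employed=None if pd.isna(row["employed"]) else bool(row["employed"]),
                wage_per_hour=_opt_float(row["wage_per_hour"]),
                usual_hours_per_day=_opt_float(row["usual_hours_per_day"]),
                hdrs17=None if pd.isna(row["hdrs17"]) else int(row["hdrs17"]),
                utility=_opt_float(row["utility"]),
                eq5d_state=None if pd.isna(row["eq5d_state"]) else str(row["eq5d_state"]),
                resource_use=ru,
            )
        )
    return out


def _opt_float(v) -> float | None:
    return None if pd.isna(v) else float(v)


def frame_from_records(records: Iterable[PatientWaveRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "patient_id": r.patient_id,
            "arm": r.arm,
            "wave": r.wave,
            "gender": r.gender,
            "employed": r.employed,
            "wage_per_hour": r.wage_per_hour,
            "usual_hours_per_day": r.usual_hours_per_day,
            "hdrs17": r.hdrs17,
            "utility": r.utility,
            "eq5d_state": r.eq5d_state,
        }
        for c in RESOURCE_COLUMNS:
            row[c] = r.resource_use.get(c)
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(COLUMNS))
    return _coerce_dtypes(df)


def _coerce_dtypes(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["patient_id"] = df["patient_id"].astype(str)
    df["wave"] = df["wave"].astype(int)
    df["employed"] = df["employed"].astype("boolean")
    df["eq5d_state"] = df["eq5d_state"].astype("string")
    df["hdrs17"] = df["hdrs17"].astype("Float64")
    for c in ("wage_per_hour", "usual_hours_per_day", "utility") + RESOURCE_COLUMNS:
        df[c] = pd.to_numeric(df[c], errors="coerce").astype(float)
    return df


# ---------------------------------------------------------------------------
# table I/O


def read_trial_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a wave-format trial table (CSV, UTF-8).

    Returns a long DataFrame with one row per patient per wave.  Missing
    cells come back as missing values, never as zeros.  Raises
    :class:`TrialTableError` naming the offending row and column on
    malformed or invalid content.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            dtype={"patient_id": str, "eq5d_state": str},
            encoding="utf-8",
        )
    except (pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise TrialTableError(f"cannot parse {path}: {exc}") from exc
    missing_cols = [c for c in COLUMNS if c not in df.columns]
    if missing_cols:
        raise TrialTableError(f"{path} lacks required columns {missing_cols}")
    df = df[list(COLUMNS)]

    # locate non-numeric garbage cell by cell before coercing
    for c in ("wave", "wage_per_hour", "usual_hours_per_day", "hdrs17", "utility") + RESOURCE_COLUMNS:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = coerced.isna() & df[c].notna() & (df[c].astype(str).str.strip() != "")
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise TrialTableError(
                f"non-numeric value {df[c].iloc[i]!r}", row=i + 2, column=c
            )
        df[c] = coerced
    emp = df["employed"]
    if emp.dtype == object:
        mapped = emp.map(
            {"True": True, "False": False, True: True, False: False,
             "true": True, "false": False, "1": True, "0": False, 1: True, 0: False}
        )
        bad = mapped.isna() & emp.notna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise TrialTableError(
                f"non-boolean value {emp.iloc[i]!r}", row=i + 2, column="employed"
            )
        df["employed"] = mapped
    df = _coerce_dtypes(df)
    validate_frame(df)
    return df


def write_trial_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a long trial table as CSV; round-trips field-for-field."""
    df.to_csv(path, index=False, encoding="utf-8")


def validate_frame(df: pd.DataFrame) -> None:
    """Enforce the trial-table invariants; raise on the first violation.

    Checks arm/wave/gender domains, HDRS-17 range, utility upper bound,
    EQ-5D-5L state strings, non-negative resource use, and the
    one-record-per-patient-per-wave grid.
    """

    def first_bad(mask: pd.Series, msg: str, col: str):
        if mask.any():
            i = int(np.flatnonzero(mask.to_numpy())[0])
            raise TrialTableError(msg.format(v=df[col].iloc[i]), row=i + 2, column=col)

    first_bad(~df["arm"].isin(ARMS), "unknown arm {v!r}", "arm")
    first_bad(~df["wave"].isin(WAVES), "wave {v!r} not one of 0/6/12", "wave")
    first_bad(df["gender"].notna() & ~df["gender"].isin(GENDERS), "unknown gender {v!r}", "gender")

    h = df["hdrs17"]
    first_bad(h.notna() & ((h < 0) | (h > HDRS_MAX)), "hdrs17 {v} outside [0, 52]", "hdrs17")
    first_bad(h.notna() & (h != h.round()), "hdrs17 {v} not an integer", "hdrs17")

    u = df["utility"]
    first_bad(u.notna() & (u > 1.0), "utility {v} exceeds 1", "utility")

    s = df["eq5d_state"].astype("string")
    first_bad(
        s.notna() & ~s.str.fullmatch(r"[1-5]{5}").fillna(False),
        "eq5d_state {v!r} is not five digits in 1-5",
        "eq5d_state",
    )

    for c in RESOURCE_COLUMNS:
        first_bad(df[c].notna() & (df[c] < 0), "negative quantity {v}", c)
    first_bad(
        df["wage_per_hour"].notna() & (df["wage_per_hour"] < 0),
        "negative wage {v}",
        "wage_per_hour",
    )

    dup = df.duplicated(subset=["patient_id", "wave"], keep=False)
    if dup.any():
        pid, wave = df.loc[dup, ["patient_id", "wave"]].iloc[0]
        raise TrialTableError(f"duplicate record for patient {pid!r} at wave {wave}")

    waves_per_patient = df.groupby("patient_id")["wave"].agg(frozenset)
    incomplete = waves_per_patient[waves_per_patient != frozenset(WAVES)]
    if len(incomplete):
        raise TrialTableError(
            f"patient {incomplete.index[0]!r} has waves {sorted(incomplete.iloc[0])}, "
            f"expected {list(WAVES)}"
        )
    arms_per_patient = df.groupby("patient_id")["arm"].nunique()
    if (arms_per_patient > 1).any():
        pid = arms_per_patient[arms_per_patient > 1].index[0]
        raise TrialTableError(f"patient {pid!r} appears in more than one arm")


# ---------------------------------------------------------------------------
# validation report


@dataclass
class CohortReport:
    """Report-only cohort description: arm sizes and per-wave missingness."""

    arm_sizes: dict[str, int]
    #: long frame: arm, wave, variable, n_missing, n, proportion
    missingness: pd.DataFrame

    def missing_proportion(self, variable: str, wave: int, arm: str) -> float:
        m = self.missingness
        sel = m[(m["variable"] == variable) & (m["wave"] == wave) & (m["arm"] == arm)]
        return float(sel["proportion"].iloc[0])


def validate_cohort(df: pd.DataFrame) -> CohortReport:
    """Describe a validated cohort; never raises (report-only).

    Missingness is reported per arm x wave x variable with the full
    randomized arm as denominator.
    """
    arm_sizes = {
        arm: int(df.loc[df["arm"] == arm, "patient_id"].nunique()) for arm in ARMS
    }
    variables = ("hdrs17", "utility") + RESOURCE_COLUMNS
    rows = []
    for arm in ARMS:
        for wave in WAVES:
            sub = df[(df["arm"] == arm) & (df["wave"] == wave)]
            n = len(sub)
            for v in variables:
                miss = int(sub[v].isna().sum())
                rows.append(
                    {
                        "arm": arm,
                        "wave": wave,
                        "variable": v,
                        "n_missing": miss,
                        "n": n,
                        "proportion": miss / n if n else np.nan,
                    }
                )
    return CohortReport(arm_sizes=arm_sizes, missingness=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# unit costs and analysis configuration


#: trial-table resource column -> unit-cost table resource name
RESOURCE_UNIT_KEYS = {
    "rtms_sessions": "rtms_session",
    "psychotherapy_sessions": "psychotherapy_session",
    "gp_contacts": "gp_contact",
    "mental_care_contacts": "mental_care_contact",
    "other_care_contacts": "other_care_contact",
    "home_help_hours": "home_help_hour",
    "medication_days": "medication_day",
    "travel_trips": "travel_trip",
    "family_help_hours": "housekeeping_hour",
}
#: shadow price for unpaid (volunteer) work, euros/hour
UNPAID_WORK_RATE_KEY = "housekeeping_hour"


@dataclass(frozen=True)
class UnitCostTable:
    """Resource type -> euros per unit, with a price-index scale factor.

    ``cpi_factor`` re-expresses the reference price year in the index
    year; it is applied exactly once, at lookup.
    """

    entries: Mapping[str, float]
    cpi_factor: float = 1.0

    def __post_init__(self):
        if self.cpi_factor <= 0:
            raise ConfigurationError(f"cpi_factor must be > 0, got {self.cpi_factor}")
        for k, v in self.entries.items():
            if v < 0:
                raise ConfigurationError(f"negative unit cost for {k!r}: {v}")

    def unit_cost(self, resource: str) -> float:
        """Index-year euros per unit of ``resource``."""
        try:
            return float(self.entries[resource]) * self.cpi_factor
        except KeyError:
            raise ConfigurationError(
                f"unit-cost table has no entry for resource {resource!r}"
            ) from None

    @classmethod
    def from_csv(cls, path: str | Path, cpi_factor: float = 1.0) -> "UnitCostTable":
        df = pd.read_csv(path)
        for col in ("resource", "unit_cost_eur"):
            if col not in df.columns:
                raise ConfigurationError(f"unit-cost table {path} lacks column {col!r}")
        entries = dict(zip(df["resource"].astype(str), df["unit_cost_eur"].astype(float)))
        return cls(entries=entries, cpi_factor=cpi_factor)

    @classmethod
    def default(cls, cpi_factor: float = 1.0) -> "UnitCostTable":
        """The illustrative unit-cost table shipped with the package."""
        with resources.files("trialcea.data").joinpath("unit_costs.csv").open("rb") as fh:
            df = pd.read_csv(fh)
        entries = dict(zip(df["resource"].astype(str), df["unit_cost_eur"].astype(float)))
        return cls(entries=entries, cpi_factor=cpi_factor)


PERSPECTIVES = ("societal", "healthcare")
PRODUCTIVITY_METHODS = ("friction", "human_capital")


@dataclass
class AnalysisConfig:
    """Analysis settings: perspective, costing method, bootstrap and PMM.

    Defaults follow common Dutch economic-evaluation practice: societal
    perspective, friction-cost productivity valuation with an 85
    working-day friction period, 5000 bootstrap replicates, a
    willingness-to-pay grid from 0 to 80,000 euros in 1,000-euro steps
    with a 50,000 euro reference value, and 5 PMM donors.
    """

    perspective: str = "societal"
    productivity_method: str = "friction"
    friction_period_days: float = 85.0
    n_bootstrap: int = 5000
    wtp_grid: tuple[float, ...] = tuple(float(x) for x in range(0, 80001, 1000))
    wtp_reference: float = 50000.0
    pmm_donors: int = 5
    seed: int = 0
    response_threshold: float = 0.5
    remission_threshold: float = 8.0
    cpi_factor: float = 1.0

    def __post_init__(self):
        if self.perspective not in PERSPECTIVES:
            raise ConfigurationError(f"unknown perspective {self.perspective!r}")
        if self.productivity_method not in PRODUCTIVITY_METHODS:
            raise ConfigurationError(
                f"unknown productivity method {self.productivity_method!r}"
            )
        if self.n_bootstrap < 1:
            raise ConfigurationError("n_bootstrap must be >= 1")
        grid = tuple(float(x) for x in self.wtp_grid)
        if not grid:
            raise ConfigurationError("wtp_grid must be non-empty")
        if any(x < 0 for x in grid) or any(b <= a for a, b in zip(grid, grid[1:])):
            raise ConfigurationError("wtp_grid must be non-negative, strictly increasing")
        self.wtp_grid = grid
        if not (0 < self.response_threshold <= 1):
            raise ConfigurationError("response_threshold must lie in (0, 1]")
        if self.pmm_donors < 1:
            raise ConfigurationError("pmm_donors must be >= 1")
        if self.friction_period_days <= 0:
            raise ConfigurationError("friction_period_days must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys {sorted(unknown)}")
        if "wtp_grid" in raw:
            raw["wtp_grid"] = tuple(raw["wtp_grid"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = {f: getattr(self, f) for f in self.__dataclass_fields__}
        d["wtp_grid"] = list(self.wtp_grid)
        return d
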