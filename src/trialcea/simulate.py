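"""Synthetic trial cohorts with the statistical structure the analysis assumes.

The generator emulates a two-arm, three-wave (0/6/12 months) depression
trial: arm- and wave-specific utility trajectories and HDRS-17 declines,
right-skewed zero-inflated cost categories, a Gaussian copula linking a
patient's utility level to their cost level, and blockwise
missing-at-random follow-up driven by a logistic model on arm, gender,
employment and baseline utility.

Default parameters (:func:`SimulationParams.default`) are the shipped
``default_trial.yaml`` and represent a 48-vs-41 patient Dutch
treatment-resistant depression cohort; see ``docs/methods.md`` for what
the generator does and does not emulate.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit
from scipy.stats import gamma as gamma_dist
from scipy.stats import norm

from .schema import (
    ARMS,
    COLUMNS,
    RESOURCE_COLUMNS,
    RECALL_RESOURCE_COLUMNS,
    UnitCostTable,
    ConfigurationError,
    _coerce_dtypes,
)

N_WAVES = 3

#: share of the healthcare euro total attributed to each resource when
#: converting simulated category totals back to resource quantities
HEALTHCARE_SHARES = {
    "gp_contacts": 0.13,
    "mental_care_contacts": 0.70,
    "other_care_contacts": 0.09,
    "home_help_hours": 0.05,
    "medication_days": 0.03,
}


@dataclass
class CostCategoryParams:
    """Zero-inflated gamma parameters per arm, one entry per wave.

    ``mean`` is the overall mean per 4-week window with zeros included;
    the positive part is gamma with coefficient of variation ``cv``.
    """

    mean: Mapping[str, list[float]]
    p_zero: Mapping[str, list[float]]
    cv: Mapping[str, list[float]]

    def validate(self, name: str) -> None:
        for arm in ARMS:
            for key, lo, hi in (("mean", 0.0, np.inf), ("p_zero", 0.0, 1.0), ("cv", 0.0, np.inf)):
                vals = getattr(self, key)[arm]
                if len(vals) != N_WAVES:
                    raise ConfigurationError(f"{name}.{key}[{arm}] needs {N_WAVES} waves")
                if any(not (lo <= v <= hi) for v in vals):
                    raise ConfigurationError(f"{name}.{key}[{arm}] out of range: {vals}")


@dataclass
class MissingnessModel:
    """Per-wave logistic model for skipping an assessment block."""

    intercepts: Mapping[int, float]
    arm_control: Mapping[int, float]
    female: float = 0.0
    employed: float = 0.0
    baseline_utility: float = 0.0
    baseline_utility_center: float = 0.47

    def probability(self, wave: int, is_control, is_female, is_employed, u0) -> np.ndarray:
        eta = (
            self.intercepts[wave]
            + self.arm_control[wave] * np.asarray(is_control, dtype=float)
            + self.female * np.asarray(is_female, dtype=float)
            + self.employed * np.asarray(is_employed, dtype=float)
            + self.baseline_utility * (np.asarray(u0, dtype=float) - self.baseline_utility_center)
        )
        return expit(eta)


@dataclass
class SimulationParams:
    """Full parameterisation of the synthetic cohort generator."""

    n_per_arm: Mapping[str, int]
    female_prob: float
    employment_prob: float
    wage_mean_per_hour: float
    wage_sd_per_hour: float
    min_wage_per_hour: float
    usual_hours_mean: float
    usual_hours_sd: float
    utility_mean: Mapping[str, list[float]]
    utility_sd: Mapping[str, list[float]]
    hdrs_mean: Mapping[str, list[float]]
    hdrs_sd: Mapping[str, list[float]]
    healthcare_cost: CostCategoryParams
    family_help_cost: CostCategoryParams
    travel_cost: CostCategoryParams
    paid_absenteeism_days: CostCategoryParams
    paid_presenteeism_days: CostCategoryParams
    unpaid_absenteeism_days: CostCategoryParams
    unpaid_presenteeism_days: CostCategoryParams
    rtms: Mapping[str, Mapping[str, float]]
    psychotherapy_sessions_mean: Mapping[str, float]
    utility_within_corr: float = 0.6
    hdrs_within_corr: float = 0.6
    cost_within_corr: float = 0.5
    hdrs_utility_corr: float = -0.6
    utility_cost_corr: float = -0.3
    missingness: MissingnessModel = field(
        default_factory=lambda: MissingnessModel(
            intercepts={0: -np.inf, 6: -np.inf, 12: -np.inf},
            arm_control={0: 0.0, 6: 0.0, 12: 0.0},
        )
    )
    seed: int = 0

    _CATEGORY_FIELDS = (
        "healthcare_cost",
        "family_help_cost",
        "travel_cost",
        "paid_absenteeism_days",
        "paid_presenteeism_days",
        "unpaid_absenteeism_days",
        "unpaid_presenteeism_days",
    )

    def __post_init__(self):
        for arm in ARMS:
            if arm not in self.n_per_arm:
                raise ConfigurationError(f"n_per_arm lacks arm {arm!r}")
            if self.n_per_arm[arm] < 2:
                raise ConfigurationError("n_per_arm must be >= 2 per arm")
            for key in ("utility_mean", "utility_sd", "hdrs_mean", "hdrs_sd"):
                vals = getattr(self, key)[arm]
                if len(vals) != N_WAVES:
                    raise ConfigurationError(f"{key}[{arm}] needs {N_WAVES} waves")
            if any(s < 0 for s in self.utility_sd[arm] + self.hdrs_sd[arm]):
                raise ConfigurationError("standard deviations must be >= 0")
        for p in (self.female_prob, self.employment_prob):
            if not 0 <= p <= 1:
                raise ConfigurationError(f"probability {p} outside [0, 1]")
        for name in self._CATEGORY_FIELDS:
            getattr(self, name).validate(name)
        for rho in (
            self.utility_within_corr,
            self.hdrs_within_corr,
            self.cost_within_corr,
        ):
            if not 0 <= rho <= 1:
                raise ConfigurationError("within-patient loadings must lie in [0, 1]")
        for rho in (self.hdrs_utility_corr, self.utility_cost_corr):
            if not -1 <= rho <= 1:
                raise ConfigurationError("copula correlations must lie in [-1, 1]")

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationParams":
        raw = dict(raw)
        for name in cls._CATEGORY_FIELDS:
            entry = raw[name]
            raw[name] = CostCategoryParams(
                mean={a: list(entry[a]["mean"]) for a in ARMS},
                p_zero={a: list(entry[a]["p_zero"]) for a in ARMS},
                cv={a: list(entry[a]["cv"]) for a in ARMS},
            )
        m = raw["missingness"]
        raw["missingness"] = MissingnessModel(
            intercepts={int(k): float(v) for k, v in m["intercepts"].items()},
            arm_control={int(k): float(v) for k, v in m["arm_control"].items()},
            female=float(m.get("female", 0.0)),
            employed=float(m.get("employed", 0.0)),
            baseline_utility=float(m.get("baseline_utility", 0.0)),
            baseline_utility_center=float(m.get("baseline_utility_center", 0.47)),
        )
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationParams":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "SimulationParams":
        """Reference-trial study conditions shipped as ``default_trial.yaml``."""
        with resources.files("trialcea.data").joinpath("default_trial.yaml").open(
            "r", encoding="utf-8"
        ) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _zig_draw(rng, cat: CostCategoryParams, arm: str, wave_idx: int, latent_q, n: int):
    """Zero-inflated gamma draw via a copula quantile ``latent_q``."""
    m = cat.mean[arm][wave_idx]
    p0 = cat.p_zero[arm][wave_idx]
    cv = cat.cv[arm][wave_idx]
    if m <= 0 or p0 >= 1:
        return np.zeros(n)
    mean_pos = m / (1.0 - p0)
    nonzero = rng.random(n) >= p0
    if cv <= 0:
        vals = np.full(n, mean_pos)
    else:
        shape = 1.0 / cv**2
        scale = mean_pos * cv**2
        vals = gamma_dist.ppf(latent_q, shape, scale=scale)
    return np.where(nonzero, vals, 0.0)


def generate_cohort(
    params: SimulationParams, unit_costs: UnitCostTable | None = None
) -> pd.DataFrame:
    """Generate a complete synthetic cohort (no missingness).

    Simulated euro category totals are converted back to resource
    quantities through ``unit_costs`` (default: the shipped table) so
    that the costing module reproduces them.  Reproducible given
    ``params.seed``; per-arm sample moments converge to the requested
    means as n grows.  Utilities are truncated at 1 from above and may
    be negative; costs are non-negative with a point mass at zero.
    """
    if unit_costs is None:
        unit_costs = UnitCostTable.default()
    rng = np.random.default_rng(np.random.SeedSequence([int(params.seed), 0]))

    frames = []
    for arm in ARMS:
        n = int(params.n_per_arm[arm])
        is_ctl = arm == "control"
        female = rng.random(n) < params.female_prob
        employed = rng.random(n) < params.employment_prob
        wage = np.clip(
            rng.normal(params.wage_mean_per_hour, params.wage_sd_per_hour, n),
            params.min_wage_per_hour,
            None,
        )
        wage = np.where(employed, wage, np.nan)
        hours = np.clip(rng.normal(params.usual_hours_mean, params.usual_hours_sd, n), 2.0, 12.0)

        # patient-level latents (Gaussian copula)
        z_u = rng.standard_normal(n)
        r_uc = params.utility_cost_corr
        z_c = r_uc * z_u + np.sqrt(1 - r_uc**2) * rng.standard_normal(n)
        r_hu = params.hdrs_utility_corr
        z_h = r_hu * z_u + np.sqrt(1 - r_hu**2) * rng.standard_normal(n)

        a_u, a_h, a_c = (
            params.utility_within_corr,
            params.hdrs_within_corr,
            params.cost_within_corr,
        )

        per_wave_rows = []
        for w_idx, wave in enumerate((0, 6, 12)):
            mu_u = params.utility_mean[arm][w_idx]
            sd_u = params.utility_sd[arm][w_idx]
            eps = rng.standard_normal(n)
            utility = np.minimum(mu_u + sd_u * (np.sqrt(a_u) * z_u + np.sqrt(1 - a_u) * eps), 1.0)

            mu_h, sd_h = params.hdrs_mean[arm][w_idx], params.hdrs_sd[arm][w_idx]
            eps = rng.standard_normal(n)
            hdrs = np.clip(
                np.rint(mu_h + sd_h * (np.sqrt(a_h) * z_h + np.sqrt(1 - a_h) * eps)), 0, 52
            )

            def cat_q():
                eps = rng.standard_normal(n)
                return norm.cdf(np.sqrt(a_c) * z_c + np.sqrt(1 - a_c) * eps)

            hc_eur = _zig_draw(rng, params.healthcare_cost, arm, w_idx, cat_q(), n)
            help_eur = _zig_draw(rng, params.family_help_cost, arm, w_idx, cat_q(), n)
            travel_eur = _zig_draw(rng, params.travel_cost, arm, w_idx, cat_q(), n)
            pabs = _zig_draw(rng, params.paid_absenteeism_days, arm, w_idx, cat_q(), n)
            ppres = _zig_draw(rng, params.paid_presenteeism_days, arm, w_idx, cat_q(), n)
            uabs = _zig_draw(rng, params.unpaid_absenteeism_days, arm, w_idx, cat_q(), n)
            upres = _zig_draw(rng, params.unpaid_presenteeism_days, arm, w_idx, cat_q(), n)
            pabs = np.where(employed, pabs, 0.0)
            ppres = np.where(employed, ppres, 0.0)

            row = {
                "wave": wave,
                "utility": utility,
                "hdrs17": hdrs,
                "travel_trips": travel_eur / unit_costs.unit_cost("travel_trip"),
                "family_help_hours": help_eur / unit_costs.unit_cost("housekeeping_hour"),
                "paid_absenteeism_days": pabs,
                "paid_presenteeism_days": ppres,
                "unpaid_absenteeism_days": uabs,
                "unpaid_presenteeism_days": upres,
            }
            from .schema import RESOURCE_UNIT_KEYS

            for col, share in HEALTHCARE_SHARES.items():
                row[col] = share * hc_eur / unit_costs.unit_cost(RESOURCE_UNIT_KEYS[col])
            if wave == 6:
                treated = rng.random(n) < params.rtms[arm]["p_treated"]
                row["rtms_sessions"] = np.where(treated, float(params.rtms[arm]["sessions"]), 0.0)
                row["psychotherapy_sessions"] = rng.poisson(
                    params.psychotherapy_sessions_mean[arm], n
                ).astype(float)
            else:
                row["rtms_sessions"] = np.zeros(n)
                row["psychotherapy_sessions"] = np.zeros(n)
            per_wave_rows.append(row)

        prefix = "I" if not is_ctl else "C"
        pids = np.array([f"{prefix}{i:04d}" for i in range(n)])
        for row in per_wave_rows:
            df_w = pd.DataFrame(
                {
                    "patient_id": pids,
                    "arm": arm,
                    "wave": row["wave"],
                    "gender": np.where(female, "female", "male"),
                    "employed": employed,
                    "wage_per_hour": wage,
                    "usual_hours_per_day": hours,
                    "hdrs17": row["hdrs17"],
                    "utility": row["utility"],
                    "eq5d_state": pd.array([pd.NA] * n, dtype="string"),
                }
            )
            for c in RESOURCE_COLUMNS:
                df_w[c] = row[c]
            frames.append(df_w)

    df = pd.concat(frames, ignore_index=True)[list(COLUMNS)]
    df = df.sort_values(["arm", "patient_id", "wave"], ignore_index=True,
                        key=lambda s: s.map({"intervention": 0, "control": 1}) if s.name == "arm" else s)
    return _coerce_dtypes(df)


#: columns masked when a follow-up assessment block is skipped
_FOLLOWUP_BLOCK = ("utility", "eq5d_state", "hdrs17") + RECALL_RESOURCE_COLUMNS
#: baseline block: demographics and baseline HDRS are never masked
_BASELINE_BLOCK = ("utility", "eq5d_state") + RECALL_RESOURCE_COLUMNS


def apply_missingness(df: pd.DataFrame, params: SimulationParams) -> pd.DataFrame:
    """Mask assessment blocks per the logistic missingness model.

    Masking is blockwise per wave: a skipped assessment loses all wave
    outcomes together.  Arm, gender, employment and baseline HDRS are
    never masked; treatment sessions are administrative records and
    survive.  Reproducible given ``params.seed`` (a substream separate
    from cohort generation).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(params.seed), 1]))
    df = df.copy()
    base = df[df["wave"] == 0].set_index("patient_id")
    pids = base.index.to_numpy()
    is_ctl = (base["arm"] == "control").to_numpy()
    is_female = (base["gender"] == "female").to_numpy()
    is_emp = base["employed"].fillna(False).to_numpy(dtype=bool)
    u0 = base["utility"].to_numpy(dtype=float)
    u0 = np.where(np.isnan(u0), params.missingness.baseline_utility_center, u0)

    for wave in (0, 6, 12):
        p = params.missingness.probability(wave, is_ctl, is_female, is_emp, u0)
        mask = rng.random(len(pids)) < p
        if not mask.any():
            continue
        masked_ids = set(pids[mask])
        sel = (df["wave"] == wave) & df["patient_id"].isin(masked_ids)
        block = _BASELINE_BLOCK if wave == 0 else _FOLLOWUP_BLOCK
        for col in block:
            df.loc[sel, col] = pd.NA if col == "eq5d_state" else np.nan
    return df
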