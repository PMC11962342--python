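"""Estimation engine: patient-level bootstrap with nested PMM and SUR.

The pipeline resamples patients with replacement (stratified by arm so
both arms stay populated), runs a fresh predictive-mean-matching
imputation *inside* each replicate, recomputes QALYs,
response/remission and cumulative costs from the completed wave-level
data, and fits the two-equation SUR system per outcome and costing
scenario.  The treatment coefficients of the cost and effect equations
are the replicate's incremental cost and incremental effect.

Randomness is disciplined by one master seed: replicate ``r`` draws
from the substream ``[seed, r]`` and is reproducible in isolation.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import costing
from .costing import PERIODS_PER_YEAR
from .imputation import ImputationError, _pmm_column
from .schema import WAVES, WAVE_TIMES, AnalysisConfig, UnitCostTable
from .sure import EstimationError, sure_fit

#: scenario label -> (perspective, productivity method); the base case is
#: societal/friction, the two sensitivity analyses swap one lever each
SCENARIOS = {
    "societal": ("societal", "friction"),
    "healthcare": ("healthcare", "friction"),
    "human_capital": ("societal", "human_capital"),
}
OUTCOMES = ("qaly", "response", "remission")

#: wide-table layout: statics first, then the imputation-eligible block
_STATIC_COLS = ["treat", "female", "employed", "day_value", "c_int", "h_0"]
_IMPUTE_COLS = (
    ["u_0", "u_6", "u_12", "h_6", "h_12"]
    + [f"hc_{w}" for w in WAVES]
    + [f"inf_{w}" for w in WAVES]
    + [f"pabs_{w}" for w in WAVES]
    + [f"oprod_{w}" for w in WAVES]
)
WIDE_COLUMNS = _STATIC_COLS + _IMPUTE_COLS
#: predictor set for PMM: gender, randomization group, employment, plus
#: utilities, HDRS scores and cost categories at every wave
PMM_PREDICTORS = ["female", "treat", "employed", "h_0"] + _IMPUTE_COLS

_TRAPZ_WEIGHTS = np.array([0.25, 0.5, 0.25])  # waves at 0, 0.5, 1.0 years


def wide_from_long(df: pd.DataFrame, unit_costs: UnitCostTable) -> pd.DataFrame:
    """One row per patient: statics, wave utilities/HDRS and category euros.

    ``c_int`` is the patient's total intervention lump cost (treated as
    an administrative record); recurring categories are euros per 4-week
    window at each wave.  ``pabs``/``oprod`` split productivity into
    paid absenteeism (cappable under the friction method) and the rest.
    """
    wc = costing.wave_cost_frame(df, unit_costs)
    base = df[df["wave"] == 0].set_index("patient_id")
    pids = base.index

    wide = pd.DataFrame(index=pids)
    wide["treat"] = (base["arm"] == "intervention").astype(float)
    wide["female"] = (base["gender"] == "female").astype(float)
    wide["employed"] = base["employed"].fillna(False).astype(float)
    wide["c_int"] = wc.groupby("patient_id")["intervention"].sum().reindex(pids)
    wide["day_value"] = (
        wc[wc["wave"] == 0].set_index("patient_id")["day_value"].reindex(pids).fillna(0.0)
    )

    for src, prefix in (("utility", "u"), ("hdrs17", "h")):
        piv = df.pivot(index="patient_id", columns="wave", values=src).reindex(pids)
        for w in WAVES:
            wide[f"{prefix}_{w}"] = piv[w].astype(float)
    for src, prefix in (
        ("healthcare", "hc"),
        ("informal", "inf"),
        ("paid_absenteeism_eur", "pabs"),
        ("other_productivity_eur", "oprod"),
    ):
        piv = wc.pivot(index="patient_id", columns="wave", values=src).reindex(pids)
        for w in WAVES:
            wide[f"{prefix}_{w}"] = piv[w].astype(float)
    return wide[WIDE_COLUMNS].reset_index().rename(columns={"patient_id": "patient_id"})


@dataclass
class _Derived:
    """Per-patient quantities entering the SUR system."""

    treat: np.ndarray
    qaly: np.ndarray
    response: np.ndarray
    remission: np.ndarray
    baseline_cost: np.ndarray  # societal 4-week euros at wave 0
    u0: np.ndarray
    h0: np.ndarray
    cost: dict  # scenario label -> cumulative 12-month euros


def _derive(mat: np.ndarray, col: dict, config: AnalysisConfig) -> _Derived:
    u = mat[:, [col["u_0"], col["u_6"], col["u_12"]]]
    qaly = u @ _TRAPZ_WEIGHTS
    h0 = mat[:, col["h_0"]]
    h12 = mat[:, col["h_12"]]
    with np.errstate(invalid="ignore", divide="ignore"):
        response = ((h0 - h12) / h0 >= config.response_threshold).astype(float)
    remission = (h12 < config.remission_threshold).astype(float)

    w = _TRAPZ_WEIGHTS * PERIODS_PER_YEAR
    cum = {
        p: mat[:, [col[f"{p}_0"], col[f"{p}_6"], col[f"{p}_12"]]] @ w
        for p in ("hc", "inf", "pabs", "oprod")
    }
    day_value = mat[:, col["day_value"]]
    pabs_capped = np.minimum(cum["pabs"], config.friction_period_days * day_value)
    c_int = mat[:, col["c_int"]]

    cost = {
        "societal": c_int + cum["hc"] + cum["inf"] + pabs_capped + cum["oprod"],
        "healthcare": c_int + cum["hc"],
        "human_capital": c_int + cum["hc"] + cum["inf"] + cum["pabs"] + cum["oprod"],
    }
    baseline_cost = (
        mat[:, col["hc_0"]] + mat[:, col["inf_0"]] + mat[:, col["pabs_0"]] + mat[:, col["oprod_0"]]
    )
    return _Derived(
        treat=mat[:, col["treat"]],
        qaly=qaly,
        response=response,
        remission=remission,
        baseline_cost=baseline_cost,
        u0=mat[:, col["u_0"]],
        h0=h0,
        cost=cost,
    )


def _fit_one(d: _Derived, scenario: str, outcome: str) -> tuple[float, float]:
    """SUR treatment effects (delta cost, delta effect) for one cell."""
    ones = np.ones_like(d.treat)
    X1 = np.column_stack([ones, d.treat, d.baseline_cost])
    if outcome == "qaly":
        y2, base2 = d.qaly, d.u0
    elif outcome == "response":
        y2, base2 = d.response, d.h0
    elif outcome == "remission":
        y2, base2 = d.remission, d.h0
    else:
        raise ValueError(f"unknown outcome {outcome!r}")
    X2 = np.column_stack([ones, d.treat, base2])
    fit = sure_fit(d.cost[scenario], X1, y2, X2)
    return float(fit.beta1[1]), float(fit.beta2[1])


def bootstrap_engine(
    wide: pd.DataFrame,
    config: AnalysisConfig,
    scenarios: tuple[str, ...] | None = None,
    outcomes: tuple[str, ...] | None = None,
    max_failure_fraction: float = 0.01,
) -> pd.DataFrame:
    """Run the PMM-in-bootstrap and return replicate-level estimates.

    Returns a long DataFrame with columns ``replicate``, ``scenario``,
    ``outcome``, ``delta_cost``, ``delta_effect`` and ``converged``.
    Failed replicates are flagged, never silently dropped; the run
    aborts if more than ``max_failure_fraction`` of replicates fail.
    """
    scenarios = tuple(scenarios or SCENARIOS)
    outcomes = tuple(outcomes or OUTCOMES)
    for s in scenarios:
        if s not in SCENARIOS:
            raise ValueError(f"unknown scenario {s!r}")

    mat0 = wide[WIDE_COLUMNS].to_numpy(dtype=float)
    col = {c: i for i, c in enumerate(WIDE_COLUMNS)}
    impute_idx = [col[c] for c in _IMPUTE_COLS]
    predictor_idx = [col[c] for c in PMM_PREDICTORS]
    any_missing = bool(np.isnan(mat0[:, impute_idx]).any())

    arm_rows = [np.flatnonzero(mat0[:, col["treat"]] == 1.0),
                np.flatnonzero(mat0[:, col["treat"]] == 0.0)]
    if any(len(rows) == 0 for rows in arm_rows):
        raise ValueError("both arms must be populated")

    records = []
    n_failed = 0
    B = config.n_bootstrap
    for r in range(B):
        rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), r]))
        idx = np.concatenate(
            [rows[rng.integers(0, len(rows), len(rows))] for rows in arm_rows]
        )
        M = mat0[idx].copy()
        failed = False
        try:
            if any_missing:
                _impute_matrix(M, impute_idx, predictor_idx, config.pmm_donors, rng)
            d = _derive(M, col, config)
            cells = []
            for s in scenarios:
                for o in outcomes:
                    cells.append((s, o) + _fit_one(d, s, o))
        except (EstimationError, ImputationError):
            failed = True
            cells = [(s, o, np.nan, np.nan) for s in scenarios for o in outcomes]
        n_failed += failed
        for s, o, dc, de in cells:
            records.append((r, s, o, dc, de, not failed))

    if n_failed > max_failure_fraction * B:
        raise EstimationError(
            f"{n_failed} of {B} bootstrap replicates failed "
            f"(> {max_failure_fraction:.0%} tolerated)"
        )
    return pd.DataFrame(
        records,
        columns=["replicate", "scenario", "outcome", "delta_cost", "delta_effect", "converged"],
    )


def _impute_matrix(
    M: np.ndarray, impute_idx: list[int], predictor_idx: list[int], k: int,
    rng: np.random.Generator,
) -> None:
    """In-place PMM over the impute-eligible columns of one resample."""
    for j in impute_idx:
        if not np.isnan(M[:, j]).any():
            continue
        use = [c for c in predictor_idx if c != j]
        M[:, j] = _pmm_column(M[:, j], M[:, use], k, rng, name=str(j))


@dataclass
class PointInterval:
    """Bootstrap point estimate (mean) with a 95% percentile interval."""

    estimate: float
    lower: float
    upper: float

    def __iter__(self):
        return iter((self.estimate, self.lower, self.upper))


def point_and_interval(values: np.ndarray) -> PointInterval:
    """Mean and 2.5th/97.5th percentiles (linear interpolation) over
    converged replicates; NaN (flagged) replicates are excluded."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) < 2:
        raise ValueError("need at least two converged replicates")
    lo, hi = np.percentile(v, [2.5, 97.5])
    return PointInterval(estimate=float(v.mean()), lower=float(lo), upper=float(hi))
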