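"""Clinical outcomes: tariff-based utilities, QALYs and response/remission.

Utilities index health-related quality of life (1 = full health, 0 =
dead; negative values — states worse than dead — are permitted by
additive tariffs).  QALYs are the area under the utility-time curve by
linear interpolation; over a one-year horizon with waves at 0, 0.5 and
1.0 years the maximum is 1.0 (0.5 over the first six months).  No
discounting is applied — the horizon is exactly one year.

Depression severity uses the 17-item Hamilton scale (HDRS-17):
*response* is a >= 50% reduction from baseline, *remission* a score
below 8.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import logging

import numpy as np
import pandas as pd
import yaml

from .schema import ARMS, WAVE_TIMES, WAVES, AnalysisConfig, TrialTableError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TariffModel:
    """Additive five-dimension tariff: utility = full health - decrements.

    ``decrements[dim]`` holds the five per-level decrements of one
    dimension; level 1 carries decrement 0 and decrements are
    non-decreasing in level.
    """

    dimensions: tuple[str, ...]
    decrements: dict[str, tuple[float, ...]]
    full_health_value: float = 1.0

    def __post_init__(self):
        if len(self.dimensions) != 5:
            raise ValueError("a tariff has exactly five dimensions")
        for dim in self.dimensions:
            decs = self.decrements[dim]
            if len(decs) != 5:
                raise ValueError(f"dimension {dim!r} needs five level decrements")
            if decs[0] != 0.0:
                raise ValueError(f"dimension {dim!r}: level-1 decrement must be 0")
            if any(b < a for a, b in zip(decs, decs[1:])):
                raise ValueError(f"dimension {dim!r}: decrements must be non-decreasing")
            if any(d < 0 for d in decs):
                raise ValueError(f"dimension {dim!r}: decrements must be >= 0")

    def utility(self, state: Sequence[int] | str) -> float:
        """Index value of a five-level health state such as ``"21123"``."""
        levels = [int(c) for c in state] if isinstance(state, str) else [int(x) for x in state]
        if len(levels) != 5 or any(not 1 <= lv <= 5 for lv in levels):
            raise ValueError(f"state {state!r} must be five levels in 1-5")
        total = sum(self.decrements[dim][lv - 1] for dim, lv in zip(self.dimensions, levels))
        return self.full_health_value - total

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TariffModel":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(
            dimensions=tuple(raw["dimensions"]),
            decrements={d: tuple(float(x) for x in raw["decrements"][d]) for d in raw["dimensions"]},
            full_health_value=float(raw.get("full_health_value", 1.0)),
        )

    @classmethod
    def synthetic(cls) -> "TariffModel":
        """The shipped synthetic illustrative tariff (not a national value set)."""
        with resources.files("trialcea.data").joinpath("synthetic_tariff.yaml").open(
            "r", encoding="utf-8"
        ) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            dimensions=tuple(raw["dimensions"]),
            decrements={d: tuple(float(x) for x in raw["decrements"][d]) for d in raw["dimensions"]},
            full_health_value=float(raw.get("full_health_value", 1.0)),
        )


def utility_from_state(state: Sequence[int] | str, tariff: TariffModel) -> float:
    """Tariff value of an EQ-5D-5L state (full health minus decrements)."""
    return tariff.utility(state)


def qaly_auc(utilities: Sequence[float], times: Sequence[float]) -> float:
    """QALYs by trapezoidal area under the utility curve.

    ``times`` are in years and must be strictly increasing.  Missing
    (NaN) utilities are dropped pairwise; with fewer than two remaining
    points the QALY is not computable and NaN is returned (imputation
    upstream is responsible for filling the gap — a missing QALY is
    never defaulted to a number here).
    """
    u = np.asarray(utilities, dtype=float)
    t = np.asarray(times, dtype=float)
    if u.shape != t.shape:
        raise ValueError("utilities and times must have equal length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    keep = ~np.isnan(u)
    u, t = u[keep], t[keep]
    if len(u) < 2:
        return float("nan")
    return float(np.trapezoid(u, t))


def classify_response(baseline_hdrs: float, followup_hdrs: float, threshold: float = 0.5):
    """True iff the HDRS-17 score fell by at least ``threshold`` (fraction).

    Missing follow-up yields ``None`` (unknown), never ``False``.
    """
    if baseline_hdrs is None or np.isnan(baseline_hdrs) or baseline_hdrs <= 0:
        raise ValueError("baseline HDRS must be a positive score")
    if followup_hdrs is None or np.isnan(followup_hdrs):
        return None
    return bool((baseline_hdrs - followup_hdrs) / baseline_hdrs >= threshold)


def classify_remission(followup_hdrs: float, threshold: float = 8.0):
    """True iff the follow-up HDRS-17 score is strictly below ``threshold``."""
    if followup_hdrs is None or np.isnan(followup_hdrs):
        return None
    return bool(followup_hdrs < threshold)


def resolve_utilities(df: pd.DataFrame, tariff: TariffModel | None = None) -> pd.DataFrame:
    """Fill the utility column from EQ-5D-5L states where needed.

    Where both a utility and a state are present the utility wins and a
    warning is logged; states only matter when utilities were not
    supplied directly.
    """
    df = df.copy()
    has_state = df["eq5d_state"].notna()
    both = has_state & df["utility"].notna()
    if both.any():
        log.warning(
            "%d records carry both a utility and an EQ-5D state; keeping the utility",
            int(both.sum()),
        )
    need = has_state & df["utility"].isna()
    if need.any():
        if tariff is None:
            raise ValueError("cohort carries EQ-5D states but no tariff was supplied")
        df.loc[need, "utility"] = [
            tariff.utility(s) for s in df.loc[need, "eq5d_state"]
        ]
    return df


def patient_outcomes(df: pd.DataFrame, config: AnalysisConfig | None = None,
                     tariff: TariffModel | None = None) -> pd.DataFrame:
    """Per-patient outcomes from a validated long cohort.

    Returns one row per patient: QALYs over 0-6 and 0-12 months
    (computed only when every involved wave is observed, otherwise
    missing), response/remission indicators at 6 and 12 months (nullable
    booleans) and baseline utility/HDRS.
    """
    config = config or AnalysisConfig()
    df = resolve_utilities(df, tariff)
    wide_u = df.pivot(index="patient_id", columns="wave", values="utility")
    wide_h = df.pivot(index="patient_id", columns="wave", values="hdrs17").astype(float)
    base = df[df["wave"] == 0].set_index("patient_id")

    t = np.array([WAVE_TIMES[w] for w in WAVES])
    u = wide_u[list(WAVES)].to_numpy(dtype=float)
    qaly_6 = np.where(
        np.isnan(u[:, :2]).any(axis=1), np.nan, np.trapezoid(u[:, :2], t[:2], axis=1)
    )
    qaly_12 = np.where(np.isnan(u).any(axis=1), np.nan, np.trapezoid(u, t, axis=1))

    h = wide_h[list(WAVES)].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel_drop = (h[:, [0]] - h[:, 1:]) / h[:, [0]]
    resp = rel_drop >= config.response_threshold
    rem = h[:, 1:] < config.remission_threshold
    missing_follow = np.isnan(h[:, 1:]) | np.isnan(h[:, [0]])

    out = pd.DataFrame(
        {
            "patient_id": wide_u.index,
            "arm": base.loc[wide_u.index, "arm"].to_numpy(),
            "qaly_6m": qaly_6,
            "qaly_12m": qaly_12,
            "response_6m": _nullable_bool(resp[:, 0], missing_follow[:, 0]),
            "response_12m": _nullable_bool(resp[:, 1], missing_follow[:, 1]),
            "remission_6m": _nullable_bool(rem[:, 0], missing_follow[:, 0]),
            "remission_12m": _nullable_bool(rem[:, 1], missing_follow[:, 1]),
            "baseline_utility": u[:, 0],
            "baseline_hdrs": h[:, 0],
        }
    ).reset_index(drop=True)
    return out


def _nullable_bool(values: np.ndarray, missing: np.ndarray) -> pd.array:
    arr = pd.array(values, dtype="boolean")
    arr[missing] = pd.NA
    return arr


def cohort_outcomes(
    df: pd.DataFrame,
    config: AnalysisConfig | None = None,
    tariff: TariffModel | None = None,
    denominator: str = "randomized",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-patient outcomes plus a per-arm summary table.

    ``denominator`` selects the convention for response/remission rates:
    ``"randomized"`` divides positive counts by the full randomized arm
    (missing counted as non-response, the intention-to-treat reading of
    published rate tables); ``"observed"`` divides by the non-missing
    count.  The summary mirrors the usual trial table: mean, SD, median,
    min, max and missing count per arm and wave for HDRS-17, utilities
    and QALYs, plus response/remission counts and rates.
    """
    if denominator not in ("randomized", "observed"):
        raise ValueError(f"unknown denominator convention {denominator!r}")
    outcomes = patient_outcomes(df, config, tariff)
    rows = []
    for arm in ARMS:
        sub = outcomes[outcomes["arm"] == arm]
        n_arm = len(sub)
        for wave in WAVES:
            raw = df[(df["arm"] == arm) & (df["wave"] == wave)]
            for var, series in (("hdrs17", raw["hdrs17"].astype(float)),
                                ("utility", raw["utility"])):
                rows.append(_summary_row(arm, wave, var, series, n_arm))
        for wave, qcol in ((6, "qaly_6m"), (12, "qaly_12m")):
            rows.append(_summary_row(arm, wave, qcol, sub[qcol], n_arm))
        for wave, suffix in ((6, "6m"), (12, "12m")):
            for kind in ("response", "remission"):
                ind = sub[f"{kind}_{suffix}"]
                n_pos = int((ind == True).sum())  # noqa: E712  (nullable boolean)
                n_obs = int(ind.notna().sum())
                denom = n_arm if denominator == "randomized" else n_obs
                rows.append(
                    {
                        "arm": arm,
                        "wave": wave,
                        "variable": kind,
                        "count": n_pos,
                        "n": denom,
                        "rate": n_pos / denom if denom else np.nan,
                        "n_missing": n_arm - n_obs,
                    }
                )
    return outcomes, pd.DataFrame(rows)


def _summary_row(arm: str, wave: int, var: str, series: pd.Series, n_arm: int) -> dict:
    vals = pd.to_numeric(series, errors="coerce").astype(float)
    obs = vals.dropna()
    return {
        "arm": arm,
        "wave": wave,
        "variable": var,
        "mean": obs.mean() if len(obs) else np.nan,
        "sd": obs.std(ddof=1) if len(obs) > 1 else np.nan,
        "median": obs.median() if len(obs) else np.nan,
        "min": obs.min() if len(obs) else np.nan,
        "max": obs.max() if len(obs) else np.nan,
        "n_missing": int(n_arm - len(obs)),
        "n": n_arm,
    }
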