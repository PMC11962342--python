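"""Decision quantities: ICER/ICUR with dominance, CE planes and CEACs.

Conventions (fixed for reproducibility; ties have measure ~0 with
continuous bootstrap estimates):

* quadrants of the cost-effectiveness plane — NE: dE > 0, dC > 0;
  SE: dE > 0, dC <= 0; SW: dE <= 0, dC <= 0; NW: dE <= 0, dC > 0;
* a replicate is cost-effective at willingness-to-pay lambda iff its
  incremental net monetary benefit lambda*dE - dC is strictly positive;
* "dominant" means lower costs and higher effects (dC < 0, dE > 0),
  "dominated" the reverse; only otherwise is the ratio dC/dE reported.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import metadata
from pathlib import Path

import numpy as np
import pandas as pd

from . import costing, inference, outcomes as outcomes_mod
from .inference import OUTCOMES, SCENARIOS, PointInterval, bootstrap_engine, point_and_interval
from .schema import AnalysisConfig, UnitCostTable, read_trial_table, validate_cohort

QUADRANTS = ("NE", "SE", "SW", "NW")


@dataclass(frozen=True)
class IcerLabel:
    """ICER/ICUR as a dominance label or a ratio in euros per effect unit."""

    kind: str  # dominant | dominated | ratio | undefined
    value: float | None = None

    def __str__(self) -> str:
        if self.kind == "ratio":
            return f"{self.value:.0f} EUR per effect unit"
        return self.kind


def icer(delta_cost: float, delta_effect: float) -> IcerLabel:
    """Classify the incremental cost-effectiveness ratio.

    Lower costs with higher effects are *dominant* (no ratio reported);
    higher costs with lower effects are *dominated*; a zero incremental
    effect makes the ratio undefined.
    """
    if not (np.isfinite(delta_cost) and np.isfinite(delta_effect)):
        raise ValueError("incremental cost and effect must be finite")
    if delta_effect == 0:
        return IcerLabel("undefined")
    if delta_cost < 0 and delta_effect > 0:
        return IcerLabel("dominant")
    if delta_cost > 0 and delta_effect < 0:
        return IcerLabel("dominated")
    return IcerLabel("ratio", delta_cost / delta_effect)


def quadrant_distribution(delta_effect: np.ndarray, delta_cost: np.ndarray) -> dict[str, float]:
    """Shares of replicates per CE-plane quadrant; shares sum to 1."""
    de = np.asarray(delta_effect, dtype=float)
    dc = np.asarray(delta_cost, dtype=float)
    keep = ~(np.isnan(de) | np.isnan(dc))
    de, dc = de[keep], dc[keep]
    if len(de) == 0:
        raise ValueError("need at least one replicate")
    n = len(de)
    return {
        "NE": float(np.sum((de > 0) & (dc > 0)) / n),
        "SE": float(np.sum((de > 0) & (dc <= 0)) / n),
        "SW": float(np.sum((de <= 0) & (dc <= 0)) / n),
        "NW": float(np.sum((de <= 0) & (dc > 0)) / n),
    }


def ceac(delta_effect: np.ndarray, delta_cost: np.ndarray, wtp_grid) -> np.ndarray:
    """Probability of a positive net monetary benefit per WTP value."""
    de = np.asarray(delta_effect, dtype=float)
    dc = np.asarray(delta_cost, dtype=float)
    keep = ~(np.isnan(de) | np.isnan(dc))
    de, dc = de[keep], dc[keep]
    grid = np.asarray(list(wtp_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("wtp_grid must be non-empty")
    nmb = grid[:, None] * de[None, :] - dc[None, :]
    return (nmb > 0).mean(axis=1)


@dataclass
class CEResult:
    """Decision summary for one outcome x costing scenario."""

    outcome: str
    scenario: str
    perspective: str
    productivity_method: str
    delta_cost: PointInterval
    delta_effect: PointInterval
    icer_label: IcerLabel
    quadrant_shares: dict[str, float]
    ceac: dict[float, float]
    prob_at_reference_wtp: float
    n_replicates: int


def summarize_replicates(replicates: pd.DataFrame, config: AnalysisConfig) -> list[CEResult]:
    """Turn the replicate table into one :class:`CEResult` per cell."""
    results = []
    for (scenario, outcome), sub in replicates.groupby(["scenario", "outcome"], sort=False):
        ok = sub[sub["converged"]]
        dc = ok["delta_cost"].to_numpy()
        de = ok["delta_effect"].to_numpy()
        pc = point_and_interval(dc)
        pe = point_and_interval(de)
        curve = ceac(de, dc, config.wtp_grid)
        ref = float(ceac(de, dc, [config.wtp_reference])[0])
        persp, method = SCENARIOS[scenario]
        results.append(
            CEResult(
                outcome=outcome,
                scenario=scenario,
                perspective=persp,
                productivity_method=method,
                delta_cost=pc,
                delta_effect=pe,
                icer_label=icer(pc.estimate, pe.estimate),
                quadrant_shares=quadrant_distribution(de, dc),
                ceac=dict(zip((float(x) for x in config.wtp_grid), curve.tolist())),
                prob_at_reference_wtp=ref,
                n_replicates=int(len(ok)),
            )
        )
    return results


def results_table(results: list[CEResult]) -> pd.DataFrame:
    """The base-case + sensitivity grid as one row per outcome x scenario."""
    rows = []
    for r in results:
        rows.append(
            {
                "outcome": r.outcome,
                "scenario": r.scenario,
                "perspective": r.perspective,
                "productivity_method": r.productivity_method,
                "delta_cost": r.delta_cost.estimate,
                "delta_cost_lower": r.delta_cost.lower,
                "delta_cost_upper": r.delta_cost.upper,
                "delta_effect": r.delta_effect.estimate,
                "delta_effect_lower": r.delta_effect.lower,
                "delta_effect_upper": r.delta_effect.upper,
                "icer": str(r.icer_label),
                "NE_pct": 100 * r.quadrant_shares["NE"],
                "SE_pct": 100 * r.quadrant_shares["SE"],
                "SW_pct": 100 * r.quadrant_shares["SW"],
                "NW_pct": 100 * r.quadrant_shares["NW"],
                "prob_ce_at_reference_wtp": r.prob_at_reference_wtp,
                "n_replicates": r.n_replicates,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class AnalysisBundle:
    """Everything one full run produces."""

    config: AnalysisConfig
    outcome_summary: pd.DataFrame
    cost_summary: pd.DataFrame
    replicates: pd.DataFrame
    results: list[CEResult]
    table: pd.DataFrame
    ceac_curves: pd.DataFrame
    log: dict


def run_analysis(
    cohort: str | Path | pd.DataFrame,
    config: AnalysisConfig | None = None,
    unit_costs: UnitCostTable | None = None,
    tariff=None,
    out_dir: str | Path | None = None,
) -> AnalysisBundle:
    """End-to-end evaluation: outcomes, costs, bootstrap, decision grid.

    Produces, for each outcome (QALY / response / remission) and each
    costing scenario (societal base case, healthcare perspective,
    human-capital productivity), the adjusted incremental cost and
    effect with percentile intervals, the dominance label, CE-plane
    quadrant shares and the CEAC.  When ``out_dir`` is given, the
    tables, plot-ready point sets and a run log (master seed, config
    hash, software version) are written there as delimited text.
    """
    config = config or AnalysisConfig()
    if unit_costs is None:
        unit_costs = UnitCostTable.default(cpi_factor=config.cpi_factor)
    df = cohort if isinstance(cohort, pd.DataFrame) else read_trial_table(cohort)
    df = outcomes_mod.resolve_utilities(df, tariff)

    report = validate_cohort(df)
    _, outcome_summary = outcomes_mod.cohort_outcomes(df, config)
    cost_summary = costing.cost_summary(df, unit_costs)

    wide = inference.wide_from_long(df, unit_costs)
    replicates = bootstrap_engine(wide, config)
    results = summarize_replicates(replicates, config)
    table = results_table(results)

    curves = []
    for r in results:
        for wtp, p in r.ceac.items():
            curves.append(
                {"outcome": r.outcome, "scenario": r.scenario, "wtp": wtp, "probability": p}
            )
    ceac_curves = pd.DataFrame(curves)

    cfg = config.to_dict()
    log = {
        "seed": config.seed,
        "n_bootstrap": config.n_bootstrap,
        "arm_sizes": report.arm_sizes,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "config": cfg,
        "version": _package_version(),
    }

    bundle = AnalysisBundle(
        config=config,
        outcome_summary=outcome_summary,
        cost_summary=cost_summary,
        replicates=replicates,
        results=results,
        table=table,
        ceac_curves=ceac_curves,
        log=log,
    )
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


def _package_version() -> str:
    try:
        return metadata.version("trialcea")
    except metadata.PackageNotFoundError:
        return "unknown"


_FLOAT_FMT = "%.10g"


def write_bundle(bundle: AnalysisBundle, out_dir: str | Path) -> None:
    """Write the result tables, CE-plane/CEAC point sets and run log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.outcome_summary.to_csv(out / "outcome_summary.csv", index=False, float_format=_FLOAT_FMT)
    bundle.cost_summary.to_csv(out / "cost_summary.csv", index=False, float_format=_FLOAT_FMT)
    bundle.table.to_csv(out / "ce_results.csv", index=False, float_format=_FLOAT_FMT)
    bundle.ceac_curves.to_csv(out / "ceac.csv", index=False, float_format=_FLOAT_FMT)
    bundle.replicates.to_csv(out / "ce_plane.csv", index=False, float_format=_FLOAT_FMT)
    with open(out / "run_log.json", "w", encoding="utf-8") as fh:
        json.dump(bundle.log, fh, indent=2, sort_keys=True)


def render_plots(out_dir: str | Path) -> list[Path]:
    """Render CE-plane and CEAC figures from a written result directory.

    The delimited point sets are the tested surface; the images are a
    convenience for reports.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    plane = pd.read_csv(out / "ce_plane.csv")
    curves = pd.read_csv(out / "ceac.csv")
    written = []
    for outcome in plane["outcome"].unique():
        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
        base = plane[(plane["outcome"] == outcome) & (plane["scenario"] == "societal")]
        ax1.scatter(base["delta_effect"], base["delta_cost"], s=6, alpha=0.4)
        ax1.axhline(0, color="grey", lw=0.8)
        ax1.axvline(0, color="grey", lw=0.8)
        ax1.set_xlabel(f"incremental {outcome}")
        ax1.set_ylabel("incremental cost (EUR)")
        ax1.set_title("cost-effectiveness plane (societal)")
        for scenario, sub in curves[curves["outcome"] == outcome].groupby("scenario"):
            ax2.plot(sub["wtp"], sub["probability"], label=scenario)
        ax2.set_xlabel("willingness to pay (EUR per effect unit)")
        ax2.set_ylabel("P(cost-effective)")
        ax2.set_ylim(0, 1)
        ax2.legend(fontsize=8)
        ax2.set_title("acceptability curve")
        fig.tight_layout()
        path = out / f"ce_{outcome}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
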