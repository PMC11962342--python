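# trialcea

Trial-based cost-utility analysis for two-arm randomized trials with a
baseline and two follow-up waves — the design used when a new treatment
(here: repetitive transcranial magnetic stimulation plus psychotherapy
for treatment-resistant depression) is compared against usual care
(the next pharmacological step) on both health outcomes and societal
costs over one year.

It is written for health-economics analysts who have patient-level
trial tables (EQ-5D-5L utilities or states, HDRS-17 depression scores,
and 4-week-recall resource use at months 0, 6 and 12) and want the
standard trial-based economic evaluation: adjusted incremental costs
and effects with bootstrap uncertainty, cost-effectiveness planes and
acceptability curves. A synthetic cohort generator with the same
statistical structure ships with the package, so the entire pipeline is
testable — and demonstrable — without access to patient data.

## The method

For patient *i* with utilities $u_{i,t}$ at $t \in \{0, 0.5, 1\}$ years,
QALYs are the area under the linearly interpolated utility curve,
$\mathrm{QALY}_i = \sum_t \tfrac{\Delta t}{2}(u_{i,t}+u_{i,t+1})$
(maximum 1.0 over twelve months; negative utilities — states worse than
dead — are allowed). Response is a ≥ 50% HDRS-17 reduction from
baseline; remission is a score < 8.

Costs come in four categories: intervention (bottom-up session
costing), healthcare utilization, informal care, and productivity
losses (friction-cost method by default, human-capital method as a
sensitivity analysis). Recurring categories are measured as euros per
4-week window; cumulative 12-month costs integrate the piecewise-linear
rate over the year (13.04 four-week periods) and add intervention lump
sums. The societal perspective sums all four categories; the healthcare
perspective keeps intervention + healthcare only.

Inference follows the nested-resampling recipe for trial-based economic
evaluations with missing data:

1. resample patients with replacement, stratified by arm (non-parametric
   bootstrap, default B = 5000);
2. inside each replicate, impute missing wave-level utilities, HDRS
   scores and cost categories by predictive mean matching (donors drawn
   from nearest predicted means; every imputed value is an observed
   value), then recompute QALYs, response/remission and cumulative costs;
3. fit a two-equation seemingly-unrelated-regression system by feasible
   GLS — cost on treatment + baseline cost, effect on treatment +
   baseline utility (or baseline HDRS) — so that correlated cost/effect
   errors and baseline imbalance are handled jointly; the treatment
   coefficients are the replicate's $\Delta C$ and $\Delta E$.

The replicate cloud yields percentile intervals, the incremental
cost-effectiveness/utility ratio with dominance classification
($\Delta C<0, \Delta E>0$ ⇒ *dominant*), CE-plane quadrant shares, and
the acceptability curve $\mathrm{CEAC}(\lambda) =
P(\lambda\,\Delta E - \Delta C > 0)$ over a willingness-to-pay grid.

## Worked example

```bash
trialcea simulate --seed 7 -o cohort.csv        # 48 vs 41 patients, 20-40% follow-up missingness
trialcea analyze cohort.csv --seed 1 --bootstrap 1000 -o results
trialcea report results                          # render CE-plane / CEAC figures
```

which prints

```
wrote 267 records to cohort.csv
base case (societal, QALYs): dC = 1005 EUR (-3003; 4321), dE = 0.0340 (-0.0229; 0.0930), ICUR: 29602 EUR per effect unit, P(CE at 50000 EUR/QALY) = 0.60
```

Read: on this simulated cohort the intervention cost on average €1,005
more per patient over the year (95% percentile interval −€3,003 to
€4,321 — the cost difference is indistinguishable from zero at n = 89)
and produced 0.034 extra QALYs, for an incremental cost-utility ratio
of about €29,600 per QALY; at a willingness-to-pay of €50,000 per QALY
the intervention is cost-effective in 60% of bootstrap replicates.
`results/ce_results.csv` holds the full 3-outcome × 3-scenario grid
(societal and healthcare perspectives, human-capital sensitivity),
`ceac.csv` and `ce_plane.csv` the plot-ready point sets, and
`run_log.json` the master seed and config hash; reruns with the same
seed are byte-identical.

Library use mirrors the CLI:

```python
import trialcea as t

params = t.SimulationParams.default()      # reference-trial study conditions
cohort = t.apply_missingness(t.generate_cohort(params), params)
bundle = t.run_analysis(cohort, t.AnalysisConfig(n_bootstrap=5000, seed=1))
print(bundle.table)                        # 9-row decision grid
```

The trial-table column dictionary is in `docs/column_dictionary.md`;
the model, parameter and design notes are in `docs/methods.md`.

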