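# Methods

## Scope and model

`trialcea` implements a patient-level economic evaluation alongside a
two-arm randomized trial with assessments at 0, 6 and 12 months: a
cost-utility analysis (QALYs) and cost-effectiveness analyses (response
and remission on the HDRS-17) from a societal perspective, with a
healthcare-perspective and a human-capital-method sensitivity analysis.
The time horizon is exactly one year, so no discounting is applied
anywhere.

Internally time is measured in years (waves at 0, 0.5, 1.0); month
labels exist only at the I/O boundary. QALYs are per-year quantities
and the trapezoid weights over the three waves are (0.25, 0.5, 0.25).

## Utilities and clinical outcomes

Utilities may be supplied directly or derived from EQ-5D-5L states via
an additive tariff (full-health value minus one decrement per
dimension-level). The package ships a *synthetic* illustrative tariff
whose decrements have the structural properties of a real value set
(zero at level 1, monotone in level, worst state below 0) but are not a
published national tariff; users supply their own for real analyses.
Although utilities are often described as ranging from 0 to 1, additive
tariffs produce negative values for severe states; the implementation
permits them and only enforces the upper bound of 1.

Response is a ≥ 50% relative HDRS-17 reduction from baseline (the
threshold is configurable as a fraction); remission is a score strictly
below 8 (configurable). A missing follow-up score yields a *missing*
indicator, never `False`.

Per-arm summary rates are reported, by default, with the full
randomized arm as denominator (missing counted as non-response), the
intention-to-treat convention used in published trial tables; an
observed-case denominator is available. The inference pipeline does not
use either convention — it imputes wave-level scores and recomputes the
indicators.

## Costing

Four categories per patient:

* **intervention** — stimulation and psychotherapy sessions costed
  bottom-up (counts × unit price). Session counts are treated as
  administrative records: they are costed as lump sums for the elapsed
  period and are never subject to questionnaire missingness.
* **healthcare utilization** — contacts, home help and medication days
  × unit prices.
* **informal care** — family/friends help hours at the housekeeping
  shadow price, plus travel.
* **productivity** — absenteeism and presenteeism days, paid and
  unpaid. A lost paid day is valued at the patient's wage × usual
  daily hours; presenteeism enters as efficiency-equivalent lost days
  (the efficiency fraction is applied upstream in the questionnaire,
  not inferred here); unpaid work is valued at the housekeeping shadow
  price.

Unit costs live in a small table (euros per unit at a reference price
year) and are scaled exactly once, at load, by a consumer-price-index
factor.

**Cumulative 12-month costs.** Recurring categories are observed as
euros per 4-week recall window at three waves. The package treats the
per-window cost as a piecewise-linear function of time through the
wave measurements and integrates it over the year, scaled by 13.04
four-week periods per year — the same linear-interpolation convention
as the QALY area under the curve, and an auditable answer to a question
the wave design leaves open (how three 4-week snapshots become an
annual total). Intervention lump sums are added in the period they
occur. A category with any missing wave is missing cumulatively;
imputation happens upstream, never by silent zero-filling.

**Friction vs human capital.** The friction-cost method values paid
absence only up to the friction period (default 85 working days, the
conventional Dutch figure; configurable), the human-capital method
values the entire absence. Because a single 4-week window can never
exceed the friction period, the cap is applied to the *integrated
annual* paid-absence duration (in days, converted through the
patient's day value); a per-window cap would make the two methods
always coincide. Presenteeism and unpaid absence are not capped — no
replacement-worker argument applies to them. Friction costs therefore
never exceed human-capital costs, with equality whenever no patient's
cumulative absence exceeds the friction period.

## Missing data and inference

Missingness in such trials is heavy (20–40% per follow-up wave) and
blockwise — a skipped assessment loses the whole wave battery. The
estimation engine handles it with single imputation by **predictive
mean matching nested inside a non-parametric bootstrap**:

1. patients are resampled with replacement, stratified by arm.
   Stratification is a deliberate strengthening of plain resampling: at
   n ≈ 45 per arm, unstratified draws can produce nearly-empty arms and
   degenerate regressions.
2. within each replicate, every wave-level variable with missing cells
   (utilities, follow-up HDRS, the three recurring cost categories per
   wave, split into paid-absenteeism euros and other productivity
   euros) is imputed by PMM: a linear prediction on the predictor set
   (gender, randomization group, employment, plus all wave-level
   utilities, HDRS scores and cost categories), donors = the
   `pmm_donors` (default 5, standard practice) observed cases with
   nearest predictions, one donor's observed value copied at random.
   Imputed values are always values actually observed, which respects
   zero-inflation and skew. Predictors that are themselves missing are
   mean-filled when the design matrix is built — a single-pass
   simplification chosen over chained iteration for determinism and
   speed inside thousands of replicates.
3. QALYs, response/remission and cumulative costs are recomputed from
   the completed wave-level data (imputing inputs and re-deriving
   outcomes, rather than imputing the derived outcomes directly).
4. a two-equation SUR system is fitted by two-step feasible GLS:
   cumulative cost on treatment + baseline 4-week societal cost;
   outcome on treatment + baseline utility (QALYs) or baseline HDRS
   (response/remission, as a linear probability model). The treatment
   coefficients are the replicate's incremental cost and effect.

Point estimates are replicate means; intervals are 2.5th/97.5th
percentiles (linear interpolation). Percentile rather than BCa
intervals match the simple bootstrap design. Replicate-level estimation
failures (e.g. a degenerate all-zero remission equation in a tiny
resample) are flagged and excluded from summaries, and the run aborts
if more than 1% of replicates fail.

Randomness discipline: one master seed; replicate *r* draws from the
seed-sequence substream `[seed, r]`, so any replicate is reproducible
in isolation and runs are byte-identical given the seed.

Numerical notes: the residual covariance uses denominator *n*; with
identical regressor matrices two-step FGLS reproduces OLS exactly
(asserted to 1e-10 in the tests, against an explicit Kronecker-algebra
oracle to 1e-8 on a hand-built system). Singular designs raise rather
than limp.

## Decision outputs

For each outcome × scenario cell: the ICER/ICUR with dominance
classification (ΔC < 0 and ΔE > 0 ⇒ dominant, no ratio reported;
ΔE = 0 ⇒ explicitly undefined), CE-plane quadrant shares with the
boundary convention NE: ΔE>0, ΔC>0; SE: ΔE>0, ΔC≤0; SW: ΔE≤0, ΔC≤0;
NW: ΔE≤0, ΔC>0, and the CEAC, where a replicate counts as
cost-effective iff its net monetary benefit λ·ΔE − ΔC is strictly
positive (ties count as not cost-effective; with continuous estimates
they have measure zero — the convention is stated for reproducibility).
Consequently CEAC(0) equals the share of replicates with ΔC < 0 and
CEAC(λ→∞) tends to the share with ΔE > 0.

The default willingness-to-pay grid runs from €0 to €80,000 in €1,000
steps with a €50,000/QALY reference value — the Dutch threshold for
high-burden conditions; for response and remission the axis reads as
euros per additional responder/remitter. The grid is configuration,
not a claim about any particular published figure.

The delimited outputs (decision grid, CEAC points, replicate cloud) are
the tested surface; rendered figures are a convenience.

## The synthetic cohort generator

The generator exists so that every downstream stage is testable without
patient data. Its default parameters describe a 48-vs-41 patient Dutch
treatment-resistant depression trial: arm × wave utility means rising
from ≈ 0.475/0.463 at baseline to ≈ 0.678/0.515 at twelve months (SDs
0.22–0.29), HDRS-17 falling from ≈ 21.6/21.2 to ≈ 12.1/13.4, heavily
right-skewed zero-inflated cost categories (zero-inflated gamma; many
categories have SD > mean), ≈ 40% employment, two-thirds female, 25
stimulation sessions in the intervention arm and a 58% chance of
crossover stimulation in the control arm during naturalistic follow-up.

Dependence is induced by a Gaussian copula: per-patient latents for
utility level, HDRS level and cost level, with within-patient loadings
(0.5–0.6) giving serial correlation across waves, a −0.6
utility–HDRS coupling and a −0.3 utility–cost coupling (sicker
patients cost more). The copula parameters and the missingness-model
coefficients are *not* estimates from any dataset — no such
correlations are published — they are plausible values fixed once and
labelled synthetic.

Missingness is blockwise per wave via a logistic model on arm, gender,
employment and (centered) baseline utility, with intercepts set to give
≈ 2% at baseline and ≈ 23–29% / 27–37% (intervention/control) at the
follow-ups. Baseline demographics and baseline HDRS are never masked.

What the generator does **not** emulate: individual EQ-5D-5L dimension
profiles (it draws utilities directly), questionnaire line items beyond
the category totals the analysis consumes, within-category resource
composition (healthcare euros are split across resources by fixed
shares), truncation of baseline severity at trial-entry thresholds,
informative (not-at-random) dropout, and the real joint distribution of
wages, employment and illness. Passing tests therefore demonstrate that
the *pipeline* is correct under a realistic data-generating process,
not that any particular clinical conclusion holds in real data.

## Problem sizes in the test suite

The suite verifies parameter recovery on a 2,000-per-arm cohort with a
built-in incremental effect (ΔQALY = +0.05, ΔC = −€1,000 injected at
follow-up only, so the baseline-adjusted estimand equals the raw
contrast) at 200 bootstrap replicates, and percentile-interval coverage
over 200 cohorts of 100 per arm at 250 replicates — sizes chosen to
make Monte-Carlo error small relative to the assertions while keeping
the default test run fast. The end-to-end check runs the reference-trial
48-vs-41 cohort with missingness through 500 replicates twice and
asserts determinism.

## Known limitations

* Response/remission enter the SUR system as linear probability
  models; a logistic link inside SUR is out of scope and rare in this
  literature, but predicted incremental probabilities are not
  constrained to [−1, 1] in pathological replicates.
* Single-pass PMM with mean-filled predictors is cruder than chained
  multiple imputation; it is the price of nesting a full imputation in
  every bootstrap replicate. Rubin-style multiple imputation with
  pooling is deliberately not implemented — the bootstrap carries the
  uncertainty.
* The friction-period cap operates on integrated annual absence, not
  on spells, because spell structure is invisible in 4-week recall
  windows.
* Exactly three waves are supported end-to-end; the wave set is
  declared in one place but the interpolation logic assumes the
  0/6/12-month design.
* No lifetime extrapolation, Markov modelling or value-of-information
  analysis.
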