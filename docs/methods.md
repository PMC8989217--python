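# Methods

## Model structure and assumptions

The engine propagates a one-year, single-cycle decision tree analytically
(an expected-value cohort model, not a Markov model): each patient occupies
exactly one terminal state for the whole year — outpatient care,
non-surgical hospitalization, surgical hospitalization, or in-hospital
death. There are no within-year transitions, relapse states or event
timing, and the cohort is homogeneous within disease type (no age/sex
stratification). Because the horizon is one year, neither costs nor QALYs
are discounted.

Survivors accrue the utility of their state for the full year; decedents
accrue zero QALYs for the year. In-hospital mortality is applied uniformly
to surgical and non-surgical admissions, since the inputs provide a single
per-disease mortality. The three living-state weights plus the death weight
sum to one within each disease branch.

### Effect modifiers

Both avoidance and telemonitoring act on subgroups and are
population-averaged:

* avoidance: hospitalization RR applies to the avoider fraction only,
  giving the multiplier `p_avoid·RR_avoid + (1 − p_avoid)`; the
  outpatient-visit cost reduction likewise applies to avoiders only
  (per-patient factor `1 − p_avoid·visit_reduction` in expectation);
* telemonitoring: the hospitalization RR and the extra non-invasive
  diagnostic use apply to the compliant fraction only; the program cost
  (maintenance + encounters × duration × wage) accrues to every enrolled
  patient, because the program is deployed per patient while compliance
  gates only the clinical effect.

The telemonitoring strategy is always evaluated during the pandemic, i.e.
with the avoidance multiplier active underneath; the configuration type
enforces this.

### Cost assembly

The input table does not by itself say which cost rows attach to which
branch. The convention used throughout: outpatient visits, medications and
non-invasive imaging accrue to all patients; endoscopy only to hospitalized
patients; ward cost to all hospitalized; surgery cost to the surgical
fraction; in-hospital death cost to the decedent fraction. This is the
unique simple assembly consistent with the full set of expected costs and
increments the model is validated against, and it is independently
cross-checked by the microsimulation oracle, whose per-patient accrual
rules are written separately from the closed-form expectation.

All internal arithmetic runs at full floating precision; percentages,
whole-dollar costs and 4-decimal QALYs appear only in display columns.

## Parameters

Every input is a `(base, low, high, family)` record; ranges are stored
verbatim. Key defaults (units in the bundled table): disease mix
`p_UC = 0.568`; hospitalization 0.186 (UC) / 0.225 (CD) per patient-year;
surgery per hospitalization 0.051 / 0.331; in-hospital mortality
0.003 / 0.018; avoidance prevalence 0.261 with hospitalization RR 1.156
and visit-cost reduction 0.261; telemonitoring compliance 0.590 with
hospitalization RR 0.364 and diagnostic-use RR 1.565; utilities 0.83
(outpatient), 0.55 (hospitalized), 0.40 (surgical); WTP 46,450 USD/QALY
(1× Hong Kong GDP per capita; the 3× variant is a `--wtp` setting, not a
second code path). WTP, horizon and the HKD conversion (metadata only —
all amounts are USD) are `point` parameters: nothing varies them.

## One-way sensitivity analysis

Each parameter is swept over its printed range on a 101-point grid (others
at base); incremental cost and QALYs are recomputed at every point.
Thresholds are bisection roots (absolute parameter tolerance 1e-6, max 200
iterations) of an incremental quantity; bisection is chosen because every
incremental quantity here is monotone — mostly affine — in a single input,
making it unconditionally robust. Searches may extend beyond the printed
range when a root lies outside it. The tornado ranks parameters by the
span of net monetary benefit across their bounds: with a dominant base
case the ICER is undefined over much of each bar, and NMB is its
well-defined monotone analogue.

## Probabilistic sensitivity analysis

Distribution fitting reads each range as a 95% interval, sd =
(high − low)/3.92 — the standard convention when source variances are
unreported. Beta and gamma are moment-matched to (mean = base, sd); normal
is direct; lognormal anchors the natural-scale *median* at base (relative
risks are conventionally geometric-mean point estimates) with log-sd =
(ln high − ln low)/3.92; zero-width ranges degenerate to point masses. An
infeasible beta moment fit (sd² ≥ mean(1 − mean)) raises an error naming
the parameter.

Draws are taken parameter-by-parameter in the canonical table order from a
single seeded generator, and all strategies are evaluated on the same draw
(common random parameters), so per-draw comparisons are paired — required
for cost-effectiveness-plane quadrant proportions. Draws producing an
effective hospitalization probability above 1 are rejected and redrawn,
with the count reported.

By default each draw is additionally constrained to the parameter's
printed sensitivity range by rejection resampling. The ranges are the
bounds the deterministic analysis declares plausible, and unbounded
sampling would let the avoidance hospitalization RR cross 1.0 in ≈0.8% of
draws, flipping the sign of a monotone increment in a regime the range
itself excludes. `truncate=False` restores unbounded sampling of the
fitted distributions. Truncation shifts the mean of a skewed distribution
by a fraction of its sd (order 0.1–0.3%), which is visible at n = 10,000
Monte Carlo precision; the expectation-identity tests therefore run in
untruncated mode, where the tree's multilinearity in independent draws
makes E[outcome] equal the tree evaluated at per-parameter means, exactly.

Summaries per comparison: means, sds, normal-theory 95% CIs of the means
(mean ± 1.96·sd/√n), quadrant proportions (boundary draws fold into the
adjacent weak-dominance quadrant so proportions sum to 1), and the
proportion cost-effective at the WTP. Identical seeds give bit-identical
results.

## Microsimulation oracle (synthetic cohort)

The generator draws patient-level trajectories as independent Bernoulli
cascades — disease type, avoider and compliant status (drawn independently
of disease type, as no disease-specific rates exist), hospitalization with
the patient's own RR product applied multiplicatively, then surgery and
death — and accrues cost/QALYs with the same assembly rules as the cohort
engine. Per-patient RR scaling reproduces the cohort engine's
population-averaged multipliers exactly in expectation, so sample means
converge to the analytic values (validated at 3 standard errors,
n = 200,000; rates use binomial SEs, cost/QALYs sample SEs).

What the generator emulates: the tree's joint event structure and cost
accrual under the stated independence assumptions. What it does not:
real-world correlation between avoidance and disease severity, within-year
event timing, repeat admissions, or utility heterogeneity — so passing
convergence tests validates the engine's arithmetic, not the model's
clinical fidelity. The fixture writer emits the canonical parameter file
plus low/high perturbed variants of every non-point parameter for harness
use.

## Problem sizes

Defaults are the analysis's natural sizes and run in seconds on one CPU:
10,000 PSA draws, 101-point sweeps, 200,000 simulated patients per strategy
for oracle validation. CLI and tests scale these down only where a smaller
size already exercises the code path.

## Known limitations

* The one-year, two-status (outpatient/hospitalized) structure understates
  QALY losses for patients who deteriorate without being admitted.
* The PSA parameterization is a modelling choice: the ranges carry no
  stated interpretation (95% CI vs min–max), and tail-sensitive outputs —
  e.g. the proportion of draws in which avoidance is costlier — move by
  several percentage points between defensible parameterizations
  (range/3.92 with or without truncation spans roughly 82–86% for that
  quantity). Sign-robust findings (avoidance loses QALYs; telemonitoring
  dominates) are stable across all of them.
* Mean PSA increments carry a small upward bias relative to the
  deterministic base case under truncated sampling (see above); the
  deterministic base case is the authoritative point estimate.
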