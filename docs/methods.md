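# Methods

## The task and its value algebra

A lead-time TTO task compares Life A — `LT` years of full health, then `UT`
years in the target EQ-5D-5L state — with Life B, `x` years of full health.
At the indifference duration `T` the state's value is `U = (T − LT)/UT`,
with attainable range `[−LT/UT, 1]`. Durations live on a 3-month grid and
are held internally as integer quarter-year counts, so `U` is computed from
integer arithmetic and `compute_value`/`invert_value` round-trip exactly on
grid points; value comparisons in the invariants need no tolerance beyond
1e−12. The smallest detectable value difference is `min_step/UT` (0.025 for
a 3-month step over 10 unhealthy years; 0.05 over 5).

Two design pairs are packaged: the lead-time contrast (LT=10 vs LT=5, both
UT=5, so value ranges [−2, 1] vs [−1, 1]) and the visual-aid contrast
(both LT=10/UT=5; the experimental variant raises the unhealthy-time bar to
highlight the point equivalent to dead).

## The iteration schedule

The engine reproduces the instrument's printed opening anchors: first offer
`LT+UT`, second `LT`, third the exact midpoint of the bracket fixed by the
second answer (12.5 or 5 years for LT=10; 7.5 or 2.5 for LT=5). Beyond the
third offer the original computerized instrument's step sequence is not
public ("stepwise at intervals of 3 months to 1 year"); this package uses a
documented stand-in: bisection of the current preference bracket with the
midpoint snapped to whole years while the bracket is wide, then half-years,
then quarter-years. Consequences, proven in tests by exhaustive
enumeration: every quarter-grid duration is reachable; an error-free agent
with a grid utility elicits it *exactly*; the search needs at most 8
questions after the anchors (tree depth ≤ 12, far under the defensive
64-offer cap).

Degenerate cases. `x = 0` (immediate death, value `−LT/UT`) is posed as the
final refinement of a bottom bracket, since the range's lower bound must be
attainable. A task is **censored** when it terminates at a grid bound (0 or
`LT+UT`) without the respondent ever reporting indifference — the
"exhausted tradable time" phenomenon; an agent whose indifference point
falls strictly between two adjacent grid offers is instead asked to settle
on the closer endpoint (recorded as a forced indifference, not censored).
Respondents cannot revise earlier answers; the engine is response-agnostic
and leaves all stochastic behavior to the agent model.

## The respondent model

Each agent holds per-state true utilities `u*` and responds to an offer of
value `v` by perceiving `d = v − u_eff + ε`, `ε ~ N(0, σ)`, answering
"about the same" when `|d| ≤ δ`, otherwise preferring Life B when `d > 0`.
The effective utility carries the two lead-time bias mechanisms,

```
u_eff = u* − κ·(LT/UT − 1) − ν·(LT + UT − 10)/10,
```

normalized so both vanish at the LT=5/UT=5 arm (ratio 1, 10-year bar):
`κ` is the framing effect (people trade more time when more is available)
and `ν` the visual-contrast error (with a longer total bar, a given value
difference looks smaller, so respondents trade extra years to *see* the
difference). Both are identified only as between-arm contrasts, which is
all the arm-comparison analyses require.

The raised-bar variant acts through an engagement gain `γ`: when the
offer's value is within 0.5 of dead, the indifference tolerance shrinks to
`δ/(1+γ)` (more iterations before settling), and per-offer response times
(lognormal with parameters `base_log_time`, `time_sd`) inflate by `(1+γ)`
when, additionally, the agent's own indifference region lies near dead
(`|u_eff| ≤ 0.5`) and the offer probes it (`|v − u_eff| ≤ 0.25`). Gating
the time inflation on the agent's indifference region rather than on each
offer alone is deliberate: the opening anchors of *every* task pass through
values 0 and ±0.5, so per-offer gating would leak extra time into tasks
ending far from dead, contradicting the observed localization of the
effect to values near 0.

Utilities are generated hierarchically: respondent shift `b_r ~ N(0,
respondent_sd)` plus a per-state draw centered at `state_mean + b_r` with
SD `state_sd`, truncated to the attainable support [−2, 1]. The respondent
shift is what makes values cluster within respondent — the structure the
mixed-model analyses adjust for. Demographics (age group, gender,
education) are drawn from categorical frequencies and used only as model
covariates.

Default generating parameters (illustrative, not fitted): state means set
to the packaged experimental-arm per-state means (the arm where the bias
terms vanish), `state_sd = 0.45`, `respondent_sd = 0.3` (marginal SD ≈
0.54, matching the ~0.5–0.6 SDs of the published per-state values),
`σ = 0.15`, `δ = 0.05` (one grid step in value units), `κ = 0.04`,
`ν = 0.02` (together ≈ the observed 0.08 grand-mean arm gap), `γ = 0.4`,
`base_log_time = log 6 s`, `time_sd = 0.5` (≈ 0.6 min/task at ~6 questions,
the published order of magnitude). These defaults produce a value
distribution with its mode in the 0.5–1 bin and secondary mass at the
bounds, and a small exhaustion rate confined to the short-lead-time arm.

What the simulator does *not* emulate: learning/fatigue across the five
tasks, respondent-specific bias coefficients, cultural covariate effects,
time preference (deliberately excluded from the valuation model), and the
"confusing" reading of the visual aid (only the engagement reading is
implemented). Passing calibration tests therefore certify the pipeline's
statistical machinery under the stated generative assumptions, not the
behavior of any real population.

## Cleaning rules

Respondents whose recorded values are all equal (exact equality on the
quarter-grid representation of values, not of times — arms differ in their
T scales) are removed first; then individual tasks with duration ≤ 1 s
(inclusive, reading "completed within 1 s"). The record identity
`retained = (participants − all-same) × 5 − fast` then reproduces the
published totals (1,834 and 1,891) from the published exclusion counts,
which implicitly assumes the fast tasks belonged to retained participants.

## Analyses

* Per-arm summaries: unadjusted per-state mean/SD/n; proportion of
  non-negative values; the grand mean as the *unweighted* mean of per-state
  means (this convention reproduces the published 0.35/0.43; per-state n's
  were never printed); exhaustion as tasks ending at `T = 0`. A single
  record yields SD 0 with n=1 flagged. Display rounding (2 dp values, 1 dp
  percentages) happens only at display.
* Aggregate contrast: OLS of standard-arm state means on experimental-arm
  means, CIs from the t distribution with n−2 df, checked against a
  normal-equations oracle at 1e−10.
* Seven value bins partition [−2, 1] with {0} its own bin; membership of 0
  is exact grid equality, boundaries follow the half-open printed
  definitions.
* Arm comparisons cluster on respondent. Continuous outcomes: linear model
  with a respondent random intercept (REML); if the optimizer fails or the
  Wald p-value is undefined, the estimate falls back to OLS with
  cluster-robust standard errors, and the result descriptor records which
  path ran. Binary outcomes: logistic GEE with exchangeable working
  correlation (population-averaged odds ratio) — chosen over a
  random-intercept logit because it has stable, well-defined Wald
  inference in this stack. p-values are two-sided; no multiplicity
  correction is applied, matching the source analyses.

## Calibration study conditions

The suite's stochastic checks run at fixed seed 20130731 under conditions
chosen once, a priori:

* **Parameter recovery** — σ=0.15, δ=0.05, 400 respondents/arm,
  `state_sd = respondent_sd = 0.1`. The heterogeneity is set so the
  prescribed ±0.03 recovery band is a ≈3×SE Monte-Carlo bound at n=400 per
  state (both arms pooled; both arms are unbiased in this run).
* **Bias sign** — κ=0.04 or ν=0.1 with the same noise: the LT=10 arm's
  grand mean falls below the LT=5 arm's.
* **Type-I error** — 500 replicates of a true null: both arms share one
  TaskConfig and all bias terms are zero (with different LT/UT per arm even
  a bias-free generator is not null — censoring support differs), 60
  respondents/arm. The rejection count must sit in the exact-binomial
  ≥99% band [14, 37] at α=0.05; the observed run is 25/500.
* **Engagement localization** — γ=0.6, 400/arm, visual-aid configs: the
  time and question effects must be significant within 0.5 of dead and
  absent (p>0.05) on the pooled records beyond 0.5.

Replicate counts and arm sizes are the package's chosen desk-scale study
sizes; they keep the whole suite in the minutes range while leaving the
binomial/SE bounds with comfortable power.

## Known limitations

* The post-anchor iteration schedule is a reconstruction; real instruments
  may visit different intermediate offers (final values agree on the grid,
  question counts may differ).
* The forced-indifference rule resolves off-grid indifference points
  deterministically to the nearer endpoint; real respondents may not.
* GEE's population-averaged odds ratio is not numerically identical to a
  conditional (random-intercept) odds ratio; for the null-calibration and
  direction checks used here the distinction is immaterial.
* Printed-table inputs are transcribed constants; one printed quantity (the
  aggregate intercept's upper confidence bound) is not reproducible from
  the printed state means under OLS and is not asserted anywhere.
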