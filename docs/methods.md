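# Methods

## Model and estimand

The unit of analysis is a *construct*: a knee-replacement brand subdivided
by fixation, bearing mobility and constraint, each combination treated as a
distinct entity because each feature shifts revision risk. The estimand at
each post-operative time point *t* is the construct's **net failure** — the
marginal probability that a procedure has undergone its first linked
revision by *t*, with death treated as independent censoring. It is
estimated by one minus the Kaplan–Meier product-limit survivor function.
Net failure is a counterfactual "if patients did not die" quantity, not the
real-world cumulative incidence that a competing-risks (Aalen–Johansen)
estimator would target; for device comparison it is the standard registry
choice because it isolates implant performance from cohort mortality.
Competing-risks estimation and case-mix adjustment are out of scope.

Ties and conventions: at tied times, events are processed before
censorings (censored records remain in the risk set for events at the same
time); revisions at exactly *t* count toward F(t); the at-risk count at *t*
is "still under observation at *t*" (follow-up ≥ *t*), applied identically
to reference and comparators.

## Uncertainty

Variance is the classical Greenwood estimator
`S(t)² Σ d_i/(n_i(n_i−d_i))`, which equals the variance of F(t). The 95%
interval is the symmetric normal ("plain") interval on the failure scale,
clipped to [0, 1]. The symmetric form was chosen over a log(−log)
transform because at the failure probabilities and risk-set sizes where
this analysis operates (a few percent, ≥500 at risk) the normal
approximation is adequate and published registry reference intervals are
symmetric; the choice is exposed as the single CI method rather than a
config switch because the classification logic (below) depends only on CI
limits and mixing transforms between reference and comparator would be
incoherent. If a risk set is exhausted by events (n_i = d_i) the Greenwood
sum diverges; the estimate is flagged degenerate (F = 1, variance
undefined) and excluded from comparisons.

The auxiliary PTIR (prosthesis time incidence rate, revisions per 100
observed component-years) is provided for report parity with registry
annual reports and plays no role in classification.

## Benchmarking procedure

At each time point (default 3, 5, 7, 10 years):

- **Reference**: lowest estimated net failure among constructs with ≥ 1000
  at risk. Ties break by larger risk set, then lexicographic label, so
  output is deterministic. The reference's *point estimate* (not a CI
  bound) sets the margins; this matches plotting margins as fixed vertical
  lines.
- **Margins**: m20 = 0.2·F_ref(t), m100 = 1.0·F_ref(t) — absolute
  failure-difference thresholds at 20% and 100% relative risk (a comparator
  at m100 has exactly double the reference failure). F_ref = 0 is flagged
  degenerate.
- **Comparison**: Δ = F_comp − F_ref, SE pooled as √(Var_comp + Var_ref),
  95% CI Δ ± 1.96·SE, Wald z = Δ/SE with a two-sided p reported
  descriptively only. No multiple-testing correction is applied;
  classification uses only the CI limits.
- **Classification**, ordered, first match wins: (1) CI lower limit > m100
  → inferior at 100%; (2) lower > m20 → inferior at 20%; (3) upper < m20 →
  noninferior at 20%; (4) upper < m100 → noninferior at 100%; (5) else
  inconclusive. Inferiority is evaluated before noninferiority, so a narrow
  CI lying wholly between the margins is *inferior at 20%* — its lower
  limit already excludes the acceptable region, and that reading keeps the
  five bands mutually exclusive and exhaustive. Margin comparisons are
  strict; exact equality (measure zero) falls through to the weaker
  category.
- **Stratification** by gender recomputes reference, margins and
  eligibility within each stratum; records with unknown gender are dropped
  from stratified runs with a logged count. A time point (or stratum) with
  no qualifying reference is omitted with a logged reason and the run
  continues.

The at-risk thresholds are design parameters: ~1000 at risk with ~5%
cumulative failure yields a mean Greenwood 95% CI full width near 3
percentage points, and ~500 near 5 points — wide enough bands to make the
margin comparisons meaningful. `scripts/acceptance.py` recomputes both
widths by simulation (200 replicate cohorts, exponential revision times at
5% failure by 10 years, cohort sizes 1053 and 526 so the expected at-risk
counts at the evaluation time are ~1000 and ~500, no earlier censoring).

## Synthetic registry generator

Real registry extracts are not public, so validation runs on simulated
data. Per construct scenario: enrolment offset u ~ Uniform(window) measured
in years *before* the data lock (so u is also the administrative censoring
time and risk sets thin with evaluation time the way registry at-risk
counts do), revision time ~ exponential with per-year hazard λ_r, death
time ~ exponential(λ_d); observed time is the minimum, status the argmin.
Exponential hazards give closed-form truth F(t) = 1 − exp(−λ_r t) for
parameter-recovery and coverage tests; a Weibull shape option exists for
robustness checks only. Substreams are keyed by (global seed, construct
label), so adding a scenario never perturbs another's records.

The canned `nzjr_like_scenario` mimics the shape of a national 3-year
analysis: 25 constructs over a 21.4-year enrolment window with death hazard
0.02/yr (plausible for an elderly arthroplasty cohort); one
reference-grade construct (true 3-year failure 1.22%, cohort 4000, ~3200
at risk at 3 years) and 24 comparators with hazard multipliers 0.95–3.2×
and cohorts 900–3500, so a generated registry populates all five bands in
expectation and keeps 20+ constructs above the 500-at-risk bar at 3 years.

What the generator does **not** emulate: age/comorbidity case-mix,
informative censoring, surgeon/hospital clustering, non-uniform enrolment
rates, and calendar-time trends in revision practice. Passing tests
therefore demonstrate correctness of the estimators and decision rules
under the model's assumptions, not robustness to those real-data features.

## Verification design

- The product-limit machinery is checked to 1e−12 against two independent
  implementations (lifelines, and an event-by-event textbook loop written
  separately in the tests) on 1000 random small datasets, and against
  hand-derived values on a 4-record example (F(3) = 0.625, Var =
  0.08203125).
- Without censoring before *t* the estimator must reduce *exactly* to the
  empirical proportion with binomial variance p(1−p)/n.
- Greenwood SE is compared with a 500-resample nonparametric bootstrap SE
  (within 15%) on an n = 1000 cohort.
- Monte-Carlo suites (seeded, deterministic): mean estimate within 3 MC
  standard errors of closed-form truth; invariance of the estimate to the
  death-censoring hazard; 95% CI empirical coverage within [93%, 97%] at
  n = 1000 over 1000 replicates; full-pipeline type-I error for inferiority
  calls ≤ α/2 + MC error when comparator and reference share a true failure
  (the comparator cohort is sized between the two at-risk thresholds so the
  reference is designated by rule, keeping the calibration question
  well-posed); >80% power to flag a comparator with treble the reference's
  failure at 10 years with ~2% reference failure and ≥1000 at risk per arm.
- Simulation sizes (replicate counts 200–1000, cohorts ≤ 2000) were chosen
  to keep Monte-Carlo error well below the tested tolerances while the full
  suite runs in about a minute.

## Known limitations

- The plain symmetric CI can clip at 0 for very rare failure; a
  transformed interval would be preferable below ~10 events.
- Classification inherits the noninferiority framing: it never declares
  *superiority* to the reference, and a construct better than the reference
  simply lands in a noninferior band.
- The dynamic reference is an estimated quantity; its selection noise is
  not propagated into the difference CIs (the designated-reference
  calibration test quantifies the procedure as specified, not
  selection-adjusted inference).
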