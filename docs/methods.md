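# Methods

## The problem

In a cohort study of hospital certification, each patient is classified by
whether their hospital was certified before or after their admission:
admissions up to 180 days *before* certification form the **Pre** group,
admissions from 180 days *after* certification onward the **Post** group, and
the admissions in between the **Transitional** group.  Survival after
admission can be analysed on two time scales:

* **patient time** `t` — days since the patient's hospital admission; all
  patients share time zero, no delayed entry;
* **calendar time** `c` — days since 1970-01-01; patients enter the risk set
  at their admission day `c*` and must be treated as left-truncated.

By construction, Pre patients of a given hospital are admitted before its
Post patients, so on the calendar scale the groups are shifted against each
other.  If, additionally, the hazard declines with time since admission —
typical for acute events such as fractures in geriatric patients — then at
any calendar time where both groups are under observation the Pre patients
have, on average, been under observation longer and therefore sit on the low
part of their hazard curve, while Post patients are more recently admitted
and sit on the high part.  A Cox model on the calendar scale then estimates a
Post-vs-Pre hazard ratio above 1 even when the two groups share exactly the
same hazard in patient time.  This **structural bias** is neither confounding
nor a proportional-hazards violation; it is a property of how the calendar
scale composes risk sets.

## Diagnostic machinery

**Nonparametric estimation.**  Nelson–Aalen and Kaplan–Meier estimators are
computed from counting-process intervals with the single risk-set convention
`entry < u <= exit` (subjects censored at `u` are still at risk at `u`; tied
events are processed before tied censorings).  Delayed entry is supported, so
the Nelson–Aalen estimator is valid on the calendar scale.

**Piecewise-constant hazard approximation.**  Per group, the patient-time
hazard is approximated as constant on intervals `(t_{k-1}, t_k]`.  Two
fitting routes:

* `occurrence_exposure` (default): rate = events / person-time per interval —
  the maximum-likelihood estimator of the piecewise-exponential model,
  reproducible without any curve-fitting step;
* `na_slope`: slopes of a continuous piecewise-linear least-squares fit
  through the Nelson–Aalen jump points (the geometric construction of
  approximating the cumulative hazard by line segments), equally weighted;
  negative slopes are clipped to zero with a warning.

Both are consistent for the same model and agree within Monte-Carlo error on
large simulated cohorts.  Cut points are user-supplied; the shipped default
(quantiles of the event times, four intervals) is a heuristic, not a
study-specific choice.

**Transformation to calendar time.**  The individual calendar-time hazard of
a subject admitted at `c*` is `1(c >= c*) * alpha_group(c - c*)`; the group's
empirical population hazard at `c` is the arithmetic mean over its subjects
at risk at `c` (at risk: `c* < c <= c* + T*`).  At `c = c*` exactly the
subject contributes nothing: the hazard at patient time 0 is taken as 0 and
the at-risk indicator is strict, resolving the boundary where the two
indicator conventions meet.  Points where a group has no subject at risk are
explicitly masked (NaN), never imputed, so the spikes caused by sparse risk
sets under left truncation stay visible.  The pointwise ratio of two
population hazards is the calendar-time empirical hazard-ratio curve — the
curve that makes the structural bias visible as a ratio persistently above 1
during the overlap period.

## Resolving estimators

All Cox fits are **marginal** models: the partial likelihood treats subjects
as independent and a cluster-robust sandwich variance aggregates score
residuals within clusters (hospital, or matched pair).  Partial-likelihood
maximisation is delegated to `statsmodels` `PHReg` (delayed entry, Efron —
the package default — or Breslow ties).  The sandwich itself is computed from
vectorised Breslow-form score residuals, which is exact for untied event
times (event times are continuous in all simulations here) and matches
`R survival::coxph(..., cluster = )` to at least 7 significant digits on
left-truncated clustered test data.  Confidence intervals are normal-theory
on the log scale: `exp(beta ± 1.96 se)`.

* **Patient-time Cox** — risk sets on `t`; unbiased under the null because
  all subjects share time zero.
* **Naive calendar Cox** — risk sets on `c` with entry at `c*`; inherits the
  structural bias.
* **Matching** — 1-to-1 exact matching of each Post subject to a Pre subject
  with the *same admission day*, drawn uniformly without replacement, Post
  subjects visited in seeded random order (the processing order is not
  otherwise identified; randomising it avoids systematic preference).
  Matching balances the study-entry distribution exactly, so the calendar
  Cox on matched pairs is free of the bias; pairs become the clusters.
  Matching is on admission day only by default; a within-hospital flag
  exists.  The Transitional group is omitted.
* **Two-scale Cox, patient-time baseline** — adds the admission date (in
  years since 1970-01-01, an exact rescaling of the admission day) as a fixed
  covariate.
* **Two-scale Cox, calendar baseline** — adds days-since-admission as a
  time-varying covariate, updated in weekly segments (each subject's
  follow-up is split into 7-day segments; within a segment the covariate is
  the days since admission at segment start).
* **Two-scale Poisson regression** — the follow-up of every subject is split
  on both scales at once (Lexis splitting) into cells of group × patient-time
  band × calendar band; cell event counts are modelled as Poisson with a
  log person-time offset and reference-coded band factors:
  `log E[events] = log(PT) + beta_group + gamma_t-band + delta_c-band`.
  Person-time and events are conserved exactly by the split (asserted on
  every call).  The band factors are the parametric model of the two time
  scales and therefore belong in the linear predictor even though the
  scientific covariate of interest is only the group.  Default bands: four
  patient-time intervals at (0,7], (7,30], (30,90], (90,180] days and
  calendar years.  Bands with zero events everywhere would have divergent
  coefficients; their cells are dropped with a warning.

**Proportional-hazards diagnostic.**  `ph_test` implements the
Grambsch–Therneau score test from scaled Schoenfeld residuals (transform of
event times: identity by default, ranks optional), numerically reproducing
the classical `cox.zph` statistic of R `survival` (< 3.0) to 3+ decimals.
Like that statistic it can be conservative under heavy censoring; simulation
checks in the test suite show size ≈ 4.5 % (identity transform, uncensored
exponential data, n = 200) and power ≈ 1 against strongly crossing Weibull
hazards.

## The synthetic-cohort generator

The simulator emulates the structure of a nationwide certification study:

| parameter | default | rationale |
|---|---|---|
| hospitals | 154 | study-scale cluster count |
| certification window | 2013-01-01 … 2021-12-31 (uniform) | multi-year certification roll-out |
| patients/hospital | 192 (~29 600 total) | study-scale cohort |
| admission window | the whole observation window, per hospital | a claims cohort observes every hospital throughout the period; this is what shifts Pre entries early and Post entries late |
| group window | ±180 days around certification | Pre/Transitional/Post definition |
| true hazard | 7e-3, 2e-3, 8e-4, 4e-4 /day on (0,7], (7,30], (30,90], (90,180] | monotonically decreasing; 180-day cumulative hazard ≈ 0.18 (≈ 16 % mortality), front-loaded as in geriatric fracture cohorts; package defaults, not estimates from any dataset |
| group multipliers | all 1 | null effect |
| censoring | administrative at 180 days | only censoring mechanism; an optional independent exponential censoring rate exists (default 0) |

Event times are drawn by closed-form inversion of `multiplier * A(t) =
-log U` interval by interval; draws beyond the hazard's support never have
the event and are administratively censored.  Randomness follows a strict
substream contract: the root seed spawns one `SeedSequence` child per
hospital and, in the replication harness, per replication — so enlarging a
simulation adds hospitals/replicates without perturbing existing draws, and
identical seeds give byte-identical output tables.

An optional mode draws admissions from an offset window *around* each
hospital's certification date instead of the absolute window; it produces
the same phenomenon, more weakly, because each hospital's contribution to
the entry flow is truncated.

**What the generator does not emulate:** covariate-driven confounding (age,
sex, care needs), informative censoring, multiple admissions, competing
risks, non-uniform certification roll-out, or hospital-level frailty
(patients are independent within hospitals, so the cluster-robust variance
is conservative-neutral there).  Consequently, passing tests demonstrate the
structural time-scale mechanism and the correctness of the estimators, not
robustness to confounding in real claims data.

## Replication experiment and problem sizes

The canonical bias preset is the generator's default design under the null.
The replication harness fits, per replicate, the naive calendar Cox,
patient-time Cox, matched Cox on both scales, both two-scale Cox variants
and the two-scale Poisson model, and summarises mean log-HR, its SD,
`exp(mean log-HR)` and the fraction of 95 % CIs covering the truth.

Replicated runs (test suite and acceptance script) use scaled-down cohorts
of 100 hospitals × 42 patients (4 200 per replicate, 200 replicates): the
structural bias is an asymptotic property of the design, not of the sample
size, while CI-coverage quality depends mostly on the number of clusters,
which is kept near study scale.  At this scale the preset yields a mean
naive calendar HR ≈ 1.07–1.09 against ≈ 0.98–1.00 for every corrected
estimator.  The matched estimators run on the subset of exactly
admission-day-matched pairs (a few hundred pairs per replicate at this
density), so their replicate-to-replicate spread is roughly twice that of
the full-cohort estimators.

## Numerical choices and edge cases

* Epoch-day convention: 1970-01-01 ↔ 0; dates before the epoch are rejected.
* Group boundaries are closed on both outer sides (admission exactly 180
  days before certification is Pre; exactly 180 days after is Post);
  configurable via the window parameter.
* Administrative censoring is applied once, at cohort construction
  (`T* > max_followup` ⇒ `T* = max_followup`, event cleared), so every
  downstream module sees the same cohort.
* Hazard evaluation is half-open on the left: `alpha(t) = alpha_k` for
  `t ∈ (t_{k-1}, t_k]`, zero beyond the last cut and undefined (error) at
  `t <= 0`.
* Zero-person-time intervals get rate 0 with a warning; events in such an
  interval are impossible and raise.
* Cox fits require at least one event and non-constant covariates; the
  two-scale variants drop a degenerate (constant) time-scale covariate with
  a warning instead of failing.
* Convergence is declared from the score norm at the optimum; non-converged
  fits are flagged and excluded from replication summaries (recorded, never
  fatal).
* Ties: Efron default, Breslow available.  The robust sandwich uses
  Breslow-form score residuals — identical to Efron's when event times are
  untied, which holds almost surely for the continuous simulated times.

## Known limitations

* The piecewise-exponential cut points of a real analysis are
  study-specific; the shipped defaults are quantile heuristics.
* The empirical calendar-time hazard-ratio curve carries no confidence band;
  it is a descriptive diagnostic meant to be read next to the calendar Cox
  estimate.
* The matched-pairs marginal Cox analysis is used on left-truncated
  (calendar-scale) data, where its variance theory is an approximation.
* The classical Grambsch–Therneau statistic is conservative under heavy
  censoring (documented above); it is a diagnostic, not a gatekeeper, here.
* With few clusters (≲ 50) the sandwich CIs undercover mildly (a known
  property of unadjusted cluster-robust variances); the replication defaults
  keep ~100 clusters.
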