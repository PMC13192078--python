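# twoscales

Survival analysis of cohort studies can be run on two different clocks: the
patient's **time-to-event** (days since hospital admission) or **calendar
time** (days since 1970-01-01).  When the comparison groups are defined by a
calendar event — here, whether a hospital was certified before or after the
patient's admission — the groups enter the calendar scale at systematically
different dates.  Combined with a hazard that declines after admission, a
Cox model on the calendar scale then inflates the group hazard ratio even
when the groups share exactly the same hazard in patient time.  That
*structural bias* is not confounding and not a proportional-hazards
violation; it is a consequence of how the calendar scale composes risk sets.

`twoscales` is a toolkit for epidemiologists and biostatisticians to
**diagnose** this bias and **resolve** it:

* cohort construction with the epoch-day calendar convention, Pre /
  Transitional / Post certification groups (±180-day window) and
  administrative censoring;
* Nelson–Aalen and Kaplan–Meier estimation with delayed entry
  (left truncation);
* piecewise-constant hazard approximation per group,
  `alpha_j(t) = sum_k 1(t_{k-1} < t <= t_k) alpha_{j,k}`, fitted by
  occurrence/exposure rates or by piecewise-linear approximation of the
  Nelson–Aalen curve;
* transformation of hazards between time scales: individual calendar-time
  hazards `1(c >= c*_i) alpha_j(c - c*_i)`, empirical population hazards
  (at-risk averages) per group, and the time-dependent empirical hazard
  ratio in calendar time — the diagnostic curve;
* exact 1-to-1 matching of Post to Pre patients on the calendar admission
  date;
* marginal Cox models (cluster-robust sandwich variance) on either scale,
  two-time-scale Cox variants (admission year as baseline covariate, or
  weekly-updated time-since-admission as time-varying covariate), Lexis
  splitting and two-scale piecewise-exponential Poisson regression
  (`log E[events] = log PT + beta_group + gamma_t-band + delta_c-band`);
* a seeded synthetic-cohort simulator that reproduces the structural bias
  end to end, plus a replication harness comparing all estimators.

See `docs/methods.md` for the model details, defaults and limitations.

## Worked example

A null cohort (both groups share one decreasing hazard) of 4 200 patients in
100 hospitals, certification dates spread over 2013–2021:

```python
import twoscales as ts

cfg = ts.bias_config(n_hospitals=100, patients_per_hospital=42, seed=1)
cohort = ts.cohort_from_config(cfg)

naive = ts.cox_fit(ts.to_counting_process(cohort, "calendar"),
                   model_tag="cox_naive", time_scale="calendar")
pt = ts.cox_fit(ts.to_counting_process(cohort, "patient_time"),
                model_tag="cox", time_scale="patient_time")
pairs, _ = ts.match_one_to_one(cohort, seed=1)
matched = ts.cox_fit(
    ts.to_counting_process(ts.matched_cohort(pairs, cohort),
                           "calendar", cluster_col="pair_id"),
    model_tag="cox_matched", time_scale="calendar")
pois = ts.poisson_two_scale(ts.lexis_split(cohort))

table = ts.results_table([naive, pt, matched, pois])
print(table[table["term"] == "group_Post"].round(3).to_string(index=False))
```

```
            model   time_scale       term    hr  ci_low  ci_high     p
        cox_naive     calendar group_Post 1.137   0.934    1.385 0.201
              cox patient_time group_Post 1.000   0.857    1.168 0.997
      cox_matched     calendar group_Post 1.030   0.691    1.535 0.884
poisson_two_scale         both group_Post 1.012   0.821    1.247 0.912
```

The true Post-vs-Pre hazard ratio is exactly 1.  The naive calendar-scale
Cox model drifts upward (here 1.14) because Pre patients entered calendar
time earlier and, with a decreasing hazard, sit lower on their hazard curve
whenever the groups are compared; the patient-time model, the calendar model
on the 315 admission-date-matched pairs, and the two-scale Poisson model all
return ≈ 1.  Averaged over 200 replicates the naive model centres near 1.08
while every corrected estimator centres within 2 % of 1 (run
`twoscales experiment` or the acceptance script to reproduce).

The same pipeline is available from the shell:

```bash
twoscales simulate --seed 1 --outdir run/
twoscales cox --subjects run/subjects.csv --hospitals run/hospitals.csv \
    --scale patient-time --outdir run/
twoscales fit-hazard --subjects run/subjects.csv --hospitals run/hospitals.csv \
    --cuts 7,30,90,180 --outdir run/haz
twoscales transform --subjects run/subjects.csv --hospitals run/hospitals.csv \
    --hazard-dir run/haz --outdir run/ --plot
twoscales experiment --preset bias --reps 50 --outdir run/
```

Every subcommand writes a `manifest.json` (options, seed, version) from
which the run can be reproduced exactly.

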