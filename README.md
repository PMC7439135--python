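# circamood

Circadian digital phenotyping for mood-disorder relapse monitoring.

Patients with major mood disorders (MDD, bipolar I/II) show disturbed
circadian behaviour — weakened or shifted daily heart-rate rhythms,
nocturnal activity and light exposure, irregular sleep timing — before
and during mood episodes. `circamood` implements, end to end, the
analytic machinery of a wearable-plus-app monitoring system built on
that observation, together with the biostatistical layer used to
evaluate whether such feedback reduces episode recurrence. It is aimed
at chronobiology and digital-psychiatry researchers who want a tested,
reproducible reference implementation they can run on synthetic
cohorts or adapt to their own wearable exports.

## What it computes

* **Cosinor rhythmometry** — least-squares fit of
  `y = M + A·cos(2π(t−φ)/24)` to the trailing 48 h of heart rate;
  amplitude `A` and the circular distance of the acrophase `φ` from
  midday feed the scoring layer.
* **H-scores** — four 0–100 daily "healthiness" scores (heart-rate
  rhythm CR, activity ACT, light exposure LE, sleep SL), e.g.
  `CR = 0.5·N(A) + 0.5·(100 − N(acrophase distance))` with `N` a
  clamped 0–100 normalisation; their average drives a risk indicator,
  coaching messages, and **warning alerts** (average < 50, or < 60 on
  two consecutive days).
* **Digital-phenotype features** — 13 basic daily features extended by
  mean/SD/trend-gradient over 3/6/12-day windows to 130 named slots,
  plus a pluggable mood-predictor interface.
* **Behaviour change (DGC)** — the *delta of gradient change*
  `DGC = g(X_after) − g(X_before)` of a daily feature around each
  alert (4-point OLS slopes sharing the alert day), compared between
  intervention and control arms with Kolmogorov–Smirnov and
  Mann–Whitney U tests on per-subject medians.
* **Adherence** — 30-day wear rates (worn hours / 720) with 6-point
  moving-average and moving-SD trend lines per subject and group, and
  the ≥ 60% annual-wear inclusion filter.
* **Outcome GLMs** — Poisson (optionally negative-binomial) log-link
  models of annual episode counts and durations; the exponentiated
  group coefficient is a rate ratio reported with a Wald 95% CI and as
  a percent change `100·(1 − exp β)`.
* **Synthetic cohorts** — a fully seeded generator for minute-level
  heart rate / steps / light, sleep, mood charts, wear gaps and
  two-group episode outcomes with known ground truth, so every stage
  has a recoverable target.

See `docs/methods.md` for models, defaults and limitations.

## Worked example

```python
import pandas as pd
import circamood as cm

spec = cm.CohortSpec(n_crm=2, n_control=2, days=30, seed=42)
subjects, truth = cm.generate_cohort(spec)
subject = subjects[0]

fit = cm.fit_cosinor(subject.streams["heart_rate"],
                     pd.Timestamp("2023-01-10 21:00"))
print(f"cosinor: M={fit.mesor:.1f} bpm, A={fit.amplitude:.1f} bpm, "
      f"acrophase={fit.acrophase:.2f} h")

daily = cm.daily_summaries(subject)          # the 13 basic features/day
scores = cm.score_days(daily)                # H-scores + risk level
alerts = cm.evaluate_alerts(scores["average"])
print(f"{len(alerts)} warning alerts; first: {alerts[0].date} ({alerts[0].rule})")
```

prints

```
cosinor: M=71.1 bpm, A=8.6 bpm, acrophase=14.75 h
14 warning alerts; first: 2023-01-08 (below-50)
```

The fitted rhythm matches this subject's generating parameters
(M = 71.2, A = 8.4, φ = 14.75): the 48-hour window recovers the truth
to within the sampling noise. The subject's scores then hover in the
high-risk band — under the default *personal* normalisation a
stationary synthetic subject scores near mid-scale, so alerts are
frequent (see the methods note) — and each alert is a time anchor for
the DGC behaviour-change analysis:

```python
samples = cm.dgc_samples(daily["steps_during_daytime"].reset_index(drop=True),
                         [(a.date - subject.study_period()[0].date()).days
                          for a in alerts])
result = cm.compare_groups(samples, samples)   # identical groups -> no difference
```

## Command line

```bash
crm synth --outdir run/ --seed 7        # write a synthetic cohort
crm run   --outdir run/ --seed 7        # all stages + manifest.json
crm validate run/cohort                 # schema-check subject files
```

Stages write plain CSV/JSON (`hscores.csv`, `alerts.csv`,
`features.csv`, `dgc_group_tests.csv`, `wear_trends.csv`,
`glm_results.csv`); a YAML config mirrors `CohortSpec` and the scoring
options.

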