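# Methods

`circamood` implements an analysis pipeline for circadian digital
phenotypes collected by a wrist-worn tracker (heart rate, step counts,
ambient light, sleep records) and a daily mood chart, in a two-group
(intervention vs control) relapse-monitoring design. This note records
the models, the defaults and why they were chosen, what the synthetic
cohorts do and do not emulate, and the numerical conventions.

## Cosinor rhythmometry

The heart-rate circadian rhythm is summarised by a single-component
cosinor fit over the trailing 48 hours,

    y(t) = M + A cos(2π (t − φ) / 24) + ε,

estimated by ordinary least squares through the linear parameterisation
`y = M + b1 cos(ωt) + b2 sin(ωt)`, with `A = √(b1² + b2²)` and
`φ = atan2(b2, b1)/ω`. Time `t` is the fractional hour of the local
clock day, so `φ` is directly a clock time. The score pipeline uses the
amplitude `A` (beats/min) and the circular distance of `φ` from a fixed
midday reference (12:00), folded into [0, 12] hours.

Numerical conventions:

* A fit needs ≥ 24 samples spanning at least half the 48-h window;
  otherwise it is *unavailable* (`None`), never an exception.
* A fitted amplitude below 10⁻⁹ beats/min makes the acrophase
  meaningless; the fit is flagged degenerate and the distance set to 0,
  so a flat-but-regular signal is judged on amplitude alone rather
  than punished by an arbitrary phase.
* The fit is recomputed daily at 21:00 (the mood-chart hour). A day
  with no heart-rate sample of its own gets no rhythm features, even
  though the trailing window could be fit from earlier days — a stale
  rhythm estimate should not stand in for an unobserved day.
* The period is fixed at 24 h; no multi-component or free-period
  fitting (the scores are defined on the single daily rhythm).

## Time zones of the day and the H-scores

Sunrise and sunset default to a fixed 06:30 / 18:30 local clock
(configurable; the quantities are clock-time based, so no astronomical
model is used by default). The ideal bedtime is 8 h before sunrise; the
*bedtime window* of day *d* is the 8-hour night ending at sunrise of
*d*, and the *daytime window* is [sunrise, sunset) of *d*.

Four 0–100 scores are computed per subject-day (weights 0.5/0.5 and
0.5/0.25/0.25; equal within a score except sleep, where efficiency
carries half the weight because short, fragmented sleep is the
dominant risk signal):

    CR  = 0.5·N(amplitude)          + 0.5·(100 − N(acrophase distance))
    ACT = 0.5·(100 − N(bed steps))  + 0.5·N(day steps)
    LE  = 0.5·(100 − N(bed lux))    + 0.5·N(day lux)
    SL  = 0.5·N(efficiency) + 0.25·(100 − N(onset dev)) + 0.25·(100 − N(offset dev))

`N(x) = 100·(x − low)/(high − low)`, clamped to [0, 100], and is
increasing in `x` for every feature — the formulas subtract from 100
where larger is worse.

**Normalisation bounds.** Two modes:

* `personal-rolling` (default): per subject and feature, the (5th,
  95th) percentile of the trailing 30 days (needing ≥ 7 available
  days), matching the individualised-feedback intent — the score
  measures change relative to the subject's own recent behaviour.
* `fixed-config`: population bounds (e.g. amplitude 0–20 beats/min,
  daytime steps 0–12,000, deviations 0–240 min), used as the fallback
  while history is short.

A known consequence of personal-rolling bounds on a *stationary*
subject: typical days normalise near mid-scale, so the average score
hovers near 50–60 and the alert rules fire far more often than they
would for a real patient whose bad stretches are episodic. Synthetic
alert rates are therefore not calibrated to clinical deployments; they
serve as time anchors for the behaviour-change analysis.

**Risk indicator and alerts.** The daily average of the available
scores maps to high (< 60), moderate (60–80) and low (≥ 80) risk —
cutoffs aligned with the alert scale and configurable. A warning alert
fires when the average falls below 50, or below 60 on two consecutive
available days; at most one alert per day (the below-50 rule takes
precedence) and a missing day resets the consecutive-day run — no
alert is raised from unobserved behaviour. Coaching messages come from
a fixed per-domain catalog, emitted for each score below 60, in fixed
order.

## Feature vectors

13 basic daily features (cosinor amplitude and acrophase distance,
steps and mean light by time zone, total daily steps, sleep
efficiency/deviations/duration, mean heart rate by time zone) are a
documented reconstruction of the quantities the scoring formulas and
feedback system consume; the list is swappable. Each basic feature is
extended by its mean, sample SD (ddof = 1) and OLS gradient over
trailing windows of 3, 6 and 12 days (inclusive of the focal day,
regressor = day index 0…n−1), for 13 + 13·3·3 = 130 named slots. A
window statistic needs ≥ 2 available days; otherwise the slot is NaN —
never imputed, and the 130-column schema never changes. A pluggable
predictor interface with a deliberately simple logistic baseline lets
the vectors drive an end-to-end mood-state demo; the baseline is not a
validated clinical predictor.

## Behaviour change: delta of gradient change (DGC)

For an alert at day *t* and a daily feature series *x*, two four-point
windows share the alert day: `X_before = (x_{t−3},…,x_t)` and
`X_after = (x_t,…,x_{t+3})`; `DGC = g(X_after) − g(X_before)` with `g`
the OLS slope against index. Positive DGC means the feature trended
upward after the alert. Any missing value in the seven-point window
omits the sample (calendar days, no re-indexing over gaps). Every
alert with complete data contributes a sample; the subject-level
summary is the median. For control subjects the same alert rules are
evaluated without delivery ("pseudo-alerts") so both arms are anchored
comparably.

Note that DGC is *invariant* under time reversal of the seven-point
window (reversal swaps the window roles and negates both slopes, so
the sign flips cancel) and antisymmetric under value negation.

Group comparison: two-sided Kolmogorov–Smirnov and Mann–Whitney U
tests on the per-subject medians (scipy implementations). Raw
per-feature p-values are the primary output; an optional
Benjamini–Hochberg flag is provided but off by default, matching the
per-feature reporting convention.

A selection effect worth knowing: alert days are by construction bad
(low-score, often low-activity) days, so regression to the mean
produces mildly positive DGC in *both* arms; the group contrast, not
the raw sign, estimates the intervention effect.

## Adherence

Wear detection: an hour counts as worn iff it contains ≥ 1 heart-rate
sample (heart rate is sampled continuously only on-wrist). The annual
wear rate is worn hours / 8760; subjects below 60% are excluded
(exactly 60% is retained — the rule excludes strictly below). The
study period is cut into 30-day units (720 h); per-unit rates are
smoothed with a 6-point sliding window (mean = MA, sample SD = MSD),
and group lines are pointwise means of the individual lines. The
6-point window is applied to the per-unit series (a smoothing of the
abbreviated series; a raw-resolution mode is not offered). A trailing
partial unit is dropped, not prorated.

## Outcome GLMs

Per subject, annual episode counts and in-period durations are derived
by category; an episode counts toward a period iff it starts inside
it, durations sum the calendar days of overlap, and a whole-day
episode with `start == end` lasts 1 day. Depressive subtype cutoffs
(major ≥ 14 days, minor 3–13, brief < 3) are configurable
reconstructions.

The group effect is a Poisson log-link GLM (statsmodels); the
exponentiated group coefficient is a rate ratio with a Wald 95% CI on
the log scale, reported also as a percent change `100·(1 − RR)` at one
decimal (positive = reduction). Durations (days/year) are modelled as
counts with the same families. A negative-binomial (NB2) family is
available for overdispersed outcomes. All subjects default to one year
of exposure; an exposure offset is available for unequal follow-up.
Zero-variance outcomes, groups with < 2 subjects, separation and
non-convergence are flagged on the result object, never silently
reported: with ~10 covariates on a few dozen subjects the adjusted
model is fragile, and CIs under near-separation are labelled
unreliable rather than trusted.

## Synthetic cohorts

The generator produces what the pipeline consumes, with recoverable
ground truth: minute-level heart rate `M_i + A_i cos(2π(t−φ_i)/24) +
N(0, σ)` with subject-specific parameters drawn around cohort-level
means (defaults: MESOR 70 ± 4, amplitude 10 ± 1.5 beats/min, acrophase
14:00 ± 1 h, noise SD 5); Poisson steps (10/min daytime, 0.2/min
otherwise); gamma-distributed light (mean 300 lux daytime, 5 at night,
shape 2 for realistic right skew); sleep onset/offset jittered N(0, 30
min) around the ideal times with Beta-distributed efficiency (mean
0.90); daily mood scores; hour-blocked wear gaps (each clock hour
independently unworn with probability 0.15, since wear/non-wear is
episodic and wear is hour-denominated); and per-subject annual episode
counts Poisson(rate × RR^group) with geometric durations (mean 30
days, capped at study end, same-type overlaps resolved), defaults 4
episodes/yr control and true rate ratio 0.4. One cohort seed derives
per-subject seeds (`seed + index`) so subjects are independently
reproducible; equal seeds give byte-identical cohort directories.

`inject_post_alert_shift` adds an intervention effect: from the day
after a chosen alert, daytime step and light means rise by configured
amounts, pre-alert data untouched. In the acceptance run the step
shift is 7 steps/min (≈ 5000 steps/day) — about twice the day-to-day
SD of daytime step totals under the default wear gaps, the regime in
which the group contrast is designed to be detectable.

What the generator does **not** emulate: relapse dynamics (behaviour
is stationary, so scores do not drift before episodes and episodes are
independent of the sensor streams), heart-rate responses to activity
or sleep, seasonal sunrise changes, device-specific artefacts, and
informative missingness (gaps are independent of state). Passing tests
therefore demonstrate that the machinery recovers what it is defined
to measure under its own assumptions — not that those assumptions hold
in any clinical population.

## Problem sizes in the shipped runs

The test suite uses 14–20-day miniature cohorts and closed-form
oracles; calibration checks use 200 GLM replicates (coverage), 1000
Mann–Whitney null replicates and 100 noisy cosinor fits. The
acceptance script runs a 30-subject, 120-day end-to-end cohort plus
the same calibration studies; these sizes were chosen so the whole
analysis reruns in well under a minute while keeping Monte-Carlo error
small relative to the asserted tolerances.

## Known limitations

* The 13-feature list, risk-indicator cutoffs, messaging catalog,
  normalisation reference and depressive-subtype thresholds are
  documented reconstructions/conventions, all configurable.
* Clinical coefficients from any particular study cohort are not
  reproducible here — no clinical data ship with the package; the GLM
  layer is validated by simulation (coverage and recovery), and the
  percent-change reporting by its algebraic identity.
* Naive local time throughout: no DST or travel modelling.
* The multivariable GLM with the full covariate list is unstable at
  pilot-study sample sizes; results carry convergence flags and should
  be read accordingly.
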