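"""Mood-episode outcome comparison between groups via log-link GLMs.

Per subject, annual episode counts and in-period durations are derived
by category (depressive with major/minor/brief subtypes, manic /
hypomanic pooled and separate, and totals). Group effects are estimated
with a Poisson log-link GLM (negative binomial NB2 optional for
overdispersed outcomes); durations in days/year are modelled as counts
with the same families. The exponentiated group coefficient is a rate
ratio, reported with a Wald 95% CI on the log scale and as a percent
change ``100 * (1 - RR)`` (positive = reduction in the intervention
group).

Depressive subtype cutoffs (major >= 14 days, minor 3-13, brief < 3)
are configurable reconstructions — clinical subtype definitions vary.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .records import SubjectRecord, ValidationError, check_episodes_nonoverlapping

COUNT_OUTCOMES = (
    "total_depressive_episodes",
    "major_depressive_episodes",
    "minor_depressive_episodes",
    "brief_depressive_episodes",
    "total_manic_hypomanic_episodes",
    "manic_episodes",
    "hypomanic_episodes",
    "total_mood_episodes",
)
DURATION_OUTCOMES = (
    "duration_total_depressive",
    "duration_manic_hypomanic",
    "duration_total_mood",
)

#: (major_min_days, minor_min_days): depressive episodes shorter than
#: minor_min_days are "brief".
SUBTYPE_THRESHOLDS = (14, 3)

COVARIATE_NUMERIC = ("age", "age_first_onset", "age_first_visit",
                     "n_prev_admissions", "n_prev_depressive",
                     "n_prev_manic", "n_prev_hypomanic")
COVARIATE_CATEGORICAL = ("gender", "diagnosis", "first_onset_type")


@dataclass
class EpisodeOutcome:
    """Annual episode counts/durations plus covariates for one subject."""

    subject_id: str
    group: str
    counts: dict[str, int] = field(default_factory=dict)
    durations: dict[str, int] = field(default_factory=dict)
    covariates: dict = field(default_factory=dict)


def derive_outcomes(subject: SubjectRecord,
                    period: tuple[dt.date, dt.date],
                    subtype_thresholds: tuple[int, int] = SUBTYPE_THRESHOLDS,
                    ) -> EpisodeOutcome:
    """Counts and in-period durations of the subject's episodes.

    ``period`` is a half-open date interval ``[start, end)``. An
    episode counts toward the period iff it starts inside it; durations
    sum the calendar days each episode overlaps the period.
    """
    check_episodes_nonoverlapping(subject.episodes)
    start, end = period
    major_min, minor_min = subtype_thresholds
    counts = {k: 0 for k in COUNT_OUTCOMES}
    durations = {k: 0 for k in DURATION_OUTCOMES}

    for ep in subject.episodes:
        in_start = max(ep.start, start)
        in_end = min(ep.end, end - dt.timedelta(days=1))
        overlap_days = max(0, (in_end - in_start).days + 1)
        starts_in = start <= ep.start < end
        if ep.type == "depressive":
            if starts_in:
                counts["total_depressive_episodes"] += 1
                counts["total_mood_episodes"] += 1
                d = ep.duration_days
                if d >= major_min:
                    counts["major_depressive_episodes"] += 1
                elif d >= minor_min:
                    counts["minor_depressive_episodes"] += 1
                else:
                    counts["brief_depressive_episodes"] += 1
            durations["duration_total_depressive"] += overlap_days
            durations["duration_total_mood"] += overlap_days
        else:  # manic or hypomanic
            if starts_in:
                counts["total_manic_hypomanic_episodes"] += 1
                counts["total_mood_episodes"] += 1
                key = "manic_episodes" if ep.type == "manic" else "hypomanic_episodes"
                counts[key] += 1
            durations["duration_manic_hypomanic"] += overlap_days
            durations["duration_total_mood"] += overlap_days

    return EpisodeOutcome(subject.subject_id, subject.group,
                          counts, durations, subject.covariates())


def outcomes_frame(outcomes: Iterable[EpisodeOutcome]) -> pd.DataFrame:
    """Flatten EpisodeOutcome records into one analysis frame."""
    rows = []
    for o in outcomes:
        rows.append({"subject_id": o.subject_id, "group": o.group,
                     **o.counts, **o.durations, **o.covariates})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class GLMFit:
    """Group-effect estimate for one outcome."""

    outcome: str
    model: str  # "univariable" | "multivariable"
    exp_beta: float
    ci_low: float
    ci_high: float
    p_value: float
    family: str
    converged: bool
    degenerate: bool = False
    note: str = ""

    @property
    def percent_change(self) -> float:
        return rate_ratio_to_percent_change(self.exp_beta)


def _dummy_code(df: pd.DataFrame, column: str) -> pd.DataFrame:
    """Dummy-code a categorical with the largest category as reference."""
    counts = df[column].value_counts()
    reference = counts.index[0]
    out = {}
    for level in counts.index[1:]:
        out[f"{column}[{level}]"] = (df[column] == level).astype(float)
    return pd.DataFrame(out, index=df.index)


def _design(df: pd.DataFrame, adjusted: bool) -> pd.DataFrame:
    X = pd.DataFrame(index=df.index)
    X["intercept"] = 1.0
    X["group_crm"] = (df["group"] == "CRM").astype(float)
    if adjusted:
        for col in COVARIATE_NUMERIC:
            if col in df.columns:
                X[col] = df[col].astype(float)
        for col in COVARIATE_CATEGORICAL:
            if col in df.columns and df[col].nunique() > 1:
                X = pd.concat([X, _dummy_code(df, col)], axis=1)
    return X


def fit_group_glm(df: pd.DataFrame, outcome: str,
                  adjusted: bool = False,
                  family: str = "poisson",
                  nb_alpha: float = 1.0,
                  exposure: Optional[np.ndarray] = None) -> GLMFit:
    """Fit the group-comparison GLM for one outcome column.

    ``df`` must hold ``group`` plus the outcome (and covariates when
    ``adjusted``). Degenerate outcomes (all zero, or a group with fewer
    than two subjects) and non-convergence are flagged on the result
    rather than raised. ``exposure`` gives per-subject follow-up (in
    years) when observation windows are unequal; by default all
    subjects count one year.
    """
    model_name = "multivariable" if adjusted else "univariable"
    y = df[outcome].to_numpy(dtype=float)
    groups = (df["group"] == "CRM").to_numpy()
    if groups.sum() < 2 or (~groups).sum() < 2:
        return GLMFit(outcome, model_name, np.nan, np.nan, np.nan, np.nan,
                      family, False, degenerate=True,
                      note="fewer than two subjects in a group")
    if np.all(y == 0) or np.var(y) == 0:
        return GLMFit(outcome, model_name, np.nan, np.nan, np.nan, np.nan,
                      family, False, degenerate=True,
                      note="zero-variance outcome")
    if family == "poisson":
        fam = sm.families.Poisson()
    elif family in ("nb", "negative-binomial"):
        fam = sm.families.NegativeBinomial(alpha=nb_alpha)
    else:
        raise ValueError(f"unknown family {family!r}")

    X = _design(df, adjusted)
    try:
        model = sm.GLM(y, X.to_numpy(dtype=float), family=fam,
                       exposure=exposure)
        res = model.fit(maxiter=200)
    except Exception as exc:  # separation / singular design
        return GLMFit(outcome, model_name, np.nan, np.nan, np.nan, np.nan,
                      family, False, degenerate=True, note=str(exc))
    j = list(X.columns).index("group_crm")
    beta = res.params[j]
    se = res.bse[j]
    note = ""
    converged = bool(res.converged) if hasattr(res, "converged") else True
    if not np.isfinite(se) or se > 50:
        note = "unstable fit (near-separation): CI unreliable"
        converged = False
    with np.errstate(over="ignore"):
        ci_low = float(np.exp(beta - 1.959963984540054 * se))
        ci_high = float(np.exp(beta + 1.959963984540054 * se))
    return GLMFit(outcome, model_name, float(np.exp(beta)), ci_low, ci_high,
                  float(res.pvalues[j]), family, converged, note=note)


def fit_all_outcomes(df: pd.DataFrame, adjusted: bool = False,
                     family: str = "poisson") -> list[GLMFit]:
    return [fit_group_glm(df, outcome, adjusted=adjusted, family=family)
            for outcome in (*COUNT_OUTCOMES, *DURATION_OUTCOMES)]


def rate_ratio_to_percent_change(exp_beta: float) -> float:
    """Percent change implied by a rate ratio: ``100 * (1 - RR)``,
    rounded to one decimal. Positive values are reductions.

    A rate ratio must be positive; zero or negative input is a domain
    error (a log-link GLM cannot produce it).
    """
    if not np.isfinite(exp_beta) or exp_beta <= 0:
        raise ValueError(f"rate ratio must be positive, got {exp_beta}")
    return round(100.0 * (1.0 - exp_beta), 1)


def results_table(fits: Iterable[GLMFit]) -> pd.DataFrame:
    """Results in the layout of a clinical outcomes table."""
    rows = []
    for f in fits:
        rows.append({
            "outcome": f.outcome, "model": f.model, "exp_beta": f.exp_beta,
            "ci_low": f.ci_low, "ci_high": f.ci_high, "p_value": f.p_value,
            "percent_change": (f.percent_change
                               if np.isfinite(f.exp_beta) and f.exp_beta > 0
                               else np.nan),
            "family": f.family, "converged": f.converged,
            "degenerate": f.degenerate, "note": f.note,
        })
    return pd.DataFrame(rows)
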