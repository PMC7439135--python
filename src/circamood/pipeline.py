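"""End-to-end pipeline orchestration: synth -> score -> features -> dgc
-> adherence -> outcomes, with a config file, per-stage logging and a
run manifest.

Each stage is a pure function of (inputs, config, seed); the manifest
records the config hash, seed, package version and per-stage row counts
so a rerun with the same config can be verified bit-identical for the
deterministic stages.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .adherence import group_trend, subject_trends
from .behavior import compare_groups, dgc_samples, pseudo_alert_times
from .hscore import (
    DEFAULT_ZONES,
    TimeZones,
    evaluate_alerts,
    score_days,
)
from .io import apply_compliance_filter, read_cohort
from .outcomes import derive_outcomes, fit_all_outcomes, outcomes_frame, results_table
from .records import SubjectRecord
from .summaries import daily_summaries
from .features import extend_features
from .synthetic import CohortSpec, generate_cohort, write_cohort

logger = logging.getLogger(__name__)

ALL_STAGES = ("synth", "score", "features", "dgc", "adherence", "outcomes")

#: Features reported in the behaviour-change comparison (the H-score
#: relevant subset).
DGC_FEATURES = (
    "cr_amplitude",
    "steps_during_daytime",
    "light_exposure_during_daytime",
    "sleep_efficiency",
    "sleep_duration",
)


@dataclasses.dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    cohort: CohortSpec = dataclasses.field(default_factory=CohortSpec)
    normalization: str = "personal-rolling"
    sunrise: str = "06:30"
    sunset: str = "18:30"
    glm_family: str = "poisson"
    compliance_threshold: float = 0.60
    apply_compliance: bool = False
    stages: tuple[str, ...] = ALL_STAGES
    seed: Optional[int] = None

    def zones(self) -> TimeZones:
        return TimeZones(dt.time.fromisoformat(self.sunrise),
                         dt.time.fromisoformat(self.sunset))

    @classmethod
    def from_yaml(cls, path: Path | str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort = CohortSpec(**raw.pop("cohort", {}))
        stages = tuple(raw.pop("stages", ALL_STAGES))
        bad = set(stages) - set(ALL_STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        return cls(cohort=cohort, stages=stages, **raw)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True,
                             default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _score_subject(subject: SubjectRecord, config: RunConfig,
                   zones: TimeZones):
    daily = daily_summaries(subject, zones=zones)
    scores = score_days(daily, normalization=config.normalization)
    alerts = evaluate_alerts(scores["average"])
    return daily, scores, alerts


def run_pipeline(config: RunConfig, outdir: Path | str) -> Path:
    """Run the configured stage prefix; returns the run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.seed is not None:
        config = dataclasses.replace(
            config, cohort=dataclasses.replace(config.cohort,
                                               seed=config.seed))
    zones = config.zones()
    manifest = {"package_version": __version__,
                "config_hash": config.config_hash(),
                "seed": config.cohort.seed,
                "stages": {}}
    stage_set = set(config.stages)

    def record(stage: str, t0: float, **counts):
        manifest["stages"][stage] = {
            "seconds": round(time.perf_counter() - t0, 2), **counts}
        logger.info("stage %s done in %.1fs %s", stage,
                    time.perf_counter() - t0, counts)

    subjects = truth = None
    if "synth" in stage_set:
        t0 = time.perf_counter()
        subjects, truth = generate_cohort(config.cohort, zones)
        write_cohort(subjects, truth, outdir / "cohort")
        record("synth", t0, subjects=len(subjects))
    else:
        cohort_dir = outdir / "cohort"
        subjects = read_cohort(cohort_dir) if cohort_dir.is_dir() else []
        if not subjects:
            raise FileNotFoundError(
                f"no cohort under {outdir / 'cohort'}; run the synth stage "
                "or place subject directories there")

    if config.apply_compliance:
        subjects, excluded = apply_compliance_filter(
            subjects, config.compliance_threshold)
        manifest["excluded_subjects"] = [sid for sid, _ in excluded]

    per_subject: dict[str, tuple] = {}
    if stage_set & {"score", "features", "dgc"}:
        t0 = time.perf_counter()
        score_rows, alert_rows = [], []
        for subject in subjects:
            daily, scores, alerts = _score_subject(subject, config, zones)
            per_subject[subject.subject_id] = (subject, daily, scores, alerts)
            alert_dates = {a.date: a.rule for a in alerts}
            for date, row in scores.iterrows():
                score_rows.append({
                    "subject_id": subject.subject_id, "date": date,
                    **row.to_dict(),
                    "alert_flag": date in alert_dates,
                    "rule": alert_dates.get(date, "")})
            for a in alerts:
                alert_rows.append({"subject_id": subject.subject_id,
                                   "date": a.date, "rule": a.rule,
                                   "message": a.message})
        if "score" in stage_set:
            pd.DataFrame(score_rows).to_csv(outdir / "hscores.csv",
                                            index=False)
            pd.DataFrame(alert_rows,
                         columns=["subject_id", "date", "rule", "message"]
                         ).to_csv(outdir / "alerts.csv", index=False)
            record("score", t0, rows=len(score_rows), alerts=len(alert_rows))

    if "features" in stage_set:
        t0 = time.perf_counter()
        frames = []
        for sid, (subject, daily, _, _) in per_subject.items():
            feat = extend_features(daily)
            feat.insert(0, "subject_id", sid)
            frames.append(feat.reset_index(names="date"))
        features_df = pd.concat(frames, ignore_index=True)
        features_df.to_csv(outdir / "features.csv", index=False)
        record("features", t0, rows=len(features_df))

    if "dgc" in stage_set:
        t0 = time.perf_counter()
        sample_rows, test_rows = [], []
        for feature in DGC_FEATURES:
            crm_s, ctrl_s = [], []
            for sid, (subject, daily, scores, alerts) in per_subject.items():
                times = ([a.date for a in alerts]
                         if subject.group == "CRM"
                         else pseudo_alert_times(scores["average"]))
                samples = dgc_samples(daily[feature], times, sid, feature)
                (crm_s if subject.group == "CRM" else ctrl_s).extend(samples)
                for s in samples:
                    sample_rows.append({
                        "subject_id": sid, "group": subject.group,
                        "feature": feature, "t": s.t, "dgc": s.dgc})
            result = compare_groups(crm_s, ctrl_s, feature)
            test_rows.append({
                "feature": feature,
                "n_crm_subjects": len(result.crm_medians),
                "n_control_subjects": len(result.control_medians),
                "crm_median": (float(np.median(result.crm_medians))
                               if result.crm_medians else np.nan),
                "control_median": (float(np.median(result.control_medians))
                                   if result.control_medians else np.nan),
                "ks_statistic": result.ks_statistic, "ks_p": result.ks_p,
                "mw_statistic": result.mw_statistic, "mw_p": result.mw_p,
                "computable": result.computable})
        pd.DataFrame(sample_rows).to_csv(outdir / "dgc_samples.csv",
                                         index=False)
        pd.DataFrame(test_rows).to_csv(outdir / "dgc_group_tests.csv",
                                       index=False)
        record("dgc", t0, samples=len(sample_rows), features=len(test_rows))

    if "adherence" in stage_set:
        t0 = time.perf_counter()
        trend_rows = []
        by_group: dict[str, list] = {"CRM": [], "non-CRM": []}
        for subject in subjects:
            trend = subject_trends(subject)
            by_group[subject.group].append(trend)
            for i, (date, rate) in enumerate(trend.points.items()):
                trend_rows.append({"subject_id": subject.subject_id,
                                   "group": subject.group, "unit": i,
                                   "period_start": date, "wear_rate": rate})
        pd.DataFrame(trend_rows).to_csv(outdir / "wear_trends.csv",
                                        index=False)
        group_rows = []
        for group, trends in by_group.items():
            usable = [t for t in trends if len(t.ma)]
            if not usable:
                continue
            gt = group_trend(usable)
            for unit, row in gt.iterrows():
                group_rows.append({"group": group, "unit": unit,
                                   "ma": row["ma"], "msd": row["msd"]})
        pd.DataFrame(group_rows).to_csv(outdir / "wear_trends_group.csv",
                                        index=False)
        record("adherence", t0, rows=len(trend_rows))

    if "outcomes" in stage_set:
        t0 = time.perf_counter()
        start = subjects[0].study_period()[0].date()
        period = (start, start + dt.timedelta(days=config.cohort.days))
        frame = outcomes_frame(derive_outcomes(s, period) for s in subjects)
        fits = (fit_all_outcomes(frame, adjusted=False,
                                 family=config.glm_family)
                + fit_all_outcomes(frame, adjusted=True,
                                   family=config.glm_family))
        results_table(fits).to_csv(outdir / "glm_results.csv", index=False)
        record("outcomes", t0, fits=len(fits))

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return outdir


# ---------------------------------------------------------------------------
# input validation

def validate_inputs(path: Path | str) -> list[dict]:
    """Schema-check every subject directory under ``path``.

    Returns a list of findings; empty means pristine. Each finding
    holds the file, an optional line, the problem, and whether it is
    auto-fixable (currently: out-of-order sensor rows, which readers
    sort on load).
    """
    import warnings as _warnings

    from .records import ParseError
    from .io import read_subject

    path = Path(path)
    findings: list[dict] = []
    subject_dirs = sorted(p for p in path.iterdir()
                          if p.is_dir() and (p / "cohort.json").exists())
    if not subject_dirs:
        findings.append({"file": str(path), "line": None,
                         "problem": "no subject directories found",
                         "auto_fixable": False})
    for sub in subject_dirs:
        try:
            with _warnings.catch_warnings(record=True) as caught:
                _warnings.simplefilter("always")
                read_subject(sub)
            for w in caught:
                findings.append({"file": str(sub), "line": None,
                                 "problem": str(w.message),
                                 "auto_fixable": "out-of-order" in str(w.message)})
        except ParseError as exc:
            findings.append({"file": exc.file or str(sub), "line": exc.line,
                             "problem": str(exc), "auto_fixable": False})
    return findings
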