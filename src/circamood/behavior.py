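"""Pre/post-alert behaviour change: the delta-of-gradient-change (DGC)
statistic and its two-group distribution tests.

For an alert at day ``t`` and a daily feature series ``x``, two 4-point
windows share the alert day: ``X_before = (x_{t-3}, ..., x_t)`` and
``X_after = (x_t, ..., x_{t+3})``. ``DGC = g(X_after) - g(X_before)``
where ``g`` is the OLS slope of value against index. A positive DGC
means the feature trended upward after the alert relative to before.

Group comparison follows the convention of testing per-subject medians:
each subject contributes the median of their DGC samples, and the two
groups of medians are compared with two-sided Kolmogorov-Smirnov and
Mann-Whitney U tests. Alert days with any missing value in the 7-point
window contribute no sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .hscore import Alert, evaluate_alerts

WINDOW = 3  # days on each side of the alert day


def trend_gradient(values: Sequence[float]) -> float:
    """OLS slope of equally spaced values against index 0..n-1.

    Raises ValueError for fewer than two points (no trend is defined).
    """
    y = np.asarray(values, dtype=float)
    if len(y) < 2:
        raise ValueError("gradient needs at least two points")
    x = np.arange(len(y), dtype=float)
    xc = x - x.mean()
    return float((xc * (y - y.mean())).sum() / (xc ** 2).sum())


@dataclass(frozen=True)
class DGCSample:
    """One alert-anchored behaviour-change measurement."""

    subject_id: str
    feature: str
    t: int  # day index of the alert within the series
    x_before: tuple[float, float, float, float]
    x_after: tuple[float, float, float, float]
    dgc: float


def dgc(series: pd.Series, t, subject_id: str = "",
        feature: str = "") -> Optional[DGCSample]:
    """DGC at alert time ``t`` on a daily feature series.

    ``series`` is indexed by day (dates or integers); ``t`` must be an
    index label with all of ``t-3 .. t+3`` present and non-missing,
    otherwise the sample is omitted (returns ``None``).
    """
    pos = series.index.get_indexer([t])[0]
    if pos < WINDOW or pos + WINDOW >= len(series):
        return None
    window = series.iloc[pos - WINDOW:pos + WINDOW + 1].to_numpy(dtype=float)
    if not np.all(np.isfinite(window)):
        return None
    before = window[:WINDOW + 1]
    after = window[WINDOW:]
    value = trend_gradient(after) - trend_gradient(before)
    return DGCSample(subject_id, feature, t,
                     tuple(before), tuple(after), value)


def dgc_samples(series: pd.Series, alert_times: Iterable,
                subject_id: str = "", feature: str = "") -> list[DGCSample]:
    """All computable DGC samples for one subject and feature."""
    out = []
    for t in alert_times:
        sample = dgc(series, t, subject_id, feature)
        if sample is not None:
            out.append(sample)
    return out


def pseudo_alert_times(averages: pd.Series) -> list:
    """Days the alert rules *would* have fired for a control subject.

    Identical logic to the delivered alerts — only delivery differs —
    so both groups are anchored at comparable time points.
    """
    return [a.date for a in evaluate_alerts(averages)]


def alert_days(alerts: Iterable[Alert]) -> list:
    return [a.date for a in alerts]


@dataclass(frozen=True)
class DGCGroupResult:
    """Two-group comparison of per-subject median DGC values."""

    feature: str
    crm_medians: tuple[float, ...]
    control_medians: tuple[float, ...]
    ks_statistic: float
    ks_p: float
    mw_statistic: float
    mw_p: float
    computable: bool = True


def subject_medians(samples: Iterable[DGCSample]) -> dict[str, float]:
    """Median DGC per subject."""
    values: dict[str, list[float]] = {}
    for s in samples:
        values.setdefault(s.subject_id, []).append(s.dgc)
    return {sid: float(np.median(v)) for sid, v in values.items()}


def compare_groups(crm_samples: Iterable[DGCSample],
                   control_samples: Iterable[DGCSample],
                   feature: str = "") -> DGCGroupResult:
    """KS and Mann-Whitney tests on per-subject median DGC values.

    A group with no computable subject yields a flagged, non-computable
    result rather than an exception.
    """
    crm = tuple(subject_medians(crm_samples).values())
    ctrl = tuple(subject_medians(control_samples).values())
    if not crm or not ctrl:
        return DGCGroupResult(feature, crm, ctrl,
                              np.nan, np.nan, np.nan, np.nan,
                              computable=False)
    ks = stats.ks_2samp(crm, ctrl)
    mw = stats.mannwhitneyu(crm, ctrl, alternative="two-sided")
    return DGCGroupResult(feature, crm, ctrl,
                          float(ks.statistic), float(ks.pvalue),
                          float(mw.statistic), float(mw.pvalue))


def benjamini_hochberg(p_values: Mapping[str, float],
                       alpha: float = 0.05) -> dict[str, bool]:
    """Optional BH step-up decision across features (off by default in
    reporting; per-feature raw p-values are the primary output)."""
    items = [(k, v) for k, v in p_values.items() if np.isfinite(v)]
    if not items:
        return {}
    items.sort(key=lambda kv: kv[1])
    m = len(items)
    decisions = {k: False for k, _ in items}
    max_k = 0
    for rank, (_, p) in enumerate(items, start=1):
        if p <= alpha * rank / m:
            max_k = rank
    for rank, (name, _) in enumerate(items, start=1):
        decisions[name] = rank <= max_k
    return decisions
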