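"""Comparison of fitted recruitment curves across conditions and subjects.

Three curve metrics, each taken against a designated baseline curve (the
first session of a record):

MEP metric (vertical cut)
    Find the stimulation intensity ``Stim_M`` at which the baseline curve
    reaches ``M%`` of its upper asymptote, then read every curve at that
    intensity.  Values are reported as percent of the baseline response.
Stimulation metric (horizontal cut)
    Take ``S%`` of the baseline session's maximum intensity, read the
    baseline response ``MEP_S`` there, then find the intensity each curve
    needs to reach ``MEP_S``.  Values are percent of the reference intensity;
    curves that cannot attain ``MEP_S`` get NaN plus a warning.
Slope metric
    Regression slope of each curve's near-linear mid-segment (the contiguous
    dense-grid region where the derivative is at least 90% of its maximum),
    optionally normalized by the baseline slope.

Group summaries across subjects are plain means with standard errors
(sample SD over sqrt(n)).  No inferential statistics are computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .curvefit import (RecruitmentCurve, TargetOutOfRange, invert_sigmoid,
                       sigmoid_eval)
from .data_model import ValidationError
from .quantify import QuantifiedSession

__all__ = [
    "CurveSet",
    "MetricResult",
    "GroupSummary",
    "UnattainableTargetWarning",
    "mep_metric",
    "stim_metric",
    "slope_metric",
    "group_aggregate",
    "direct_mep_comparison",
]

DEFAULT_CUTOFF_PCT = 50.0
LINEAR_REGION_FRACTION = 0.9


class UnattainableTargetWarning(UserWarning):
    """A curve cannot reach the requested response level (horizontal cut)."""


@dataclass
class CurveSet:
    """The fitted curves of one record: baseline first, then conditions."""

    baseline: RecruitmentCurve
    others: list[RecruitmentCurve]
    condition_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.condition_labels:
            self.condition_labels = (
                ["baseline"] + [f"cond{i + 1}" for i in range(len(self.others))])
        if len(self.condition_labels) != 1 + len(self.others):
            raise ValidationError("one label per curve (baseline included)")

    @property
    def curves(self) -> list[RecruitmentCurve]:
        return [self.baseline] + list(self.others)


@dataclass
class MetricResult:
    metric_type: str                 # MEP | STIM | SLOPE
    cutoff_pct: float | None
    condition_labels: list[str]
    raw_values: np.ndarray
    normalized: np.ndarray           # baseline == 100 (or 1.0 for SLOPE)

    def as_change(self) -> np.ndarray:
        """Percent *change* from baseline instead of percent of baseline."""
        return self.normalized - 100.0


@dataclass
class GroupSummary:
    metric_type: str
    cutoff_pct: float | None
    condition_labels: list[str]
    means: np.ndarray
    sems: np.ndarray
    n_used: np.ndarray               # records contributing per condition


# ---------------------------------------------------------------------------
# Curve metrics
# ---------------------------------------------------------------------------

def mep_metric(curves: CurveSet, m_pct: float = DEFAULT_CUTOFF_PCT
               ) -> MetricResult:
    """Vertical cut: MEP magnitudes at the baseline's M% intensity."""
    if not 0 < m_pct < 100:
        raise ValidationError("m_pct must be in (0, 100)")
    base = curves.baseline.params
    target = m_pct / 100.0 * base.M
    lo, hi = sorted((base.P, base.M))
    if not lo < target < hi:
        raise ValidationError(
            f"target response {target:g} not strictly inside the baseline "
            f"range ({lo:g}, {hi:g})")
    stim_m = invert_sigmoid(base, target)
    raw = np.array([sigmoid_eval(c.params, stim_m) for c in curves.curves])
    normalized = 100.0 * raw / raw[0]
    return MetricResult("MEP", m_pct, list(curves.condition_labels),
                        raw, normalized)


def stim_metric(curves: CurveSet, s_pct: float = DEFAULT_CUTOFF_PCT
                ) -> MetricResult:
    """Horizontal cut: intensities needed to match the baseline response.

    The reference intensity is ``s_pct%`` of the baseline session's maximum
    intensity; the response the baseline produces there is the level every
    other curve must attain.  Curves whose upper asymptote falls short get a
    NaN marker and an :class:`UnattainableTargetWarning` rather than an
    error, so group summaries degrade gracefully.
    """
    if not 0 < s_pct <= 100:
        raise ValidationError("s_pct must be in (0, 100]")
    stim_ref = s_pct / 100.0 * curves.baseline.x_span[1]
    mep_s = sigmoid_eval(curves.baseline.params, stim_ref)
    raw = np.empty(len(curves.curves))
    raw[0] = stim_ref  # closed-form identity: invert(baseline, mep_s)
    for i, curve in enumerate(curves.curves[1:], start=1):
        try:
            raw[i] = invert_sigmoid(curve.params, mep_s)
        except TargetOutOfRange:
            warnings.warn(
                f"condition {curves.condition_labels[i]!r} cannot attain the "
                f"baseline response {mep_s:g}; marked undefined",
                UnattainableTargetWarning, stacklevel=2)
            raw[i] = np.nan
    normalized = 100.0 * raw / stim_ref
    return MetricResult("STIM", s_pct, list(curves.condition_labels),
                        raw, normalized)


def _linear_region_slope(curve: RecruitmentCurve,
                         fraction: float = LINEAR_REGION_FRACTION) -> float:
    """Regression slope over the contiguous near-maximal-derivative region."""
    dy = np.gradient(curve.y_dense, curve.x_dense)
    peak = int(np.argmax(dy))
    mask = dy >= fraction * dy[peak]
    lo = peak
    while lo > 0 and mask[lo - 1]:
        lo -= 1
    hi = peak
    while hi < len(mask) - 1 and mask[hi + 1]:
        hi += 1
    xs, ys = curve.x_dense[lo:hi + 1], curve.y_dense[lo:hi + 1]
    if len(xs) < 2:
        return 0.0
    return float(np.polyfit(xs, ys, 1)[0])


def slope_metric(curves: CurveSet, normalize: bool = True,
                 fraction: float = LINEAR_REGION_FRACTION) -> MetricResult:
    """Slope of each curve's linear portion, optionally baseline-normalized."""
    raw = np.array([_linear_region_slope(c, fraction) for c in curves.curves])
    if normalize:
        if abs(raw[0]) < 1e-12:
            raise ValidationError(
                "baseline slope is ~0; normalized slope metric undefined")
        normalized = raw / raw[0]
    else:
        normalized = raw.copy()
    return MetricResult("SLOPE", None, list(curves.condition_labels),
                        raw, normalized)


# ---------------------------------------------------------------------------
# Aggregation across subjects
# ---------------------------------------------------------------------------

def group_aggregate(per_record_results: list[MetricResult]) -> GroupSummary:
    """Mean and standard error of normalized values across records.

    All records must share the condition count (the master-file rule).  NaN
    markers are excluded; the number of contributing records per condition is
    reported.  A single contributing record gives SE = NaN.
    """
    if not per_record_results:
        raise ValidationError("no metric results to aggregate")
    first = per_record_results[0]
    n_cond = len(first.normalized)
    if any(len(r.normalized) != n_cond for r in per_record_results):
        raise ValidationError("records disagree on the number of conditions")
    mat = np.vstack([r.normalized for r in per_record_results])
    means = np.empty(n_cond)
    sems = np.empty(n_cond)
    n_used = np.zeros(n_cond, dtype=int)
    for j in range(n_cond):
        col = mat[:, j]
        col = col[~np.isnan(col)]
        n_used[j] = len(col)
        if len(col) == 0:
            means[j] = sems[j] = np.nan
        else:
            means[j] = np.mean(col)
            sems[j] = (np.std(col, ddof=1) / np.sqrt(len(col))
                       if len(col) > 1 else np.nan)
    return GroupSummary(first.metric_type, first.cutoff_pct,
                        list(first.condition_labels), means, sems, n_used)


def direct_mep_comparison(
        sessions_by_condition: dict[str, list[QuantifiedSession]]
        ) -> GroupSummary:
    """Compare mean quantified MEPs across conditions without curve fitting.

    All trial values of every session under a condition are pooled; the
    grand mean and standard error are reported per condition.
    """
    labels, means, sems, n_used = [], [], [], []
    for label, sessions in sessions_by_condition.items():
        if not sessions:
            raise ValidationError(f"condition {label!r} has no sessions")
        pooled = np.concatenate(
            [np.concatenate(s.per_trial) for s in sessions])
        pooled = pooled[~np.isnan(pooled)]
        if pooled.size == 0:
            raise ValidationError(f"condition {label!r} has no trial values")
        labels.append(label)
        means.append(float(np.mean(pooled)))
        sems.append(float(np.std(pooled, ddof=1) / np.sqrt(pooled.size))
                    if pooled.size > 1 else float("nan"))
        n_used.append(pooled.size)
    return GroupSummary("DIRECT", None, labels, np.array(means),
                        np.array(sems), np.array(n_used))
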