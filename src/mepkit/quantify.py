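"""Scalar quantification of MEP epochs and per-intensity aggregation.

Four metrics are supported:

``auc``
    Trapezoidal integral of the rectified epoch, in signal·seconds.
``rms``
    Root-mean-square amplitude over the epoch duration, computed with the
    same trapezoidal discretization so that RMS >= AUC/duration holds exactly
    (Jensen's inequality, with equality for constant |f|).
``p2p``
    Peak-to-peak amplitude of the raw (unrectified) epoch.
``latency``
    Time from epoch start (end of stimulation) to the first crossing of a
    user-set percentage, referenced to baseline, of the rectified maximum.
    NaN marks epochs that never cross.

Per-intensity values are plain arithmetic means over surviving trials;
latency NaNs are excluded from means with their count reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import SessionData, ValidationError

__all__ = [
    "EpochSignal",
    "QuantifiedSession",
    "auc",
    "rms",
    "peak_to_peak",
    "latency",
    "quantify_session",
    "METRICS",
]


@dataclass
class EpochSignal:
    """A uniformly sampled MEP epoch (amplitude vs. time)."""

    values: np.ndarray
    sampling_rate_hz: float
    t_start_ms: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValidationError("epoch needs a 1-D vector of >= 2 samples")
        if self.sampling_rate_hz <= 0:
            raise ValidationError("sampling rate must be positive")

    @property
    def duration_s(self) -> float:
        """Span b - a of the sampled interval, in seconds."""
        return (self.values.size - 1) / self.sampling_rate_hz

    @property
    def times_ms(self) -> np.ndarray:
        return self.t_start_ms + np.arange(self.values.size) \
            / self.sampling_rate_hz * 1000.0


@dataclass
class QuantifiedSession:
    """Per-trial metric values and per-intensity means for one session."""

    metric_name: str
    stim_intensities: np.ndarray
    per_trial: list[np.ndarray]         # ragged [intensity -> trial values]
    per_intensity_mean: np.ndarray
    undefined_counts: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=int))
    session_id: int = 0


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def auc(epoch: EpochSignal) -> float:
    """Area under the rectified epoch by the trapezoidal rule (signal·s)."""
    return float(np.trapezoid(np.abs(epoch.values),
                              dx=1.0 / epoch.sampling_rate_hz))


def rms(epoch: EpochSignal) -> float:
    """Root-mean-square amplitude: sqrt(trapz(f^2) / (T2 - T1))."""
    energy = np.trapezoid(np.square(epoch.values),
                          dx=1.0 / epoch.sampling_rate_hz)
    return float(np.sqrt(energy / epoch.duration_s))


def peak_to_peak(epoch: EpochSignal) -> float:
    """max(f) - min(f) on the raw epoch; invariant to additive offset."""
    return float(np.max(epoch.values) - np.min(epoch.values))


def latency(epoch: EpochSignal, threshold_pct: float = 20.0,
            baseline_window_ms: float = 2.0) -> float:
    """Delay (ms, relative to epoch start) to threshold crossing, or NaN.

    The threshold is ``base + pct/100 * (max|f| - base)`` where ``base`` is
    the mean rectified amplitude over the leading ``baseline_window_ms``
    (0 gives base = 0).  The rectified trace is scanned so negative-going
    onsets are detected too.
    """
    if not 0 < threshold_pct <= 100:
        raise ValidationError("threshold_pct must be in (0, 100]")
    rect = np.abs(epoch.values)
    n_base = int(np.floor(baseline_window_ms / 1000.0
                          * epoch.sampling_rate_hz))
    if n_base >= epoch.values.size:
        raise ValidationError("baseline window must be shorter than the epoch")
    base = float(np.mean(rect[:n_base])) if n_base > 0 else 0.0
    peak = float(np.max(rect))
    if peak <= base:
        return float("nan")
    thr = base + threshold_pct / 100.0 * (peak - base)
    hits = np.flatnonzero(rect >= thr)
    if hits.size == 0:
        return float("nan")
    return float(hits[0] / epoch.sampling_rate_hz * 1000.0)


METRICS = {"auc": auc, "rms": rms, "p2p": peak_to_peak, "latency": latency}


# ---------------------------------------------------------------------------
# Session-level quantification
# ---------------------------------------------------------------------------

def quantify_session(session: SessionData, spec, metric: str = "p2p",
                     **metric_params) -> QuantifiedSession:
    """Quantify every trial of a session and average within each intensity.

    ``spec`` is a :class:`~mepkit.preprocess.EpochSpec`.  ``metric_params``
    are forwarded to the latency metric (``threshold_pct``,
    ``baseline_window_ms``).  Latency trials that never cross threshold are
    NaN and excluded from the means; their per-intensity counts are reported
    in ``undefined_counts``.
    """
    from .preprocess import extract_epochs  # deferred: avoids module cycle

    metric = metric.lower()
    if metric not in METRICS:
        raise ValidationError(
            f"unknown metric {metric!r}; choose from {sorted(METRICS)}")
    fn = METRICS[metric]
    epochs = extract_epochs(session, spec)
    values = np.array([fn(e, **metric_params) if metric == "latency" else fn(e)
                       for e in epochs])
    offs = session.trial_offsets()
    per_trial = [values[offs[i]:offs[i + 1]]
                 for i in range(len(session.trials_per_stim))]
    means = np.empty(len(per_trial))
    undef = np.zeros(len(per_trial), dtype=int)
    for i, vals in enumerate(per_trial):
        ok = vals[~np.isnan(vals)]
        undef[i] = len(vals) - len(ok)
        means[i] = np.mean(ok) if len(ok) else np.nan
    return QuantifiedSession(metric_name=metric,
                             stim_intensities=session.stim_intensities.copy(),
                             per_trial=per_trial, per_intensity_mean=means,
                             undefined_counts=undef,
                             session_id=session.session_id)
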