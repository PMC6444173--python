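"""Epoch extraction, zero-phase filtering and artifact-screening support.

Filtering is optional and off by default (surface-EMG recruitment data are
often analysed raw).  When enabled, a band-pass Butterworth with 5/600 Hz
default edges is applied forward and backward (zero phase); the filter order
is chosen automatically from a 4 dB passband-ripple / 30 dB stopband-
attenuation requirement.  A second-order notch can additionally remove up to
6 harmonics of 60 Hz line noise.

There is no automated artifact deletion: :func:`suggest_outliers` only flags
suspicious trials for the user to review (e.g. via the heat-map matrix).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .data_model import SessionData, ValidationError
from .quantify import EpochSignal, QuantifiedSession

__all__ = [
    "EpochSpec",
    "FilterSpec",
    "extract_epochs",
    "bandpass_zero_phase",
    "notch_harmonics",
    "filter_session",
    "heatmap_matrix",
    "suggest_outliers",
]

NOTCH_BASE_HZ = 60.0
MAX_NOTCH_HARMONICS = 6


@dataclass(frozen=True)
class EpochSpec:
    """Half-open analysis window [start_ms, stop_ms) relative to sweep onset
    (end of stimulation), plus the recording channel of interest."""

    start_ms: float
    stop_ms: float
    channel_index: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.start_ms < self.stop_ms:
            raise ValidationError(
                f"need 0 <= start_ms < stop_ms, got [{self.start_ms}, "
                f"{self.stop_ms})")

    def sample_bounds(self, fs: float) -> tuple[int, int]:
        start = int(np.floor(self.start_ms / 1000.0 * fs))
        n = int(np.floor((self.stop_ms - self.start_ms) / 1000.0 * fs))
        return start, start + n


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass + optional notch configuration.

    Defaults: 5–600 Hz edges, 4 dB passband ripple and 30 dB stopband
    attenuation for automatic order selection.  Stopband edges (needed by the
    order estimate but not part of the published defaults) sit at half the
    low edge and 1.25x the high edge, clipped below Nyquist.
    """

    enabled: bool = False
    low_hz: float = 5.0
    high_hz: float = 600.0
    passband_ripple_db: float = 4.0
    stopband_atten_db: float = 30.0
    notch_enabled: bool = False
    notch_base_hz: float = NOTCH_BASE_HZ
    notch_harmonics: int = 1
    notch_q: float = 30.0

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValidationError("need 0 < low_hz < high_hz")
        if not 1 <= self.notch_harmonics <= MAX_NOTCH_HARMONICS:
            raise ValidationError(
                f"notch_harmonics must be 1..{MAX_NOTCH_HARMONICS}, got "
                f"{self.notch_harmonics}")

    def validate_for_rate(self, fs: float) -> None:
        nyq = fs / 2.0
        if self.high_hz >= nyq:
            raise ValidationError(
                f"band-pass cutoff {self.high_hz} Hz at/above Nyquist "
                f"({nyq} Hz)")
        if self.notch_enabled and self.notch_harmonics * self.notch_base_hz >= nyq:
            raise ValidationError("notch harmonic at/above Nyquist")


# ---------------------------------------------------------------------------
# Epoching
# ---------------------------------------------------------------------------

def extract_epochs(session: SessionData, spec: EpochSpec) -> list[EpochSignal]:
    """Cut the analysis window out of every sweep on the chosen channel.

    Each epoch carries floor((stop-start)/1000 * fs) samples (half-open
    window convention).
    """
    if not session.annotated:
        raise ValidationError("session must be annotated before epoching")
    if not 0 <= spec.channel_index < session.n_channels:
        raise ValidationError(
            f"channel index {spec.channel_index} out of range "
            f"(session has {session.n_channels})")
    if spec.stop_ms > session.sweep_duration_ms:
        raise ValidationError(
            f"epoch window stops at {spec.stop_ms} ms but sweeps last "
            f"{session.sweep_duration_ms:g} ms")
    a, b = spec.sample_bounds(session.sampling_rate_hz)
    chan = session.sweeps[:, spec.channel_index, :]
    return [EpochSignal(values=chan[a:b, k],
                        sampling_rate_hz=session.sampling_rate_hz,
                        t_start_ms=spec.start_ms)
            for k in range(session.n_sweeps)]


# ---------------------------------------------------------------------------
# Zero-phase filtering
# ---------------------------------------------------------------------------

def _butter_sos(spec: FilterSpec, fs: float):
    nyq = fs / 2.0
    wp = [spec.low_hz, spec.high_hz]
    ws = [0.5 * spec.low_hz, min(1.25 * spec.high_hz, 0.98 * nyq)]
    order, wn = scipy.signal.buttord(wp, ws, spec.passband_ripple_db,
                                     spec.stopband_atten_db, fs=fs)
    return scipy.signal.butter(order, wn, btype="bandpass", output="sos", fs=fs)


def bandpass_zero_phase(values: np.ndarray, fs: float,
                        spec: FilterSpec | None = None) -> np.ndarray:
    """Apply the band-pass Butterworth forward and backward along axis 0.

    Zero-phase application means no phase distortion (an in-band sinusoid
    comes out time-aligned with the input) at the cost of doubling the
    effective attenuation.  Output length equals input length.
    """
    spec = spec or FilterSpec(enabled=True)
    spec.validate_for_rate(fs)
    sos = _butter_sos(spec, fs)
    return scipy.signal.sosfiltfilt(sos, np.asarray(values, float), axis=0)


def notch_harmonics(values: np.ndarray, fs: float, n_harmonics: int = 1,
                    base_hz: float = NOTCH_BASE_HZ,
                    q: float = 30.0) -> np.ndarray:
    """Zero-phase second-order notch at base_hz * k for k = 1..n_harmonics."""
    if not 1 <= n_harmonics <= MAX_NOTCH_HARMONICS:
        raise ValidationError(
            f"n_harmonics must be 1..{MAX_NOTCH_HARMONICS}, got {n_harmonics}")
    if n_harmonics * base_hz >= fs / 2.0:
        raise ValidationError("notch harmonic at/above Nyquist")
    out = np.asarray(values, float)
    for k in range(1, n_harmonics + 1):
        b, a = scipy.signal.iirnotch(k * base_hz, q, fs=fs)
        out = scipy.signal.filtfilt(b, a, out, axis=0)
    return out


def filter_session(session: SessionData, spec: FilterSpec) -> SessionData:
    """Filter whole sweeps (all channels) before epoching.

    Filtering the full sweep rather than the extracted epoch keeps the
    forward-backward edge transients away from the analysis window.
    """
    if not spec.enabled and not spec.notch_enabled:
        return session
    spec.validate_for_rate(session.sampling_rate_hz)
    out = session.sweeps
    if spec.enabled:
        out = bandpass_zero_phase(out, session.sampling_rate_hz, spec)
    if spec.notch_enabled:
        out = notch_harmonics(out, session.sampling_rate_hz,
                              spec.notch_harmonics, spec.notch_base_hz,
                              spec.notch_q)
    from dataclasses import replace
    return replace(session, sweeps=out)


# ---------------------------------------------------------------------------
# Screening support
# ---------------------------------------------------------------------------

def heatmap_matrix(q: QuantifiedSession) -> np.ndarray:
    """Per-trial metric values as an [intensities x max-trials] matrix.

    Ragged cells (intensities with fewer trials than the maximum) are NaN.
    The matrix is meant for visual screening; its defined cells equal the
    quantified per-trial values exactly.
    """
    n_int = len(q.per_trial)
    width = max(len(v) for v in q.per_trial)
    mat = np.full((n_int, width), np.nan)
    for i, vals in enumerate(q.per_trial):
        mat[i, :len(vals)] = vals
    return mat


def suggest_outliers(q: QuantifiedSession,
                     z_threshold: float = 5.0) -> list[tuple[int, int]]:
    """Flag trials whose robust z-score within their intensity is extreme.

    Each trial value is compared to the median of its intensity block.  The
    scale is a session-pooled MAD (the median of all within-block absolute
    deviations, times 1.4826): with the typical handful of trials per
    intensity a per-block MAD is too unstable to screen with, while trial
    scatter is close to homoscedastic across intensities.  Intensities with
    fewer than two trials are skipped.  Purely advisory — nothing is
    deleted.
    """
    blocks = [np.asarray(v, float) for v in q.per_trial]
    deviations = [np.abs(v - np.median(v)) for v in blocks if len(v) >= 2]
    if not deviations:
        return []
    scale = 1.4826 * float(np.median(np.concatenate(deviations)))
    flags: list[tuple[int, int]] = []
    for i, v in enumerate(blocks):
        if len(v) < 2:
            continue
        dev = np.abs(v - np.median(v))
        if scale == 0:
            # all-but-flagged identical: any deviation is infinitely extreme
            flags.extend((i, j) for j in np.flatnonzero(dev > 0))
        else:
            flags.extend((i, j) for j in np.flatnonzero(dev / scale
                                                        > z_threshold))
    return flags
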