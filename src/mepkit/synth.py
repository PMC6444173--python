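"""Synthetic recruitment-curve sessions with known ground truth.

Each simulated sweep holds one MEP-like waveform: a carrier sinusoid under a
Gaussian envelope (Morlet-like), placed at a fixed onset latency plus
per-trial jitter.  The waveform is chosen because its peak-to-peak amplitude,
AUC and RMS have simple closed forms, so quantifier and fit-recovery checks
can compare against the imposed truth directly.  The waveform's peak-to-peak
amplitude at each stimulation intensity equals a ground-truth sigmoid
evaluated at that intensity plus zero-mean Gaussian trial-to-trial
variability (the scale factor is computed on the sweep's actual sample grid,
so at zero noise the quantified peak-to-peak reproduces the sigmoid
exactly).  Optional 60 Hz line noise, slow baseline drift and injected
artifact trials emulate further nuisance features of real surface-EMG
recordings.

Randomness is driven by per-sweep substreams derived from (seed, sweep
index), so the draws for one trial never depend on how many other trials are
generated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .curvefit import SigmoidParams, sigmoid_eval
from .data_model import SessionData, ValidationError, annotate_session

__all__ = ["SynthTruth", "generate_session", "inject_artifact"]


@dataclass
class SynthTruth:
    """Ground truth for one synthetic session.

    Sigmoid defaults put the midpoint at the center of the default intensity
    range (0.5–4.5 mA in 0.5 steps) with near-saturation at the top; the
    amplitude range 0.1–2.0 mV and 5 kHz sampling mirror typical rodent
    epidural-stimulation recordings.  The default additive-noise SD is
    0.05 mV (the canonical simulation scenario's "5% noise": 5% of the
    1 mV half-maximum response).
    """

    P: float = 0.1              # lower asymptote, mV peak-to-peak
    M: float = 2.0              # upper asymptote, mV peak-to-peak
    L: float = 0.5              # logarithmic slope (rate = exp(L) ~ 1.65/mA)
    K: float = 2.5              # sigmoid location, mA
    Q: float = 1.0              # shape constant (midpoint == K when Q == 1)
    carrier_hz: float = 300.0
    envelope_sd_ms: float = 1.5
    onset_ms: float = 10.0      # MEP onset after end of stimulation
    jitter_sd_ms: float = 0.5
    noise_sd: float | None = None      # Gaussian noise SD, mV (default 0.05)
    line_noise_amp: float = 0.0        # 60 Hz amplitude, mV
    drift_amp: float = 0.0             # slow baseline drift amplitude, mV
    fs: float = 5000.0
    intensities: np.ndarray = field(
        default_factory=lambda: 0.5 * np.arange(1, 10))
    trials_per_stim: np.ndarray | int = 10
    sweep_ms: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if np.isscalar(self.trials_per_stim):
            self.trials_per_stim = np.full(len(self.intensities),
                                           int(self.trials_per_stim))
        self.trials_per_stim = np.asarray(self.trials_per_stim, dtype=int)
        if self.noise_sd is None:
            self.noise_sd = 0.05
        if self.fs <= 0 or np.any(self.trials_per_stim < 1):
            raise ValidationError("invalid synthesis parameters")
        if self.onset_ms >= self.sweep_ms:
            raise ValidationError("MEP onset must fall inside the sweep")

    @property
    def sigmoid(self) -> SigmoidParams:
        return SigmoidParams(self.P, self.M, self.L, self.K, self.Q)


def _sweep_rng(seed: int, sweep_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(sweep_index,)))


def generate_session(truth: SynthTruth) -> tuple[SessionData, SynthTruth]:
    """Simulate one annotated single-channel session from the ground truth.

    Returns the session together with the (unchanged) truth so callers can
    carry the generating parameters alongside the data.  The same truth
    (including seed) always produces bit-identical output.
    """
    n_samples = int(round(truth.sweep_ms / 1000.0 * truth.fs))
    t_ms = np.arange(n_samples) / truth.fs * 1000.0
    mean_amplitudes = sigmoid_eval(
        truth.sigmoid, np.repeat(truth.intensities, truth.trials_per_stim))
    n_sweeps = len(mean_amplitudes)
    sweeps = np.empty((n_samples, 1, n_sweeps))
    for k in range(n_sweeps):
        rng = _sweep_rng(truth.seed, k)
        t0 = truth.onset_ms + rng.normal(0.0, truth.jitter_sd_ms)
        # trial-to-trial amplitude variability around the sigmoid, floored at 0
        amplitude = max(0.0, mean_amplitudes[k]
                        + rng.normal(0.0, truth.noise_sd))
        dt = t_ms - t0
        unit = (np.cos(2e-3 * np.pi * truth.carrier_hz * dt)
                * np.exp(-0.5 * (dt / truth.envelope_sd_ms) ** 2))
        p2p = float(np.max(unit) - np.min(unit))
        wave = amplitude / p2p * unit if p2p > 0 else np.zeros_like(unit)
        if truth.line_noise_amp:
            phase = rng.uniform(0.0, 2.0 * np.pi)
            wave = wave + truth.line_noise_amp * np.sin(
                2e-3 * np.pi * 60.0 * t_ms + phase)
        if truth.drift_amp:
            phase = rng.uniform(0.0, 2.0 * np.pi)
            wave = wave + truth.drift_amp * np.sin(
                2.0 * np.pi * t_ms / (4.0 * truth.sweep_ms) + phase)
        sweeps[:, 0, k] = wave
    session = annotate_session(
        SessionData(sweeps, channel_labels=["emg0"]),
        truth.intensities, truth.trials_per_stim, truth.fs)
    return session, truth


def inject_artifact(session: SessionData, intensity_idx: int, trial_idx: int,
                    scale: float = 50.0,
                    transient_amplitude: float | None = None) -> SessionData:
    """Corrupt one trial: scale its sweep and add a square transient.

    The default transient amplitude is ``(scale - 1)`` times the sweep's peak
    absolute value over a 2 ms block in mid-sweep, so ``scale=1`` with a zero
    transient leaves the session unchanged.  Supports screening scenarios
    where a single bad trial must stand out on the heat map.
    """
    if scale < 1:
        raise ValidationError("artifact scale must be >= 1")
    k = session.sweep_index(intensity_idx, trial_idx)  # validates indices
    sweeps = session.sweeps.copy()
    sweep = sweeps[:, :, k]
    if transient_amplitude is None:
        transient_amplitude = (scale - 1.0) * float(np.max(np.abs(sweep)))
    sweep = sweep * scale
    n = sweep.shape[0]
    width = max(1, int(round(2e-3 * session.sampling_rate_hz)))
    start = n // 2
    sweep[start:start + width, :] += transient_amplitude
    sweeps[:, :, k] = sweep
    return replace(session, sweeps=sweeps)
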