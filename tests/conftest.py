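import numpy as np
import pytest

from mepkit.curvefit import RecruitmentCurve, SigmoidParams, sigmoid_eval
from mepkit.synth import SynthTruth, generate_session


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def make_curve():
    """Build a RecruitmentCurve directly from known sigmoid parameters."""

    def _make(P=0.0, M=10.0, L=0.0, K=5.0, Q=1.0, span=(0.0, 10.0)):
        params = SigmoidParams(P, M, L, K, Q)
        x = np.linspace(span[0], span[1], 200)
        return RecruitmentCurve(
            params=params, x_dense=x, y_dense=sigmoid_eval(params, x),
            fit_error=0.0, r_squared=1.0, tolerance_used=0.1, saturated=True,
            saturation_slope=0.0, iterations=1, stop_reason="tolerance",
            stall_count=0)

    return _make


@pytest.fixture
def synth_session():
    """Canonical synthetic session: 9 intensities x 5 trials, seed 0."""
    truth = SynthTruth(intensities=0.5 * np.arange(1, 10), trials_per_stim=5,
                       seed=0)
    session, truth = generate_session(truth)
    return session, truth
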