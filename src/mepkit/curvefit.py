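"""Sigmoidal recruitment-curve fitting.

The recruitment curve — MEP magnitude vs. stimulation intensity — is modelled
by a generalized logistic (a two-state Boltzmann sigmoid)

    y(x) = P + (M - P) / (1 + Q * exp(-exp(L) * (x - K)))

with lower asymptote ``P``, upper asymptote ``M``, logarithmic slope ``L``
(the growth rate is ``exp(L)`` per intensity unit, always positive), offset
``K`` and shape constant ``Q``.  Only ``P, M, L, K`` are optimized; ``Q`` is
fixed from the data at the lowest-intensity mean response.  Because ``Q`` is
fixed, ``K`` alone is not the half-maximum point: the curve's midpoint is
``K + ln(Q)/exp(L)`` (exposed as :attr:`SigmoidParams.midpoint`), which is
the identifiable location parameter to compare across fits.

Optimization is iterated Nelder-Mead from heuristic initial estimates.  One
*iteration* of the fit is one optimizer round: a Nelder-Mead run to internal
convergence, restarted from the best point found so far.  Three stopping
rules are checked in order after each round:

1. the normalized fit error falls below the tolerance (default 0.1);
2. the error improved, but by less than 0.01 (diminishing returns);
3. the error has not improved for 10 consecutive rounds (stall).

The fit error is the residual RMSE divided by the data range, so the default
tolerance is scale-free.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.optimize

from .data_model import ValidationError

__all__ = [
    "SigmoidParams",
    "RecruitmentCurve",
    "SaturationWarning",
    "TargetOutOfRange",
    "sigmoid_eval",
    "invert_sigmoid",
    "initial_estimates",
    "fit_sigmoid",
    "fit_error",
    "r_squared",
    "saturation_check",
]

DEFAULT_TOLERANCE = 0.1
STALL_DELTA = 0.01          # rule 2: smallest improvement worth continuing for
STALL_LIMIT = 10            # rule 3: consecutive non-improving iterations
SATURATION_SLOPE = 0.2      # strict upper bound for the saturated regime
Q_EPSILON = 1e-6


class SaturationWarning(UserWarning):
    """Recruitment curve does not appear to saturate at maximum intensity."""


class TargetOutOfRange(ValueError):
    """Requested response level lies outside the curve's open (P, M) range."""


@dataclass(frozen=True)
class SigmoidParams:
    P: float
    M: float
    L: float
    K: float
    Q: float

    def __post_init__(self) -> None:
        if self.Q <= 0:
            raise ValidationError("Q must be positive")

    @property
    def rate(self) -> float:
        return float(np.exp(self.L))

    @property
    def midpoint(self) -> float:
        """Intensity at which y = (P+M)/2; equals K only when Q = 1."""
        return self.K + np.log(self.Q) / self.rate

    def as_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in "PMLKQ"}


@dataclass
class RecruitmentCurve:
    """A fitted sigmoid plus its dense evaluation and diagnostics."""

    params: SigmoidParams
    x_dense: np.ndarray
    y_dense: np.ndarray
    fit_error: float
    r_squared: float
    tolerance_used: float
    saturated: bool
    saturation_slope: float
    iterations: int
    stop_reason: str            # tolerance | delta | stall
    stall_count: int            # consecutive non-improving iterations at stop

    @property
    def x_span(self) -> tuple[float, float]:
        return float(self.x_dense[0]), float(self.x_dense[-1])


# ---------------------------------------------------------------------------
# Model evaluation and inversion
# ---------------------------------------------------------------------------

def sigmoid_eval(params: SigmoidParams, x):
    """Evaluate the sigmoid at scalar or vector ``x``.

    Monotone in x whenever M != P, with limits P (x -> -inf) and
    M (x -> +inf).
    """
    x = np.asarray(x, dtype=float)
    with np.errstate(over="ignore"):
        y = params.P + (params.M - params.P) \
            / (1.0 + params.Q * np.exp(-params.rate * (x - params.K)))
    return float(y) if y.ndim == 0 else y


def invert_sigmoid(params: SigmoidParams, y_target: float) -> float:
    """Intensity at which the curve attains ``y_target`` (closed form).

    Raises :class:`TargetOutOfRange` when the target is not strictly inside
    the open interval (min(P, M), max(P, M)).
    """
    lo, hi = sorted((params.P, params.M))
    if not lo < y_target < hi:
        raise TargetOutOfRange(
            f"target {y_target} outside the curve's open range ({lo}, {hi})")
    arg = (params.M - params.P) / (params.Q * (y_target - params.P)) \
        - 1.0 / params.Q
    return float(params.K - np.log(arg) / params.rate)


# ---------------------------------------------------------------------------
# Initial estimates
# ---------------------------------------------------------------------------

def _clipped_window_median(sorted_y: np.ndarray, pct: float) -> float:
    """Median of 5 values centered on the nearest-rank percentile position.

    The window is clipped at the vector ends; an even-length clipped window
    takes the mean of its two central values (numpy's median).
    """
    n = len(sorted_y)
    idx = int(np.ceil(pct / 100.0 * n)) - 1  # nearest-rank, 0-based
    idx = min(max(idx, 0), n - 1)
    lo, hi = max(0, idx - 2), min(n, idx + 3)
    return float(np.median(sorted_y[lo:hi]))


def initial_estimates(x, y, q: float | None = None) -> SigmoidParams:
    """Heuristic starting parameters for the sigmoid fit.

    P0/M0 are medians of 5-value windows centered on the 5th/95th percentile
    positions of the sorted responses; the half-maximum location is the mean
    of the two intensities whose responses lie closest to (P0+M0)/2, and K0
    places the curve's midpoint there given the fixed Q; L0 comes from the
    steepest discrete slope via the logistic identity (max derivative =
    rate*(M-P)/4); Q is fixed at the lowest-intensity response (floored at
    1e-6) unless overridden.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValidationError("x and y must have equal length")
    if len(x) < 4:
        raise ValidationError("need at least 4 points to fit a sigmoid")
    if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
        raise ValidationError("non-finite values in fit input")

    sorted_y = np.sort(y)
    p0 = _clipped_window_median(sorted_y, 5.0)
    m0 = _clipped_window_median(sorted_y, 95.0)
    q0 = float(q) if q is not None else max(float(y[0]), Q_EPSILON)

    if m0 <= p0:  # flat data: degenerate path, optimizer still runs
        return SigmoidParams(P=float(np.mean(y)), M=float(np.mean(y)),
                             L=0.0, K=float(np.mean(x)), Q=q0)

    center = 0.5 * (p0 + m0)
    nearest = np.argsort(np.abs(y - center), kind="stable")[:2]
    x_half = float(np.mean(x[nearest]))
    s_max = float(np.max(np.diff(y) / np.diff(x)))
    l0 = float(np.log(4.0 * max(s_max, 1e-12) / (m0 - p0)))
    # x_half estimates the half-maximum location; with Q fixed the curve's
    # midpoint is K + ln(Q)/rate, so place K to put the midpoint at x_half
    k0 = x_half - np.log(q0) / np.exp(l0)
    return SigmoidParams(P=p0, M=m0, L=l0, K=k0, Q=q0)


# ---------------------------------------------------------------------------
# Fit error and goodness of fit
# ---------------------------------------------------------------------------

def fit_error(params: SigmoidParams, x: np.ndarray, y: np.ndarray) -> float:
    """Scale-free fit error: residual RMSE divided by the data range."""
    resid = sigmoid_eval(params, x) - y
    span = float(np.max(y) - np.min(y))
    rmse = float(np.sqrt(np.mean(np.square(resid))))
    if not np.isfinite(rmse):
        return float("inf")
    return rmse / (span if span > 0 else 1.0)


def r_squared(y, y_hat) -> float:
    """Coefficient of determination 1 - SSres/SStot.

    Constant data fitted perfectly gives 1; constant data with nonzero
    residuals has no defined R^2 and returns NaN.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValidationError("y and y_hat must have the same length")
    if y.size < 2:
        raise ValidationError("need at least 2 points for R^2")
    ss_res = float(np.sum(np.square(y - y_hat)))
    ss_tot = float(np.sum(np.square(y - np.mean(y))))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else float("nan")
    return 1.0 - ss_res / ss_tot


def saturation_check(x, y, pre_normalized: bool = False
                     ) -> tuple[bool, float]:
    """Check that the curve has reached its plateau at maximum intensity.

    A least-squares line through the last three (x, y) points — with y
    normalized by the maximum mean response and x by the median intensity
    step unless ``pre_normalized`` — must have slope strictly below 0.2.
    A non-saturated curve raises :class:`SaturationWarning` (a warning only;
    analysis proceeds).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValidationError("saturation check needs at least 3 points")
    if pre_normalized:
        xn, yn = x, y
    else:
        step = float(np.median(np.diff(x)))
        ymax = float(np.max(np.abs(y)))
        xn = x / (step if step > 0 else 1.0)
        yn = y / (ymax if ymax > 0 else 1.0)
    slope = float(np.polyfit(xn[-3:], yn[-3:], 1)[0])
    saturated = slope < SATURATION_SLOPE
    if not saturated:
        warnings.warn(
            f"recruitment curve may not be saturated: last-3-point slope "
            f"{slope:.3g} >= {SATURATION_SLOPE}", SaturationWarning,
            stacklevel=2)
    return saturated, slope


# ---------------------------------------------------------------------------
# Nelder-Mead fit with the three stopping rules
# ---------------------------------------------------------------------------

def _nm_round(objective, theta0: np.ndarray) -> tuple[np.ndarray, float, int]:
    """One optimizer round: a Nelder-Mead run to internal convergence."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = scipy.optimize.minimize(
            objective, theta0, method="Nelder-Mead",
            options={"maxiter": 800, "xatol": 1e-8, "fatol": 1e-10})
    return res.x, float(res.fun), int(res.nit)


def _iterate_rounds(x, y, init: SigmoidParams, tolerance: float,
                    delta: float, stall_limit: int, max_rounds: int = 50):
    """Run optimizer rounds under the three stopping rules.

    Returns (params, error, rounds, inner_iterations, stall_count, reason).
    The stall counter counts consecutive rounds with no strict improvement
    and resets whenever a round improves the error by at least ``delta``.
    """
    q = init.Q

    def objective(theta) -> float:
        p, m, l, k = theta
        return fit_error(SigmoidParams(p, m, l, k, q), x, y)

    theta_best = np.array([init.P, init.M, init.L, init.K])
    best = objective(theta_best)
    rounds = inner = stall = 0
    reason = "max_rounds"
    theta = theta_best
    for _ in range(max_rounds):
        theta, err, nit = _nm_round(objective, theta)
        rounds += 1
        inner += nit
        improvement = best - err
        if improvement > 0:
            best, theta_best = err, theta
        if err < tolerance:
            reason = "tolerance"
        elif 0 < improvement < delta:
            reason = "delta"
        elif improvement <= 0:
            stall += 1
            if stall >= stall_limit:
                reason = "stall"
        else:
            stall = 0
        if reason != "max_rounds":
            break
    return (SigmoidParams(*theta_best, q), best, rounds, inner, stall, reason)


def fit_sigmoid(x, y, tolerance: float = DEFAULT_TOLERANCE,
                q: float | None = None, delta_threshold: float = STALL_DELTA,
                stall_limit: int = STALL_LIMIT,
                n_dense: int = 200) -> RecruitmentCurve:
    """Fit the 4-parameter sigmoid to per-intensity mean responses.

    ``q`` overrides the data-derived fixed shape constant (``q=1`` gives the
    standard logistic).  At least one optimizer round always runs; the
    stopping rules are evaluated between rounds in their stated precedence.
    A fit that ends by stalling with error above tolerance is retried once
    from perturbed initials (K and L scaled by 1.1) and the better result
    kept.  The returned curve carries the dense evaluation over the
    intensity span, the normalized fit error, R^2 and the saturation flag;
    ``iterations`` counts optimizer rounds and ``stall_count`` the
    consecutive non-improving rounds at termination.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(np.diff(x) <= 0):
        raise ValidationError("intensities must be strictly ascending")
    init = initial_estimates(x, y, q=q)

    params, err, iterations, _, stall, reason = _iterate_rounds(
        x, y, init, tolerance, delta_threshold, stall_limit)
    if reason in ("delta", "stall") and err > tolerance:
        bumped = SigmoidParams(init.P, init.M, 1.1 * init.L,
                               1.1 * init.K, init.Q)
        params2, err2, it2, _, stall2, reason2 = _iterate_rounds(
            x, y, bumped, tolerance, delta_threshold, stall_limit)
        if err2 < err:
            params, err = params2, err2
            iterations, stall, reason = it2, stall2, reason2

    x_dense = np.linspace(x[0], x[-1], n_dense)
    y_dense = sigmoid_eval(params, x_dense)
    saturated, slope = saturation_check(x, y)
    return RecruitmentCurve(
        params=params, x_dense=x_dense, y_dense=y_dense,
        fit_error=err, r_squared=r_squared(y, sigmoid_eval(params, x)),
        tolerance_used=tolerance, saturated=saturated,
        saturation_slope=slope, iterations=iterations, stop_reason=reason,
        stall_count=stall)
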