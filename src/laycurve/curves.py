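"""Parametric laying-curve models.

Three nonlinear models of the weekly egg-production rate y(t) of a hen as a
function of age t (weeks), each a pure function of its parameters:

* **Segmented polynomial** — a cubic rise from lay onset (tp - tip) to the
  peak p at age tp, followed by a linear decline of slope s.
* **Yang** — a logistic maturation front multiplied by an exponential
  post-peak decline: y = a e^(-x t) / (1 + e^(-c (t - d))).
* **Persistency** — a piecewise-linear trapezoid (rise between t1 and t2,
  plateau of length P, then linear decline b4) built from smoothed ramps
  S(t, k) ~= max(t - k, 0) with a fixed smoothing constant of 0.3 weeks.

All evaluators are vectorised over t and numerically safe for ages in the
usual recording window (the ramp exponent t/0.3 reaches ~1e72 at t = 50, so
everything goes through log-sum-exp).  Each model also exposes its gradient
with respect to the parameters, used by the Gauss-Newton fitter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

SMOOTH = 0.3
"""Fixed smoothing constant of the persistency model (weeks). Structural, never fitted."""


class InvalidParameterError(ValueError):
    """Raised when curve parameters violate a model's domain constraints."""


@dataclass(frozen=True)
class SegPolyParams:
    """Segmented polynomial model parameters.

    p   : peak rate (dimensionless, in [0, 1])
    s   : weekly post-peak decline (rate/week)
    tp  : age at peak (weeks)
    tip : interval from lay onset to peak (weeks), > 0
    """

    p: float
    s: float
    tp: float
    tip: float

    def __post_init__(self) -> None:
        if not self.tip > 0:
            raise InvalidParameterError(f"tip must be > 0, got {self.tip}")
        if self.p < 0:
            raise InvalidParameterError(f"p must be >= 0, got {self.p}")


@dataclass(frozen=True)
class YangParams:
    """Yang model parameters.

    a : scale (dimensionless), >= 0
    c : reciprocal indicator of variation in sexual maturity (1/weeks), > 0
    x : post-peak decline rate (1/weeks)
    d : mean age at sexual maturity (weeks)
    """

    a: float
    c: float
    x: float
    d: float

    def __post_init__(self) -> None:
        if not self.c > 0:
            raise InvalidParameterError(f"c must be > 0, got {self.c}")
        if self.a < 0:
            raise InvalidParameterError(f"a must be >= 0, got {self.a}")


@dataclass(frozen=True)
class PersistencyParams:
    """Persistency model parameters.

    yp : peak rate (dimensionless)
    t1 : slow-to-rapid transition age (weeks)
    t2 : rapid-to-constant transition age (weeks), > t1
    P  : plateau duration ("persistency", weeks), >= 0
    b4 : post-plateau weekly decline (rate/week, typically negative)
    """

    yp: float
    t1: float
    t2: float
    P: float
    b4: float

    def __post_init__(self) -> None:
        if not self.t2 > self.t1:
            raise InvalidParameterError(
                f"t2 must be > t1, got t1={self.t1}, t2={self.t2}"
            )
        if self.P < 0:
            raise InvalidParameterError(f"P must be >= 0, got {self.P}")


def smooth_ramp(t, k):
    """Smoothed ramp S(t, k) ~= max(t - k, 0).

    S(t, k) = 0.3 * [ln(e^(t/0.3) + e^(k/0.3)) - ln(1 + e^(k/0.3))],
    evaluated with log-sum-exp so neither exponential overflows.  The
    approximation error is at most 0.3*ln(2), attained at t = k, and S is
    nondecreasing in t.
    """
    t = np.asarray(t, dtype=float)
    k = np.asarray(k, dtype=float)
    return SMOOTH * (
        np.logaddexp(t / SMOOTH, k / SMOOTH) - np.logaddexp(0.0, k / SMOOTH)
    )


def _smooth_ramp_dk(t, k):
    # dS/dk = sigmoid((k - t)/0.3) - sigmoid(k/0.3)
    t = np.asarray(t, dtype=float)
    k = np.asarray(k, dtype=float)
    return expit((k - t) / SMOOTH) - expit(k / SMOOTH)


def eval_segpoly(t, params: SegPolyParams):
    """Segmented polynomial laying rate at age(s) ``t`` (weeks).

    Cubic rise on [tp - tip, tp], linear decline p - s(t - tp) after the
    peak, 0 before lay onset; never negative.
    """
    t = np.asarray(t, dtype=float)
    p, s, tp, tip = params.p, params.s, params.tp, params.tip
    u = (tp - t) / tip
    cubic = p - 3 * p * u**2 + 2 * p * u**3
    linear = p - s * (t - tp)
    y = np.where(t < tp - tip, 0.0, np.where(t <= tp, cubic, linear))
    return np.maximum(y, 0.0)


def grad_segpoly(t, params: SegPolyParams):
    """Gradient of eval_segpoly w.r.t. (p, s, tp, tip); shape (len(t), 4)."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    p, s, tp, tip = params.p, params.s, params.tp, params.tip
    u = (tp - t) / tip
    g = np.zeros((t.size, 4))
    pre = t < tp - tip
    cub = (~pre) & (t <= tp)
    lin = t > tp
    # cubic branch: y = p (1 - 3u^2 + 2u^3); dy/du = 6 p u (u - 1)
    uc = u[cub]
    g[cub, 0] = 1 - 3 * uc**2 + 2 * uc**3
    g[cub, 2] = 6 * p * uc * (uc - 1) / tip
    g[cub, 3] = -6 * p * uc**2 * (uc - 1) / tip
    g[lin, 0] = 1.0
    g[lin, 1] = -(t[lin] - tp)
    g[lin, 2] = s
    # clamped region contributes zero gradient (subgradient at the clamp)
    y = eval_segpoly(t, params)
    g[np.asarray(y) <= 0.0] = 0.0
    return g


def eval_yang(t, params: YangParams):
    """Yang model laying rate a*e^(-x t) / (1 + e^(-c (t - d))) at age(s) ``t``."""
    t = np.asarray(t, dtype=float)
    a, c, x, d = params.a, params.c, params.x, params.d
    return a * np.exp(-x * t) * expit(c * (t - d))


def grad_yang(t, params: YangParams):
    """Gradient of eval_yang w.r.t. (a, c, x, d); shape (len(t), 4)."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    a, c, x, d = params.a, params.c, params.x, params.d
    sig = expit(c * (t - d))
    core = np.exp(-x * t) * sig
    y = a * core
    one_minus = expit(-c * (t - d))
    g = np.empty((t.size, 4))
    g[:, 0] = core
    g[:, 1] = y * (t - d) * one_minus
    g[:, 2] = -t * y
    g[:, 3] = -y * c * one_minus
    return g


def eval_persistency(t, params: PersistencyParams):
    """Persistency model laying rate at age(s) ``t`` (weeks).

    (yp/(t2-t1)) * [S(t,t1) - S(t,t2)] + b4 * S(t, t2+P), with S the smoothed
    ramp: a smoothed trapezoid rising between t1 and t2 to the plateau yp,
    constant for P weeks, then declining at b4 per week.
    """
    t = np.asarray(t, dtype=float)
    yp, t1, t2, P, b4 = params.yp, params.t1, params.t2, params.P, params.b4
    return (yp / (t2 - t1)) * (smooth_ramp(t, t1) - smooth_ramp(t, t2)) + b4 * (
        smooth_ramp(t, t2 + P)
    )


def grad_persistency(t, params: PersistencyParams):
    """Gradient of eval_persistency w.r.t. (yp, t1, t2, P, b4); shape (len(t), 5)."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    yp, t1, t2, P, b4 = params.yp, params.t1, params.t2, params.P, params.b4
    w = t2 - t1
    s1, s2, s3 = smooth_ramp(t, t1), smooth_ramp(t, t2), smooth_ramp(t, t2 + P)
    d1, d2, d3 = _smooth_ramp_dk(t, t1), _smooth_ramp_dk(t, t2), _smooth_ramp_dk(t, t2 + P)
    g = np.empty((t.size, 5))
    g[:, 0] = (s1 - s2) / w
    g[:, 1] = yp * (s1 - s2) / w**2 + (yp / w) * d1
    g[:, 2] = -yp * (s1 - s2) / w**2 - (yp / w) * d2 + b4 * d3
    g[:, 3] = b4 * d3
    g[:, 4] = s3
    return g
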