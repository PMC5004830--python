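"""Nonlinear least-squares fitting of laying curves by Gauss-Newton.

The estimator mirrors the classical NLIN-style procedure: minimise the sum of
squared errors Σ (y_it - ŷ(t))² over hen-week rates by Gauss-Newton with step
halving, stopping when the relative SSE change falls below 1e-5.  Parameter
constraints (tip > 0, c > 0, t2 > t1, P >= 0, nonnegative peaks) are enforced
by projecting each trial step onto the feasible box; an estimate that ends on
a constraint boundary is flagged and its Wald standard error suppressed,
since Wald theory is invalid there.

Standard errors come from the residual-variance-scaled inverse of the
Gauss-Newton normal matrix, and 95% confidence intervals use the t quantile
at the residual degrees of freedom.

A hidden ``linear`` family (y = alpha + beta t) exists purely so that tests
can compare the nonlinear machinery against closed-form least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import curves
from .records import (
    DegenerateDataError,
    InsufficientDataError,
    WeeklyStats,
    aggregate_weekly,
)

_EPS_GAP = 1e-6  # minimal strict-inequality gap for projected constraints


@dataclass(frozen=True)
class Family:
    """A curve family: names, evaluator, gradient, projection and init."""

    name: str
    param_names: tuple[str, ...]
    evaluate: callable  # (t, theta) -> y
    gradient: callable  # (t, theta) -> (len(t), n_params)
    project: callable  # theta -> feasible theta
    boundary_mask: callable  # theta -> bool mask of active constraints
    initialize: callable  # (weeks, mean_rates) -> theta

    @property
    def n_params(self) -> int:
        return len(self.param_names)


# ---------------------------------------------------------------------------
# family definitions

def _segpoly_eval(t, th):
    return curves.eval_segpoly(t, curves.SegPolyParams(*th))


def _segpoly_grad(t, th):
    return curves.grad_segpoly(t, curves.SegPolyParams(*th))


def _segpoly_project(th):
    p, s, tp, tip = th
    return np.array([max(p, 0.0), s, tp, max(tip, _EPS_GAP)])


def _segpoly_boundary(th):
    return np.array([th[0] <= 0.0, False, False, th[3] <= _EPS_GAP])


def _yang_eval(t, th):
    return curves.eval_yang(t, curves.YangParams(*th))


def _yang_grad(t, th):
    return curves.grad_yang(t, curves.YangParams(*th))


def _yang_project(th):
    a, c, x, d = th
    return np.array([max(a, 0.0), max(c, _EPS_GAP), x, d])


def _yang_boundary(th):
    return np.array([th[0] <= 0.0, th[1] <= _EPS_GAP, False, False])


def _pers_eval(t, th):
    return curves.eval_persistency(t, curves.PersistencyParams(*th))


def _pers_grad(t, th):
    return curves.grad_persistency(t, curves.PersistencyParams(*th))


def _pers_project(th):
    yp, t1, t2, P, b4 = th
    yp = max(yp, 0.0)
    if t2 <= t1 + _EPS_GAP:
        t2 = t1 + _EPS_GAP
    return np.array([yp, t1, t2, max(P, 0.0), b4])


def _pers_boundary(th):
    return np.array(
        [th[0] <= 0.0, False, th[2] - th[1] <= _EPS_GAP, th[3] <= 0.0, False]
    )


def _linear_eval(t, th):
    return th[0] + th[1] * np.asarray(t, dtype=float)


def _linear_grad(t, th):
    t = np.atleast_1d(np.asarray(t, dtype=float))
    g = np.empty((t.size, 2))
    g[:, 0] = 1.0
    g[:, 1] = t
    return g


def _init_common(weeks, means):
    peak = float(np.max(means))
    if peak <= 0:
        raise DegenerateDataError("all weekly mean rates are zero")
    t_peak = float(weeks[int(np.argmax(means))])
    above = weeks[means > 0.05 * peak]
    onset = float(above[0]) if above.size else float(weeks[0])
    return peak, t_peak, onset


def _segpoly_init(weeks, means):
    peak, t_peak, onset = _init_common(weeks, means)
    tip = max(t_peak - onset, 1.0)
    return np.array([peak, 0.0, t_peak, tip])


def _yang_init(weeks, means):
    peak, t_peak, onset = _init_common(weeks, means)
    # d ~ age where the mean rate first crosses half the peak (logistic midpoint)
    half = peak / 2.0
    idx = np.nonzero(means >= half)[0]
    d = float(weeks[idx[0]]) if idx.size else (onset + t_peak) / 2.0
    return np.array([peak, 1.0, 0.0, d])


def _pers_init(weeks, means):
    peak, t_peak, onset = _init_common(weeks, means)
    t1 = min(onset, t_peak - 1.0)
    t2 = max(t_peak, t1 + 1.0)
    # plateau end must start inside the observed window: once t2 + P drifts
    # past the last week the gradient w.r.t. P vanishes and the fit stalls
    near_peak = weeks[means >= 0.9 * peak]
    plateau_end = float(near_peak[-1]) if near_peak.size else t2
    plateau_end = min(plateau_end, float(weeks[-1]) - 0.25 * (weeks[-1] - t2))
    # post-plateau decline from the late-window trend rather than flat zero
    late = weeks >= weeks[-1] - 10
    b4 = float(np.polyfit(weeks[late], means[late], 1)[0]) if late.sum() >= 3 else 0.0
    return np.array([peak, t1, t2, max(plateau_end - t2, 0.0), min(b4, 0.0)])


def _linear_init(weeks, means):
    beta, alpha = np.polyfit(weeks, means, 1)
    return np.array([alpha, beta])


FAMILIES: dict[str, Family] = {
    "segpoly": Family(
        "segpoly", ("p", "s", "tp", "tip"),
        _segpoly_eval, _segpoly_grad, _segpoly_project, _segpoly_boundary,
        _segpoly_init,
    ),
    "yang": Family(
        "yang", ("a", "c", "x", "d"),
        _yang_eval, _yang_grad, _yang_project, _yang_boundary, _yang_init,
    ),
    "persistency": Family(
        "persistency", ("yp", "t1", "t2", "P", "b4"),
        _pers_eval, _pers_grad, _pers_project, _pers_boundary, _pers_init,
    ),
    "linear": Family(
        "linear", ("alpha", "beta"),
        _linear_eval, _linear_grad, lambda th: np.asarray(th, dtype=float),
        lambda th: np.array([False, False]), _linear_init,
    ),
}


def get_family(name) -> Family:
    if isinstance(name, Family):
        return name
    try:
        return FAMILIES[name]
    except KeyError:
        raise ValueError(
            f"unknown model family {name!r}; choose from {sorted(FAMILIES)}"
        ) from None


@dataclass
class FitOptions:
    """Tuning knobs of the Gauss-Newton loop."""

    tol: float = 1e-5  # relative SSE change declaring convergence
    max_iter: int = 200
    max_halvings: int = 30


@dataclass
class ModelFit:
    """A fitted laying curve with uncertainty and convergence diagnostics."""

    family: str
    param_names: tuple[str, ...]
    theta: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    sse: float
    df: int
    n_records: int
    converged: bool
    n_iter: int
    boundary: np.ndarray
    trace: list = field(default_factory=list)
    message: str = ""

    @property
    def estimates(self) -> dict[str, float]:
        return dict(zip(self.param_names, map(float, self.theta)))

    @property
    def ci95(self) -> dict[str, tuple[float, float]]:
        tq = stats.t.ppf(0.975, self.df)
        out = {}
        for i, name in enumerate(self.param_names):
            if np.isnan(self.se[i]):
                out[name] = (np.nan, np.nan)
            else:
                out[name] = (
                    float(self.theta[i] - tq * self.se[i]),
                    float(self.theta[i] + tq * self.se[i]),
                )
        return out

    def predict(self, t):
        return get_family(self.family).evaluate(t, self.theta)

    def summary(self) -> pd.DataFrame:
        ci = self.ci95
        return pd.DataFrame(
            {
                "estimate": self.theta,
                "se": self.se,
                "ci95_low": [ci[n][0] for n in self.param_names],
                "ci95_high": [ci[n][1] for n in self.param_names],
                "boundary": self.boundary,
            },
            index=list(self.param_names),
        )


def initialize_parameters(records: pd.DataFrame, family) -> np.ndarray:
    """Data-driven starting values for a curve family.

    Peak initialised at the maximum weekly mean rate, timing parameters from
    the argmax week and the first week exceeding 5% of the peak, decline
    rates at zero.
    """
    fam = get_family(family)
    ws = aggregate_weekly(records)
    if ws.weeks.size < 2:
        raise DegenerateDataError("need at least 2 distinct weeks to initialise")
    theta = fam.initialize(ws.weeks, ws.mean)
    return fam.project(theta)


def gauss_newton(stats_blocks, predict, normal_terms, project, theta0,
                 options: FitOptions | None = None):
    """Generic projected Gauss-Newton with step halving on aggregated data.

    ``stats_blocks``: list of WeeklyStats; ``predict(theta)`` -> list of ŷ
    arrays (one per block); ``normal_terms(theta)`` -> (A, b) of the normal
    equations at theta; ``project`` maps a trial vector into the feasible
    set.  Returns (theta, sse, converged, n_iter, trace, message).
    """
    opts = options or FitOptions()

    def total_sse(th):
        return sum(b.sse(y) for b, y in zip(stats_blocks, predict(th)))

    theta = project(np.asarray(theta0, dtype=float))
    sse = total_sse(theta)
    trace = [sse]
    message = ""
    converged = False
    it = 0
    for it in range(1, opts.max_iter + 1):
        A, bvec = normal_terms(theta)
        try:
            step = np.linalg.solve(A, bvec)
        except np.linalg.LinAlgError:
            step, *_ = np.linalg.lstsq(A, bvec, rcond=None)
            message = "singular normal matrix; least-squares step used"
        if not np.all(np.isfinite(step)):
            message = "non-finite Gauss-Newton step"
            break
        lam = 1.0
        new_theta, new_sse = theta, sse
        accepted = False
        for _ in range(opts.max_halvings):
            cand = project(theta + lam * step)
            cand_sse = total_sse(cand)
            if cand_sse <= sse:
                new_theta, new_sse, accepted = cand, cand_sse, True
                break
            lam *= 0.5
        if not accepted:
            converged = True  # no descent direction left: stationary
            break
        rel = (sse - new_sse) / (new_sse + 1e-12)
        theta, sse = new_theta, new_sse
        trace.append(sse)
        if rel < opts.tol:
            converged = True
            break
    return theta, sse, converged, it, trace, message


def _single_normal_terms(fam: Family, ws: WeeklyStats):
    def terms(theta):
        g = fam.gradient(ws.weeks, theta)
        yhat = np.asarray(fam.evaluate(ws.weeks, theta))
        A = g.T @ (g * ws.n[:, None])
        b = g.T @ (ws.total - ws.n * yhat)
        return A, b

    return terms


def _covariance(fam: Family, ws: WeeklyStats, theta, sse, df):
    """Residual-variance-scaled inverse normal matrix; NaN on failure."""
    g = fam.gradient(ws.weeks, theta)
    A = g.T @ (g * ws.n[:, None])
    p = fam.n_params
    try:
        A_inv = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        return np.full((p, p), np.nan)
    return (sse / df) * A_inv


def fit_model(records: pd.DataFrame, family, init=None,
              options: FitOptions | None = None) -> ModelFit:
    """Fit one curve family to hen-week egg records by least squares.

    Parameters
    ----------
    records : DataFrame with hen_id/group/week/eggs (and optionally rate).
    family : 'segpoly' | 'yang' | 'persistency' (or 'linear' for testing).
    init : optional starting vector; defaults to `initialize_parameters`.
    options : Gauss-Newton tolerances.

    Returns a :class:`ModelFit`; parameters that finish on a constraint
    boundary have their standard error and CI reported as NaN.
    """
    fam = get_family(family)
    ws = aggregate_weekly(records)
    n = ws.n_records
    if n <= fam.n_params:
        raise InsufficientDataError(
            f"{n} records cannot identify {fam.n_params} parameters"
        )
    theta0 = np.asarray(init, dtype=float) if init is not None else initialize_parameters(records, fam)

    def run(start):
        return gauss_newton(
            [ws],
            lambda th: [fam.evaluate(ws.weeks, th)],
            _single_normal_terms(fam, ws),
            fam.project,
            start,
            options,
        )

    theta, sse, converged, n_iter, trace, message = run(theta0)
    if fam.name == "persistency" and theta[2] + theta[3] > ws.weeks[-1]:
        # plateau end past the data window: P's gradient vanishes there, so
        # the fit may have stalled; restart with the plateau end pulled back
        retry0 = theta.copy()
        retry0[3] = max(0.5 * (ws.weeks[-1] - theta[2]), 1.0)
        retry = run(retry0)
        if retry[1] < sse:
            theta, sse, converged, n_iter, trace, message = retry

    df = n - fam.n_params
    boundary = fam.boundary_mask(theta)
    cov = _covariance(fam, ws, theta, sse, df)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    se[boundary] = np.nan
    if np.any(~np.isfinite(np.diag(cov))) and not message:
        message = "covariance unavailable (singular normal matrix)"
        converged = converged and False
    return ModelFit(
        family=fam.name,
        param_names=fam.param_names,
        theta=theta,
        se=se,
        cov=cov,
        sse=sse,
        df=df,
        n_records=n,
        converged=converged,
        n_iter=n_iter,
        boundary=boundary,
        trace=trace,
        message=message,
    )
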