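"""Gauss-Newton least squares: initialisation, recovery, oracles, invariants."""

import numpy as np
import pandas as pd
import pytest

from laycurve import (
    FitOptions,
    SimulationConfig,
    fit_model,
    initialize_parameters,
    simulate_egg_records,
)
from laycurve.datasets import CURVE_ESTIMATES
from laycurve.records import DegenerateDataError, InsufficientDataError

NC_SEGPOLY = CURVE_ESTIMATES["NC"]["segpoly"]
NC_YANG = CURVE_ESTIMATES["NC"]["yang"]
NC_PERSISTENCY = CURVE_ESTIMATES["NC"]["persistency"]


def _noise_free(family, truth, n_hens=10, seed=0):
    cfg = SimulationConfig(family=family, group_params={"g": truth},
                           n_hens={"g": n_hens}, noise="gaussian",
                           gaussian_sd=0.0, seed=seed)
    return simulate_egg_records(cfg)


class TestInitialization:
    def test_maturity_age_heuristic_near_truth(self):
        records = _noise_free("yang", NC_YANG)
        theta0 = initialize_parameters(records, "yang")
        d0 = theta0[3]
        assert abs(d0 - NC_YANG["d"]) <= 3.0

    def test_constant_rate_peak(self):
        records = pd.DataFrame(
            {"hen_id": "h0", "group": "g", "week": range(17, 37), "eggs": 7}
        )
        theta0 = initialize_parameters(records, "yang")
        assert theta0[0] == pytest.approx(1.0)

    def test_empty_table_raises(self):
        empty = pd.DataFrame(columns=["hen_id", "group", "week", "eggs"])
        with pytest.raises(DegenerateDataError):
            initialize_parameters(empty, "yang")

    def test_all_zero_records_raise(self):
        records = pd.DataFrame(
            {"hen_id": "h0", "group": "g", "week": range(17, 37), "eggs": 0}
        )
        with pytest.raises(DegenerateDataError):
            initialize_parameters(records, "yang")


@pytest.mark.parametrize(
    "family, truth",
    [("segpoly", NC_SEGPOLY), ("yang", NC_YANG), ("persistency", NC_PERSISTENCY)],
)
def test_noise_free_recovery(family, truth):
    """All families recover exact generating parameters from clean tabulations."""
    records = _noise_free(family, truth)
    fit = fit_model(records, family)
    assert fit.converged
    assert fit.sse < 1e-8
    for name, value in truth.items():
        assert fit.estimates[name] == pytest.approx(value, abs=1e-3)


def test_linear_family_matches_closed_form_ols():
    """The hidden linear family reproduces the normal-equations OLS solution."""
    t = np.array([17, 20, 25, 30, 40], dtype=float)
    y = np.array([0.21, 0.35, 0.52, 0.60, 0.55])
    records = pd.DataFrame(
        {"hen_id": [f"h{i}" for i in range(5)], "group": "g", "week": t,
         "eggs": y * 7, "rate": y}
    )
    fit = fit_model(records, "linear")
    X = np.column_stack([np.ones_like(t), t])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    assert fit.theta == pytest.approx(beta, abs=1e-10)
    assert fit.sse == pytest.approx(float(np.sum((y - X @ beta) ** 2)), abs=1e-10)


def test_matches_independent_optimizer(binomial_yang_records):
    """On noisy data the Gauss-Newton SSE matches scipy's trust-region NLS."""
    from scipy.optimize import least_squares

    from laycurve.curves import YangParams, eval_yang

    fit = fit_model(binomial_yang_records, "yang")
    t = binomial_yang_records["week"].to_numpy(dtype=float)
    y = binomial_yang_records["rate"].to_numpy(dtype=float)

    def resid(th):
        return eval_yang(t, YangParams(*th)) - y

    ref = least_squares(resid, x0=[0.9, 1.0, 0.0, 20.0], method="trf")
    assert fit.sse == pytest.approx(2 * ref.cost, rel=1e-6)
    assert fit.theta == pytest.approx(ref.x, rel=1e-3)


def test_sse_descends_across_iterations(binomial_yang_records):
    fit = fit_model(binomial_yang_records, "yang")
    assert all(b <= a + 1e-12 for a, b in zip(fit.trace, fit.trace[1:]))


def test_invariant_to_row_order_and_hen_labels(binomial_yang_records):
    shuffled = binomial_yang_records.sample(frac=1.0, random_state=5).reset_index(drop=True)
    relabeled = shuffled.assign(hen_id=np.arange(len(shuffled)).astype(str))
    f1 = fit_model(binomial_yang_records, "yang")
    f2 = fit_model(relabeled, "yang")
    assert f1.theta == pytest.approx(f2.theta, abs=1e-12)
    assert f1.sse == pytest.approx(f2.sse, abs=1e-12)


def test_warm_restart_converges_immediately(binomial_yang_records):
    first = fit_model(binomial_yang_records, "yang")
    again = fit_model(binomial_yang_records, "yang", init=first.theta)
    assert again.converged
    assert again.n_iter <= 2
    assert again.sse == pytest.approx(first.sse, rel=1e-8)


def test_ci_contains_estimate_and_cov_symmetric(binomial_yang_records):
    fit = fit_model(binomial_yang_records, "yang")
    for i, name in enumerate(fit.param_names):
        lo, hi = fit.ci95[name]
        assert lo < fit.theta[i] < hi
    assert np.allclose(fit.cov, fit.cov.T)
    assert np.all(np.linalg.eigvalsh(fit.cov) > -1e-12)


def test_boundary_estimate_suppresses_se():
    """A plateau fitted at the P = 0 boundary is flagged, CI suppressed."""
    truth = {"yp": 0.6, "t1": 20.0, "t2": 24.0, "P": 0.0, "b4": -0.01}
    cfg = SimulationConfig(family="persistency", group_params={"g": truth},
                           n_hens={"g": 50}, seed=11)
    fit = fit_model(simulate_egg_records(cfg), "persistency")
    if fit.estimates["P"] <= 1e-8:  # boundary reached for this draw
        i = fit.param_names.index("P")
        assert fit.boundary[i]
        assert np.isnan(fit.se[i])


def test_insufficient_records_raise():
    records = pd.DataFrame(
        {"hen_id": ["a", "b", "c"], "group": "g", "week": [17, 18, 19],
         "eggs": [1, 2, 3]}
    )
    with pytest.raises(InsufficientDataError):
        fit_model(records, "yang")


def test_unknown_family_rejected(binomial_yang_records):
    with pytest.raises(ValueError, match="unknown model family"):
        fit_model(binomial_yang_records, "wood")
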