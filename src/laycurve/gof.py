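"""Goodness-of-fit statistics for fitted laying curves.

Four statistics summarise how well a fitted curve tracks hen-week records:

* AIC = n ln(SSE/n) + 2k — relative model quality (n records, k parameters);
* MSE = SSE / (n - p) — residual variance on the rate² scale;
* R²  = 1 - SSE / SS_total, SS_total centered about the grand mean rate;
* MME = (1/m) Σ_t (ŷ̄_t - ȳ_t)/ȳ_t — mean relative deviation of the
  predicted from the observed weekly mean rate; positive means the model
  overestimates production overall, negative that it underestimates.

Weeks with zero observed mean rate are excluded from MME (the ratio is
undefined there) and the number of weeks actually used is reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nls_fit import ModelFit, get_family
from .records import aggregate_weekly


class UndefinedStatisticError(ValueError):
    """Raised when a statistic's denominator is empty or zero."""


@dataclass(frozen=True)
class GofReport:
    aic: float
    mse: float
    r2: float
    mme: float
    m_used: int

    def as_dict(self) -> dict:
        return {
            "aic": self.aic,
            "mse": self.mse,
            "r2": self.r2,
            "mme": self.mme,
            "m_used": self.m_used,
        }


def aic_from_sse(sse: float, n: int, k: int) -> float:
    """n ln(SSE/n) + 2k; -inf sentinel when the fit is exact (SSE = 0)."""
    if n <= 0:
        raise UndefinedStatisticError("AIC needs n > 0 records")
    if sse < 0:
        raise ValueError("SSE must be nonnegative")
    if sse == 0.0:
        return -np.inf
    return float(n * np.log(sse / n) + 2 * k)


def fit_statistics(fit: ModelFit, records: pd.DataFrame,
                   centered_sst: bool = True) -> dict:
    """AIC, MSE and R² of a fit against the records it was estimated from.

    ``centered_sst=False`` switches R² to the uncentered total sum of squares.
    """
    ws = aggregate_weekly(records)
    n = ws.n_records
    k = len(fit.param_names)
    if n <= k:
        raise UndefinedStatisticError(
            f"n={n} records with p={k} parameters leaves no residual df"
        )
    sse = fit.sse
    aic = aic_from_sse(sse, n, k)
    mse = sse / (n - k)
    sst = ws.ss_total_centered if centered_sst else float(ws.sumsq.sum())
    if sst <= 0:
        raise UndefinedStatisticError("total sum of squares is zero")
    r2 = 1.0 - sse / sst
    return {"aic": aic, "mse": mse, "r2": r2}


def mean_model_error(fit: ModelFit, records: pd.DataFrame) -> tuple[float, int]:
    """Signed mean relative error of weekly mean predictions.

    Returns (MME, m_used) where m_used counts the recording weeks with a
    nonzero observed mean rate.
    """
    ws = aggregate_weekly(records)
    fam = get_family(fit.family)
    yhat = np.asarray(fam.evaluate(ws.weeks, fit.theta), dtype=float)
    ybar = ws.mean
    keep = ybar > 0
    m_used = int(keep.sum())
    if m_used == 0:
        raise UndefinedStatisticError("all weekly mean rates are zero")
    mme = float(np.mean((yhat[keep] - ybar[keep]) / ybar[keep]))
    return mme, m_used


def gof_report(fit: ModelFit, records: pd.DataFrame,
               centered_sst: bool = True) -> GofReport:
    """Full goodness-of-fit report (AIC, MSE, R², MME)."""
    core = fit_statistics(fit, records, centered_sst=centered_sst)
    mme, m_used = mean_model_error(fit, records)
    return GofReport(aic=core["aic"], mse=core["mse"], r2=core["r2"],
                     mme=mme, m_used=m_used)
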