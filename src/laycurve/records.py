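"""Hen-week egg-record tables.

The canonical in-memory container is a pandas DataFrame with columns
``hen_id`` (opaque id), ``group`` (label), ``week`` (integer weeks of age),
``eggs`` (weekly egg count, 0-7) and ``rate`` (eggs/7, dimensionless).  One
row is one hen-week; the grid may be incomplete (hens can miss weeks).

Because every hen of a group shares the same predicted rate at a given week,
least-squares fitting only needs the per-(group, week) sufficient statistics
(count, sum of rates, sum of squared rates); :func:`aggregate_weekly`
computes them exactly once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("hen_id", "group", "week", "eggs")

DEFAULT_WEEK_WINDOW = (17, 50)
"""Default recording window, weeks of age, inclusive."""


class DegenerateDataError(ValueError):
    """Raised when records carry no usable signal (empty, all-zero, one week)."""


class InsufficientDataError(ValueError):
    """Raised when there are not enough records to estimate the parameters."""


def make_egg_records(hen_id, group, week, eggs) -> pd.DataFrame:
    """Assemble a validated egg-record table; ``rate`` is derived as eggs/7."""
    df = pd.DataFrame(
        {
            "hen_id": np.asarray(hen_id),
            "group": np.asarray(group),
            "week": np.asarray(week, dtype=int),
            "eggs": np.asarray(eggs),
        }
    )
    df["rate"] = df["eggs"] / 7.0
    return df


def validate_egg_records(df: pd.DataFrame) -> pd.DataFrame:
    """Check schema and value ranges; returns the table with ``rate`` ensured."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise KeyError(f"egg-record table missing required column(s): {missing}")
    if len(df) == 0:
        raise DegenerateDataError("egg-record table is empty")
    eggs = np.asarray(df["eggs"], dtype=float)
    if np.any(eggs < 0) or np.any(eggs > 7):
        bad = int(np.sum((eggs < 0) | (eggs > 7)))
        raise ValueError(f"{bad} row(s) have eggs outside [0, 7]")
    out = df.copy()
    out["rate"] = out["eggs"] / 7.0
    return out


class WeeklyStats:
    """Per-week sufficient statistics of observed rates.

    Attributes: ``weeks`` (sorted unique weeks), ``n`` (records per week),
    ``total`` (sum of rates), ``sumsq`` (sum of squared rates).  ``sse(yhat)``
    is the exact sum of squared errors of any prediction constant within a
    week, Σ_t [ sumsq_t - 2 ŷ_t total_t + n_t ŷ_t² ].
    """

    def __init__(self, weeks, n, total, sumsq):
        self.weeks = np.asarray(weeks, dtype=float)
        self.n = np.asarray(n, dtype=float)
        self.total = np.asarray(total, dtype=float)
        self.sumsq = np.asarray(sumsq, dtype=float)

    @property
    def n_records(self) -> int:
        return int(self.n.sum())

    @property
    def mean(self):
        return self.total / self.n

    @property
    def grand_mean(self) -> float:
        return float(self.total.sum() / self.n.sum())

    @property
    def ss_total_centered(self) -> float:
        gm = self.grand_mean
        return float(self.sumsq.sum() - 2 * gm * self.total.sum() + gm**2 * self.n.sum())

    def sse(self, yhat) -> float:
        yhat = np.asarray(yhat, dtype=float)
        sse = float(np.sum(self.sumsq - 2 * yhat * self.total + self.n * yhat**2))
        return max(sse, 0.0)  # guard floating cancellation on near-exact fits


def aggregate_weekly(records: pd.DataFrame, group: str | None = None) -> WeeklyStats:
    """Reduce hen-week rows to per-week sufficient statistics.

    If ``group`` is given, restrict to that group's rows first.
    """
    df = records if group is None else records[records["group"] == group]
    if len(df) == 0:
        raise DegenerateDataError(
            "no records" + (f" for group {group!r}" if group is not None else "")
        )
    rate = df["eggs"] / 7.0 if "rate" not in df.columns else df["rate"]
    tmp = pd.DataFrame({"week": df["week"].to_numpy(), "rate": rate.to_numpy()})
    agg = tmp.groupby("week")["rate"].agg(["count", "sum", lambda v: float(np.sum(v**2))])
    agg.columns = ["n", "total", "sumsq"]
    agg = agg.sort_index()
    return WeeklyStats(agg.index.to_numpy(), agg["n"], agg["total"], agg["sumsq"])
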