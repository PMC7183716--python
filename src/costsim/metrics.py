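"""Prediction-accuracy metrics for episode costs.

Three statistics: root-mean-squared error and mean absolute prediction
error, both in dollars, and cost accuracy (CA) — the percentage of the
dollars actually spent on truly high-cost episodes that is captured by the
episodes the model *flags* as high cost.  An episode is high cost when its
cost strictly exceeds the 90th percentile of the observed costs of the
dataset being evaluated.  CA below 100 means underprediction of high-cost
spending, above 100 overprediction.

Note: MAPE here is the mean absolute error in dollars, not a percentage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MetricSet",
    "rmse",
    "mape",
    "cost_accuracy",
    "evaluate",
    "stratified_errors",
    "STRATA_BOUNDS",
]

#: Percentile-rank bin edges for the stratified error table; bins are closed
#: on the left, the last bin closed on both ends.
STRATA_BOUNDS = (0, 20, 40, 60, 80, 90, 100)


def _validate(y, yhat):
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.size == 0:
        raise ValueError("empty input")
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    return y, yhat


def rmse(y, yhat) -> float:
    """Root-mean-squared prediction error, in dollars."""
    y, yhat = _validate(y, yhat)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def mape(y, yhat) -> float:
    """Mean absolute prediction error, in dollars."""
    y, yhat = _validate(y, yhat)
    return float(np.mean(np.abs(yhat - y)))


def cost_accuracy(y, yhat, threshold_percentile: float = 90, threshold: float | None = None) -> float:
    """Cost accuracy (percent).

    ``threshold`` defaults to the ``threshold_percentile`` of the *observed*
    costs ``y`` (linear-interpolation percentile).  The true high-cost set is
    {i: y_i > t}; the predicted set is {i: yhat_i > t}.  CA = 100 x (actual
    dollars of the predicted set) / (actual dollars of the true set).
    """
    y, yhat = _validate(y, yhat)
    t = float(np.percentile(y, threshold_percentile)) if threshold is None else float(threshold)
    true_total = y[y > t].sum()
    if true_total <= 0:
        raise ValueError("no observed cost above the high-cost threshold; CA is undefined")
    return float(100.0 * y[yhat > t].sum() / true_total)


@dataclass(frozen=True)
class MetricSet:
    """RMSE and MAPE in dollars, CA in percent, for one (model, dataset) pair."""

    rmse: float
    mape: float
    ca: float


def evaluate(y, yhat, threshold: float | None = None) -> MetricSet:
    return MetricSet(
        rmse=rmse(y, yhat),
        mape=mape(y, yhat),
        ca=cost_accuracy(y, yhat, threshold=threshold),
    )


def stratified_errors(y, yhat) -> pd.DataFrame:
    """Per-bin RMSE and MAPE with episodes binned by observed-cost rank.

    Episode i falls in bin [a, b) when 100 * rank_i / n lies in [a, b), with
    0-based ranks from a stable sort of the observed costs; the bins are the
    0-20/20-40/40-60/60-80/80-90/90-100 percentile strata.  Empty bins are
    reported with NaN errors rather than raised.
    """
    y, yhat = _validate(y, yhat)
    n = y.size
    if n < 10:
        raise ValueError("stratified errors require at least 10 episodes")
    order = np.argsort(y, kind="stable")
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(n)
    pct = 100.0 * rank / n
    rows = []
    for lo, hi in zip(STRATA_BOUNDS[:-1], STRATA_BOUNDS[1:]):
        mask = (pct >= lo) & ((pct < hi) if hi < 100 else (pct <= hi))
        label = f"{lo}-{hi}"
        if mask.any():
            rows.append(
                {"stratum": label, "n": int(mask.sum()),
                 "rmse": rmse(y[mask], yhat[mask]), "mape": mape(y[mask], yhat[mask])}
            )
        else:
            rows.append({"stratum": label, "n": 0, "rmse": np.nan, "mape": np.nan})
    return pd.DataFrame(rows).set_index("stratum")
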