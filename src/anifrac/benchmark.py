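"""Accuracy scoring of ANI/AF estimates against simulation truth.

RMSE plus ordinary-least-squares regression of estimate on truth with
percentile bootstrap confidence intervals (1,000 resamples by default),
and binned RMSE summaries over evolutionary distance or coverage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["RegressionSummary", "rmse", "bootstrap_regression", "rmse_by_bin"]


@dataclass(frozen=True)
class RegressionSummary:
    """Median and 95% percentile interval of bootstrap OLS coefficients."""

    r2: float
    intercept: float
    slope: float
    ci95_r2: tuple[float, float]
    ci95_intercept: tuple[float, float]
    ci95_slope: tuple[float, float]
    n_boot: int


def rmse(pred: Sequence[float], truth: Sequence[float]) -> float:
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {truth.shape}")
    if pred.size == 0:
        raise ValueError("empty input")
    return float(np.sqrt(np.mean((pred - truth) ** 2)))


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(intercept), float(slope), r2


def bootstrap_regression(
    x: Sequence[float],
    y: Sequence[float],
    n_boot: int = 1000,
    seed: int = 0,
) -> RegressionSummary:
    """OLS of y on x over bootstrap resamples; median + 95% quantile range."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("x and y must have equal length >= 2")
    rng = np.random.default_rng(seed)
    stats = np.empty((n_boot, 3))
    n = x.size
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        while np.ptp(x[idx]) == 0:  # degenerate resample: no x spread
            idx = rng.integers(0, n, size=n)
        stats[b] = _ols(x[idx], y[idx])
    med = np.median(stats, axis=0)
    lo = np.quantile(stats, 0.025, axis=0)
    hi = np.quantile(stats, 0.975, axis=0)
    return RegressionSummary(
        intercept=float(med[0]),
        slope=float(med[1]),
        r2=float(med[2]),
        ci95_intercept=(float(lo[0]), float(hi[0])),
        ci95_slope=(float(lo[1]), float(hi[1])),
        ci95_r2=(float(lo[2]), float(hi[2])),
        n_boot=n_boot,
    )


def rmse_by_bin(
    table: pd.DataFrame,
    pred_col: str,
    truth_col: str,
    bin_var: str,
    edges: Sequence[float],
) -> pd.DataFrame:
    """RMSE of ``pred_col`` vs ``truth_col`` within bins of ``bin_var``.

    Bins with no pairs are omitted.  Returns columns
    (bin_left, bin_right, n, rmse).
    """
    edges = np.asarray(edges, dtype=float)
    rows = []
    for left, right in zip(edges[:-1], edges[1:]):
        # right-closed on the last bin so the grid maximum is included
        last = right == edges[-1]
        sel = (table[bin_var] >= left) & (
            (table[bin_var] <= right) if last else (table[bin_var] < right)
        )
        sub = table[sel]
        if sub.empty:
            continue
        rows.append(
            {
                "bin_left": float(left),
                "bin_right": float(right),
                "n": int(len(sub)),
                "rmse": rmse(sub[pred_col], sub[truth_col]),
            }
        )
    return pd.DataFrame(rows, columns=["bin_left", "bin_right", "n", "rmse"])
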