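"""Discrimination and calibration metrics for binary risk predictions."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata


def c_statistic(
    scores_cases,
    scores_controls,
    ci: str = "delong",
    alpha: float = 0.05,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Concordance probability (AUROC) with a confidence interval.

    The point estimate is the fraction of (case, control) pairs in which the
    case's risk score exceeds the control's, ties counting one half —
    computed via midranks, which is exactly the pairwise definition.  The
    default CI uses the DeLong structural-component variance; ``ci="bootstrap"``
    resamples both groups.
    """
    x = np.asarray(scores_cases, dtype=float)
    y = np.asarray(scores_controls, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both score groups must be nonempty")
    m, n = x.size, y.size

    all_ranks = rankdata(np.concatenate([x, y]))
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2) / (m * n)

    if ci == "delong":
        # placements: V10[i] = P(score_control < x_i) + 0.5 P(= x_i)
        rx = rankdata(x)
        ry = rankdata(y)
        v10 = (all_ranks[:m] - rx) / n
        v01 = 1.0 - (all_ranks[m:] - ry) / m
        s10 = v10.var(ddof=1) if m > 1 else 0.0
        s01 = v01.var(ddof=1) if n > 1 else 0.0
        se = np.sqrt(s10 / m + s01 / n)
        zq = norm.ppf(1 - alpha / 2)
        lo, hi = auc - zq * se, auc + zq * se
    elif ci == "bootstrap":
        rng = np.random.default_rng(seed)
        reps = np.empty(n_boot)
        for b in range(n_boot):
            xb = x[rng.integers(0, m, m)]
            yb = y[rng.integers(0, n, n)]
            r = rankdata(np.concatenate([xb, yb]))
            reps[b] = (r[:m].sum() - m * (m + 1) / 2) / (m * n)
        lo, hi = np.quantile(reps, [alpha / 2, 1 - alpha / 2])
    else:
        raise ValueError(f"unknown ci method {ci!r}")
    return float(auc), (float(max(lo, 0.0)), float(min(hi, 1.0)))


def brier_score(predicted, outcomes) -> float:
    """Mean squared difference between predicted probability and outcome."""
    p = np.asarray(predicted, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if p.shape != y.shape:
        raise ValueError("predicted and outcomes must have equal length")
    if p.size == 0:
        raise ValueError("empty input")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("predicted probabilities must lie in [0,1]")
    return float(np.mean((p - y) ** 2))


def calibration_bins(predicted, outcomes, n_bins: int = 10) -> pd.DataFrame:
    """Decile-style calibration table.

    Rows are ranked by predicted risk (stable sort, so ties keep input
    order) and split into ``n_bins`` near-equal groups; each bin reports its
    size, mean predicted risk ("calibrated") and observed outcome rate
    ("uncalibrated").  With heavily tied predictions some bins may span a
    single predicted value; bins are never merged, so counts always sum to n.
    """
    p = np.asarray(predicted, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if p.shape != y.shape:
        raise ValueError("predicted and outcomes must have equal length")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if p.size < n_bins:
        raise ValueError("need at least n_bins observations")
    order = np.argsort(p, kind="stable")
    parts = np.array_split(order, n_bins)
    rows = [
        {
            "bin": i + 1,
            "n": len(idx),
            "mean_predicted": float(p[idx].mean()),
            "observed_rate": float(y[idx].mean()),
        }
        for i, idx in enumerate(parts)
    ]
    return pd.DataFrame(rows)
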