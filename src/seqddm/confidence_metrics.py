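"""Model-free confidence statistics and the scale-free spectral diagnostic.

Confidence ratings on the canonical 6-point scale (1 = certainly wrong ...
6 = certainly correct) are collapsed into three categories: ratings {5,6} are
*high confidence*, {3,4} *low confidence*, and {1,2} *perceived errors*.  The
model-free response-caution statistic multiplies a central RT (median by
default) with mean accuracy on the trials following each confidence category;
caution rises when decisions become both slower and more accurate, i.e. when
the decision bound widens.  The spectral-slope diagnostic quantifies slow
"scale-free" (1/f-like) fluctuations in behavioral time series as the slope
of a linear fit to the log-log periodogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy import stats as sp_stats

__all__ = [
    "CATEGORIES",
    "bin_confidence",
    "caution_statistic",
    "accuracy_by_confidence",
    "spectral_slope",
]

CATEGORIES = ("high", "low", "perceived_error")

_BIN_MAP = {
    1: "perceived_error",
    2: "perceived_error",
    3: "low",
    4: "low",
    5: "high",
    6: "high",
}


def bin_confidence(rating: int | np.ndarray) -> str | np.ndarray:
    """Collapse 6-point ratings into the 3-level confidence partition.

    {5, 6} -> "high", {3, 4} -> "low", {1, 2} -> "perceived_error".
    """
    arr = np.asarray(rating)
    if np.any((arr < 1) | (arr > 6)):
        raise ValueError("confidence ratings must lie in 1..6")
    if arr.ndim == 0:
        return _BIN_MAP[int(arr)]
    out = np.array([_BIN_MAP[int(r)] for r in arr.ravel()])
    return out.reshape(arr.shape)


def _lagged_category(trials: pd.DataFrame, lag: int) -> pd.Series:
    """Category of the trial ``lag`` positions earlier, within participant.

    ``lag`` may be negative (future trials).  Positions where the lagged trial
    belongs to another participant are NaN.
    """
    return trials.groupby("participant", sort=False)["confidence_category"].shift(lag)


def caution_statistic(
    trials: pd.DataFrame,
    lag: int = 1,
    rt_center: str = "median",
) -> pd.DataFrame:
    """Model-free response caution conditioned on a lagged confidence category.

    Groups each trial's outcome (RT, accuracy) by the confidence category
    ``lag`` trials earlier (default: the previous trial) and computes, per
    participant and category, the central RT, the mean accuracy and their
    product (caution); a companion conditioning on the trial *after* next
    (lag = -2 relative to the outcome trial, i.e. trial_n+2 confidence) is
    emitted alongside for the slow-drift control.

    Returns a tidy frame keyed by (participant, conditioning, category) with
    columns ``rt_center``, ``accuracy``, ``caution``, ``n_trials``, plus
    group-level rows (participant = -1) averaging over participants, and
    delta-vs-high-confidence columns.  Categories with no trials for a
    participant are recorded as missing (NaN), never imputed.
    """
    if rt_center not in ("median", "mean"):
        raise ValueError("rt_center must be 'median' or 'mean'")
    if "confidence_category" not in trials.columns:
        raise ValueError("trials must carry a confidence_category column")
    trials = trials.sort_values(["participant", "trial"]).reset_index(drop=True)
    center = np.median if rt_center == "median" else np.mean

    out_rows = []
    for cond_name, cond_lag in (("lag_n", lag), ("lag_n2", -lag)):
        prev = _lagged_category(trials, cond_lag)
        for pid, idx in trials.groupby("participant").groups.items():
            sub = trials.loc[idx]
            cat = prev.loc[idx]
            for c in CATEGORIES:
                sel = sub[cat == c]
                if len(sel) == 0:
                    rtc = acc = caution = np.nan
                else:
                    rtc = float(center(sel["rt"]))
                    acc = float(sel["accuracy"].mean())
                    caution = rtc * acc
                out_rows.append(
                    {
                        "participant": pid,
                        "conditioning": cond_name,
                        "category": c,
                        "rt_center": rtc,
                        "accuracy": acc,
                        "caution": caution,
                        "n_trials": len(sel),
                    }
                )
    res = pd.DataFrame(out_rows)

    # group-level: average per-participant summaries (participants with the
    # category missing drop out of that cell's average)
    grp = (
        res.groupby(["conditioning", "category"], sort=False)[
            ["rt_center", "accuracy", "caution"]
        ]
        .mean()
        .reset_index()
    )
    grp["participant"] = -1
    grp["n_trials"] = (
        res.groupby(["conditioning", "category"], sort=False)["n_trials"]
        .sum()
        .values
    )
    res = pd.concat([res, grp], ignore_index=True)

    # deltas vs the high-confidence reference within each (participant, conditioning)
    ref = res[res["category"] == "high"].set_index(["participant", "conditioning"])[
        "caution"
    ]
    key = list(zip(res["participant"], res["conditioning"]))
    res["delta_caution"] = res["caution"].values - ref.reindex(key).values
    return res


def accuracy_by_confidence(trials: pd.DataFrame) -> pd.DataFrame:
    """Accuracy per 6-point rating level, per participant and pooled.

    Pooled rows (participant = -1) average the per-participant accuracies and
    carry an exact binomial CI on the pooled trial counts together with a
    two-sided exact test against chance (0.5).  Rating levels with zero trials
    are reported as missing, not zero.
    """
    rows = []
    for pid, sub in trials.groupby("participant"):
        for r in range(1, 7):
            sel = sub[sub["confidence_rating"] == r]
            rows.append(
                {
                    "participant": pid,
                    "rating": r,
                    "accuracy": sel["accuracy"].mean() if len(sel) else np.nan,
                    "n_trials": len(sel),
                }
            )
    res = pd.DataFrame(rows)
    pooled = []
    for r in range(1, 7):
        sub = res[res["rating"] == r]
        n = int(sub["n_trials"].sum())
        k = int(
            trials.loc[
                (trials["confidence_rating"] == r) & (trials["accuracy"] == 1)
            ].shape[0]
        )
        if n == 0:
            pooled.append(
                {
                    "participant": -1,
                    "rating": r,
                    "accuracy": np.nan,
                    "n_trials": 0,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "p_vs_chance": np.nan,
                }
            )
            continue
        bt = sp_stats.binomtest(k, n, p=0.5)
        ci = bt.proportion_ci(confidence_level=0.95)
        pooled.append(
            {
                "participant": -1,
                "rating": r,
                "accuracy": float(sub["accuracy"].mean()),
                "n_trials": n,
                "ci_low": ci.low,
                "ci_high": ci.high,
                "p_vs_chance": bt.pvalue,
            }
        )
    return pd.concat([res, pd.DataFrame(pooled)], ignore_index=True)


def spectral_slope(
    series: np.ndarray,
    detrend: bool = True,
    n_log_bins: int = 20,
) -> float:
    """Slope of the linear fit to the log-log power spectrum of a series.

    Uses the raw periodogram (DC excluded), averages log-power within
    log-spaced frequency bins to equalize leverage across decades, and fits
    log power on log frequency by least squares.  White noise has slope ~0;
    1/f^b noise has slope ~-b.  The slope is invariant under positive scaling
    of the series (which only offsets log power).
    """
    x = np.asarray(series, dtype=float)
    if x.size < 64:
        raise ValueError("series must have at least 64 samples")
    if np.any(~np.isfinite(x)):
        raise ValueError("series contains missing values; drop or interpolate first")
    if np.ptp(x) == 0:
        raise ValueError("spectral slope undefined for a constant series")
    freqs, power = sp_signal.periodogram(
        x, detrend="linear" if detrend else False
    )
    keep = (freqs > 0) & (power > 0)
    lf, lp = np.log10(freqs[keep]), np.log10(power[keep])
    edges = np.linspace(lf.min(), lf.max() + 1e-12, n_log_bins + 1)
    which = np.digitize(lf, edges) - 1
    bf, bp = [], []
    for b in range(n_log_bins):
        sel = which == b
        if sel.any():
            bf.append(lf[sel].mean())
            bp.append(lp[sel].mean())
    slope, _ = np.polyfit(bf, bp, 1)
    return float(slope)
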