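"""Single-trial EEG (ERN / Pe) covariates for the regression DDM.

The error-related negativity (ERN, fronto-central, around the response) and
the error positivity (Pe, centro-parietal, 250-350 ms post-response) are the
two established electrophysiological markers of error/confidence processing.
This module extracts single-trial window amplitudes from response-locked
epochs (zero-phase 10 Hz low-pass, then the window mean), builds robust
per-participant rank predictors, removes the ERN's shared variance from the
Pe by per-participant regression, divides the residual Pe into equal-count
amplitude quantile bins (lowest bin = regression reference), and assembles
the Pe/ERN-coded design matrices consumed by the hierarchical fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from seqddm.hierarchical_fit import DesignMatrix

__all__ = [
    "EpochWindowSpec",
    "window_mean",
    "rank_transform",
    "residualize_pe",
    "pe_quantile_bins",
    "prepare_eeg_predictors",
    "eeg_regression_design",
]


@dataclass(frozen=True)
class EpochWindowSpec:
    """Component extraction window (ms relative to the response).

    Defaults follow the standard definitions: ERN at FCz over [-10, 90] ms,
    Pe at Pz over [250, 350] ms, both after a 10 Hz low-pass.
    """

    component: str  # "ERN" or "Pe"
    electrode: str
    window_ms: tuple[float, float]
    lowpass_hz: float | None = 10.0

    def __post_init__(self) -> None:
        if self.window_ms[0] >= self.window_ms[1]:
            raise ValueError("window start must precede window end")

    @staticmethod
    def ern(electrode: str = "FCz") -> "EpochWindowSpec":
        return EpochWindowSpec("ERN", electrode, (-10.0, 90.0))

    @staticmethod
    def pe(electrode: str = "Pz") -> "EpochWindowSpec":
        return EpochWindowSpec("Pe", electrode, (250.0, 350.0))


def window_mean(
    times_ms: np.ndarray, values_uv: np.ndarray, spec: EpochWindowSpec
) -> float:
    """Window-mean amplitude of one epoch (µV).

    Applies a zero-phase second-order Butterworth low-pass at
    ``spec.lowpass_hz`` (None disables filtering), then averages the samples
    whose timestamps fall inside the window, endpoints inclusive with
    nearest-sample snapping.
    """
    t = np.asarray(times_ms, dtype=float)
    x = np.asarray(values_uv, dtype=float)
    if t.ndim != 1 or t.shape != x.shape:
        raise ValueError("times and values must be matching 1-D arrays")
    lo, hi = spec.window_ms
    if lo < t[0] or hi > t[-1]:
        raise ValueError(
            f"window [{lo}, {hi}] ms lies outside the epoch [{t[0]}, {t[-1]}] ms"
        )
    if spec.lowpass_hz is not None:
        fs = 1000.0 / float(np.median(np.diff(t)))  # samples/s from ms spacing
        sos = sp_signal.butter(2, spec.lowpass_hz, btype="low", fs=fs, output="sos")
        x = sp_signal.sosfiltfilt(sos, x)
    # nearest-sample snapping of the endpoints, inclusive
    i0 = int(np.argmin(np.abs(t - lo)))
    i1 = int(np.argmin(np.abs(t - hi)))
    return float(x[i0 : i1 + 1].mean())


def rank_transform(amplitudes: np.ndarray) -> np.ndarray:
    """Ascending ranks 1..n (average ranks for ties), one participant's trials.

    Ranking is invariant under any strictly increasing transform of the
    amplitudes, which is what makes it robust to single-trial EEG noise
    scaling.
    """
    x = np.asarray(amplitudes, dtype=float)
    if x.size < 2:
        raise ValueError("rank transform needs at least 2 trials")
    return sp_stats.rankdata(x, method="average")


def residualize_pe(pe: np.ndarray, ern: np.ndarray) -> np.ndarray:
    """Residual Pe after regressing out the ERN (with intercept), per participant.

    With a zero-variance ERN the centered Pe is returned with a warning.
    """
    pe = np.asarray(pe, dtype=float)
    ern = np.asarray(ern, dtype=float)
    if pe.shape != ern.shape:
        raise ValueError("pe and ern must be paired trialwise")
    if np.ptp(ern) == 0:
        warnings.warn("zero-variance ERN; returning mean-centered Pe", stacklevel=2)
        return pe - pe.mean()
    slope, intercept = np.polyfit(ern, pe, 1)
    return pe - (intercept + slope * ern)


def pe_quantile_bins(residual_pe: np.ndarray, k: int = 5) -> np.ndarray:
    """Equal-count amplitude bins 1..k (1 = lowest amplitudes, the reference).

    Rank-based, so any monotone relabeling of the amplitudes leaves the
    assignment unchanged.  When n is not divisible by k the remainder trials
    go to the *lower* bins (n=12, k=5 gives sizes 3,3,2,2,2).  Ties are broken
    by stable sort order.
    """
    x = np.asarray(residual_pe, dtype=float)
    n = x.size
    if n < k:
        raise ValueError(f"need at least {k} trials for {k} bins, got {n}")
    base, rem = divmod(n, k)
    sizes = [base + 1 if b < rem else base for b in range(k)]
    order = np.argsort(x, kind="stable")
    bins = np.empty(n, dtype=int)
    pos = 0
    for b, s in enumerate(sizes, start=1):
        bins[order[pos : pos + s]] = b
        pos += s
    return bins


def prepare_eeg_predictors(
    trials: pd.DataFrame,
    residualize: bool = True,
    k_bins: int = 5,
) -> pd.DataFrame:
    """Add per-participant EEG predictor columns to a trial table.

    Adds ``pe_rank``, ``ern_rank`` (average ranks), ``pe_residual`` (ERN
    regressed out when ``residualize``), and ``pe_bin`` (equal-count quantile
    bins of the residual Pe, 1 = lowest amplitude).
    """
    for col in ("pe_amp", "ern_amp"):
        if col not in trials.columns:
            raise ValueError(f"trials table lacks {col!r}")
    df = trials.sort_values(["participant", "trial"]).reset_index(drop=True)
    out = []
    for _, sub in df.groupby("participant", sort=False):
        sub = sub.copy()
        pe = sub["pe_amp"].to_numpy(dtype=float)
        ern = sub["ern_amp"].to_numpy(dtype=float)
        ok = np.isfinite(pe) & np.isfinite(ern)  # missing amplitudes stay NaN
        rank_pe = np.full(pe.shape, np.nan)
        rank_ern = np.full(pe.shape, np.nan)
        res = np.full(pe.shape, np.nan)
        bins = np.full(pe.shape, np.nan)
        rank_pe[ok] = rank_transform(pe[ok])
        rank_ern[ok] = rank_transform(ern[ok])
        res[ok] = (
            residualize_pe(pe[ok], ern[ok]) if residualize else pe[ok] - pe[ok].mean()
        )
        bins[ok] = pe_quantile_bins(res[ok], k=k_bins)
        sub["pe_rank"] = rank_pe
        sub["ern_rank"] = rank_ern
        sub["pe_residual"] = res
        sub["pe_bin"] = bins
        out.append(sub)
    return pd.concat(out, ignore_index=True)


def eeg_regression_design(
    trials: pd.DataFrame,
    mode: str = "binned",
    k_bins: int = 5,
) -> DesignMatrix:
    """Design matrix with EEG predictors at lag n and lag n+2.

    ``mode="continuous"``: per-participant standardized rank covariates for
    the Pe and the ERN at both lags, on bound and drift.  ``mode="binned"``:
    indicators for residual-Pe bins 2..k at both lags (bin 1 = reference).
    Rows are outcome trials with both lags resolvable; the result feeds
    :func:`seqddm.hierarchical_fit.fit_hierarchical` unchanged.
    """
    if mode not in ("continuous", "binned"):
        raise ValueError("mode must be 'continuous' or 'binned'")
    n_missing = int(trials[["pe_amp", "ern_amp"]].isna().any(axis=1).sum())
    if n_missing > 0.10 * len(trials):
        warnings.warn(
            f"hard warning: EEG amplitudes missing on {n_missing}/{len(trials)} trials",
            stacklevel=2,
        )
    df = prepare_eeg_predictors(trials, k_bins=k_bins)

    def zscore_by_participant(col: str) -> pd.Series:
        g = df.groupby("participant", sort=False)[col]
        return (df[col] - g.transform("mean")) / g.transform("std")

    preds: dict[str, pd.Series] = {}
    if mode == "continuous":
        preds["perank"] = zscore_by_participant("pe_rank")
        preds["ernrank"] = zscore_by_participant("ern_rank")
    else:
        for b in range(2, k_bins + 1):
            preds[f"bin{b}"] = (df["pe_bin"] == b).astype(float)

    lag_tag = {1: "n", -1: "n2"}
    lagged = {}
    for lag in (1, -1):
        for name, series in preds.items():
            lagged[(name, lag)] = (
                pd.DataFrame({"participant": df["participant"], "x": series})
                .groupby("participant", sort=False)["x"]
                .shift(lag)
            )
    keep = np.ones(len(df), dtype=bool)
    for v in lagged.values():
        keep &= v.notna().to_numpy()
    if "censored" in df.columns:
        keep &= ~df["censored"].to_numpy(dtype=bool)

    sub = df[keep]
    parts, pidx = np.unique(sub["participant"].to_numpy(), return_inverse=True)
    a_cols, a_names = [np.ones(len(sub))], ["a0"]
    v_cols, v_names = [np.ones(len(sub))], ["v0"]
    for lag in (1, -1):
        for name in preds:
            col = lagged[(name, lag)][keep].to_numpy(dtype=float)
            a_cols.append(col)
            a_names.append(f"a_{name}_{lag_tag[lag]}")
            v_cols.append(col)
            v_names.append(f"v_{name}_{lag_tag[lag]}")
    return DesignMatrix(
        rt=sub["rt"].to_numpy(dtype=float),
        response=sub["accuracy"].to_numpy(dtype=np.int8),
        participant_idx=pidx.astype(np.int64),
        participants=parts,
        Xa=np.column_stack(a_cols),
        Xv=np.column_stack(v_cols),
        a_names=a_names,
        v_names=v_names,
        log={
            "n_input": len(df),
            "n_used": len(sub),
            "dropped_edge_or_censored": int(len(df) - len(sub)),
            "mode": mode,
        },
        used_index=np.flatnonzero(keep),
    )
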