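"""Trial-table I/O with validation.

The canonical trial table is delimited text (TSV by default), one row per
trial, with at least: ``participant``, ``trial`` (contiguous within
participant), ``rt`` (seconds), ``accuracy`` (0/1) and ``confidence_rating``
(1..6).  Optional columns: ``block``, ``coherence`` (or another evidence
strength measure), ``choice``, ``pe_amp``, ``ern_amp`` (µV), ``censored``,
``scale_reversed`` (per-participant flag for counterbalanced confidence
scales).  ``confidence_category`` is derived from the rating when absent.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from seqddm.confidence_metrics import bin_confidence

__all__ = ["TrialValidationError", "read_trials", "write_trials"]

REQUIRED_COLUMNS = ("participant", "trial", "rt", "accuracy", "confidence_rating")


class TrialValidationError(ValueError):
    """Structured validation failure; ``problems`` lists offending rows."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid trial table:\n  " + "\n  ".join(problems))


def read_trials(
    path: str | Path,
    sep: str = "\t",
    rt_unit: str = "s",
) -> pd.DataFrame:
    """Read and validate a canonical trial table.

    RTs are coerced to seconds (``rt_unit`` "s" or "ms").  When a
    ``scale_reversed`` column is present, ratings of flagged participants are
    remapped (1<->6, 2<->5, 3<->4) so that 6 always means "certainly correct".
    Raises :class:`TrialValidationError` naming the offending rows on missing
    mandatory columns, non-monotone trial indices, out-of-range ratings or
    nonpositive RTs.
    """
    df = pd.read_csv(path, sep=sep, comment="#")
    problems: list[str] = []
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TrialValidationError([f"missing mandatory column(s): {missing}"])
    if rt_unit == "ms":
        df["rt"] = df["rt"] / 1000.0
    elif rt_unit != "s":
        raise ValueError("rt_unit must be 's' or 'ms'")

    bad_rt = df.index[df["rt"] <= 0]
    for i in bad_rt[:20]:
        problems.append(f"row {i}: nonpositive rt {df.loc[i, 'rt']!r}")
    bad_rating = df.index[~df["confidence_rating"].isin(range(1, 7))]
    for i in bad_rating[:20]:
        problems.append(
            f"row {i}: confidence_rating {df.loc[i, 'confidence_rating']!r} not in 1..6"
        )
    for pid, sub in df.groupby("participant"):
        t = sub["trial"].to_numpy()
        if np.any(np.diff(t) <= 0):
            where = sub.index[1:][np.diff(t) <= 0]
            problems.append(
                f"participant {pid}: non-monotone trial indices at rows {list(where[:5])}"
            )
    if problems:
        raise TrialValidationError(problems)

    if "scale_reversed" in df.columns:
        flip = df["scale_reversed"].astype(bool)
        df.loc[flip, "confidence_rating"] = 7 - df.loc[flip, "confidence_rating"]
    if "confidence_category" not in df.columns:
        df["confidence_category"] = bin_confidence(
            df["confidence_rating"].to_numpy()
        )
    return df


def write_trials(trials: pd.DataFrame, path: str | Path, sep: str = "\t",
                 header_comment: str | None = None) -> None:
    """Write the canonical trial table (optionally with a # comment header)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        trials.to_csv(fh, sep=sep, index=False)
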