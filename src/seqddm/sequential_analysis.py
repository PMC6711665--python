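"""Sequential-effect procedures: slow-drift correction, matched trials, strata.

Slow "scale-free" fluctuations in behavioral state (arousal, attention) make
neighboring trials resemble each other, which can masquerade as a causal
effect of confidence on trial n upon the decision bound on trial n+1.  Two
bespoke controls address this:

* **drift correction** — confidence on trial n+2 cannot causally influence
  trial n+1, yet it carries the same slow-state information as trial n; the
  corrected effect is the drawwise difference between the lag-n and lag-n+2
  group posteriors from a *joint* fit (preserving posterior correlation);
* **matched trials** — target-category trials on trial n are compared to
  high-confidence trials on trial n whose trial n+2 falls in the target
  category, so both sets of trials stem from statistically similar periods.

Accuracy-stratified fits re-run the whole pipeline within trials whose
*predictor* trial (trial n) was objectively correct (or an error), showing
that the confidence effect is not mere post-error slowing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from seqddm.hierarchical_fit import (
    DesignMatrix,
    McmcSpec,
    PosteriorSet,
    RegressionSpec,
    build_design,
    fit_hierarchical,
    posterior_p,
)

__all__ = [
    "SequentialEffect",
    "drift_corrected_effect",
    "matched_trial_subset",
    "stratified_fit",
]


@dataclass
class SequentialEffect:
    """Raw and drift-corrected sequential effects per coefficient stem.

    ``effects[stem]`` holds aligned draw vectors ``raw_n``, ``raw_n2``,
    ``corrected`` (= raw_n - raw_n2, drawwise) and their two-sided posterior
    overlap p-values.  ``contrasts[(stem_a, stem_b)]`` holds drawwise
    between-stem differences of both the corrected and the raw lag-n draws
    (e.g. perceived-error vs low-confidence bound shift).
    """

    effects: dict
    contrasts: dict = field(default_factory=dict)

    def report(self) -> pd.DataFrame:
        """Tidy table: stem x {raw_n, raw_n2, corrected} x {mean, sd, p}."""
        rows = []
        for stem, e in self.effects.items():
            for which in ("raw_n", "raw_n2", "corrected"):
                d = e[which]
                rows.append(
                    {
                        "effect": stem,
                        "component": which,
                        "mean": float(np.mean(d)),
                        "sd": float(np.std(d)),
                        "p": e[f"p_{which}"],
                    }
                )
        for (sa, sb), c in self.contrasts.items():
            for which in ("corrected", "raw_n"):
                d = c[which]
                rows.append(
                    {
                        "effect": f"{sa} - {sb}",
                        "component": which,
                        "mean": float(np.mean(d)),
                        "sd": float(np.std(d)),
                        "p": c[f"p_{which}"],
                    }
                )
        return pd.DataFrame(rows)


def drift_corrected_effect(posterior: PosteriorSet) -> SequentialEffect:
    """Drawwise lag-n minus lag-n+2 group effects from a joint fit.

    Every group-level coefficient named ``<stem>_n`` with a partner
    ``<stem>_n2`` is corrected; between-stem contrasts are formed for the
    bound and drift confidence categories (perceived_error - low) when both
    are present.  Raises if a lag partner is missing.
    """
    stems = [n[:-2] for n in posterior.names if n.endswith("_n")]
    if not stems:
        raise ValueError("posterior contains no lag-n coefficients")
    effects = {}
    for stem in stems:
        partner = f"{stem}_n2"
        if partner not in posterior.names:
            raise ValueError(f"posterior lacks the lag-n+2 partner {partner!r}")
        raw_n = posterior.group(f"{stem}_n")
        raw_n2 = posterior.group(partner)
        corrected = raw_n - raw_n2
        effects[stem] = {
            "raw_n": raw_n,
            "raw_n2": raw_n2,
            "corrected": corrected,
            "p_raw_n": posterior_p(raw_n),
            "p_raw_n2": posterior_p(raw_n2),
            "p_corrected": posterior_p(corrected),
        }
    contrasts = {}
    for prefix in ("a", "v"):
        hi, lo = f"{prefix}_pe", f"{prefix}_low"
        if hi in effects and lo in effects:
            cc = effects[hi]["corrected"] - effects[lo]["corrected"]
            cr = effects[hi]["raw_n"] - effects[lo]["raw_n"]
            contrasts[(hi, lo)] = {
                "corrected": cc,
                "raw_n": cr,
                "p_corrected": posterior_p(cc),
                "p_raw_n": posterior_p(cr),
            }
    return SequentialEffect(effects=effects, contrasts=contrasts)


_CONTRAST_TARGET = {"low-vs-high": "low", "pe-vs-high": "perceived_error"}


def matched_trial_subset(trials: pd.DataFrame, contrast: str) -> pd.DataFrame:
    """Matched-trial control subset for one contrast.

    Keeps, per participant, all trials whose confidence category is the
    target ("target" role) plus high-confidence trials whose trial n+2 is in
    the target category ("control" role); everything else is excluded.  The
    returned frame carries a ``matched_role`` column and per-participant
    counts in ``frame.attrs['counts']``.  Depends only on the category
    sequence within participant (block labels are ignored).
    """
    if contrast not in _CONTRAST_TARGET:
        raise ValueError(f"contrast must be one of {sorted(_CONTRAST_TARGET)}")
    target = _CONTRAST_TARGET[contrast]
    df = trials.sort_values(["participant", "trial"]).reset_index(drop=True)
    cat = df["confidence_category"]
    nxt2 = df.groupby("participant", sort=False)["confidence_category"].shift(-2)
    is_target = cat == target
    is_control = (cat == "high") & (nxt2 == target)
    keep = is_target | is_control
    out = df[keep].copy()
    out["matched_role"] = np.where(is_target[keep], "target", "control")
    counts = (
        out.groupby(["participant", "matched_role"]).size().unstack(fill_value=0)
    )
    if int(is_target.sum()) == 0:
        raise ValueError(f"matched-trial subset empty: no {target!r} trials at all")
    if int(is_control.sum()) == 0:
        raise ValueError(
            "matched-trial subset empty: no high-confidence trials followed by "
            f"a {target!r} trial at n+2"
        )
    out.attrs["counts"] = counts
    return out


def _predictor_accuracy_mask(
    trials: pd.DataFrame, design: DesignMatrix, stratum: str
) -> np.ndarray:
    df = trials.sort_values(["participant", "trial"]).reset_index(drop=True)
    prev_acc = df.groupby("participant", sort=False)["accuracy"].shift(1)
    aligned = prev_acc.to_numpy()[design.used_index]
    want = 1 if stratum == "correct-only" else 0
    return aligned == want


def stratified_fit(
    trials: pd.DataFrame,
    stratum: str,
    spec: RegressionSpec = RegressionSpec(),
    mcmc: McmcSpec = McmcSpec(),
    seed: int = 0,
) -> tuple[SequentialEffect, PosteriorSet]:
    """Full pipeline on an accuracy stratum of the predictor trials.

    ``stratum`` is "correct-only" or "error-only", defined by the objective
    accuracy of trial n (the predictor).  Participants lacking any lag-n
    confidence cell within the stratum are dropped and counted in the design
    log, mirroring the reduced participant counts of stratified analyses.
    """
    if stratum not in ("correct-only", "error-only"):
        raise ValueError("stratum must be 'correct-only' or 'error-only'")
    design = build_design(trials, spec)
    mask = _predictor_accuracy_mask(trials, design, stratum)
    if not mask.any():
        raise ValueError(f"stratum {stratum!r} is empty")
    sub = design.subset(mask, drop_log_key="stratum")

    # drop participants lacking any lag-n confidence cell in the stratum
    lowcol = sub.a_names.index("a_low_n") if "a_low_n" in sub.a_names else None
    pecol = sub.a_names.index("a_pe_n") if "a_pe_n" in sub.a_names else None
    keep_participants = []
    for j in range(sub.n_participants):
        sel = sub.participant_idx == j
        ok = True
        for col in (lowcol, pecol):
            if col is not None and sub.Xa[sel, col].sum() == 0:
                ok = False
        if ok:
            keep_participants.append(j)
    dropped = sub.n_participants - len(keep_participants)
    if dropped:
        pmask = np.isin(sub.participant_idx, keep_participants)
        sub = sub.subset(pmask, drop_log_key="dropped_participants")
        sub.log["n_participants_dropped_for_empty_cells"] = dropped
    if sub.n_participants == 0:
        raise ValueError(f"no participant has complete cells in stratum {stratum!r}")

    posterior, _ = fit_hierarchical(sub, mcmc=mcmc, seed=seed)
    return drift_corrected_effect(posterior), posterior
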