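"""Synthetic multi-participant cohorts with known ground truth.

The generator emulates the statistical structure of a perceptual
decision-making experiment with trial-by-trial confidence reports:

* evidence strength varies over 5 levels (motion-coherence-like, including a
  0-coherence level with no objectively correct answer);
* choices and RTs come from the Wiener diffusion kernel with accuracy coding;
* a 6-point confidence rating is produced by post-decisional evidence
  accumulation (the decision variable keeps integrating for a fixed window
  after the bound crossing, so it can end up favoring the unchosen option —
  enabling certainty about errors);
* the *next* trial's bound separation shifts by a category-dependent amount
  (high confidence = reference, 0; low confidence and perceived errors add
  configurable increments), which is the ground truth that the hierarchical
  fit must recover;
* drift rate is modulated multiplicatively by a slow 1/f ("scale-free") gain
  series, emulating arousal/attention drift — the confound the trial_n+2
  subtraction is designed to remove;
* Pe-like and ERN-like single-trial amplitudes are linear in the (negated)
  post-decisional evidence plus noise, so the Pe tracks perceived errors and
  the two components correlate weakly with each other.

Every stochastic step draws from a single seeded generator, so cohorts are
fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from seqddm.ddm_core import DiffusionParams, simulate_trials

__all__ = [
    "SlowDriftSpec",
    "EEGModelSpec",
    "CohortConfig",
    "apply_slow_drift",
    "postdecision_confidence",
    "generate_cohort",
]

# Default 6-point cutpoints on the noisy post-decisional evidence variable
# (choice-conditional frame).  Calibrated once so that, at the default drift
# gains, the category mix per participant lands on the intended study
# conditions (about 58% high confidence, 35% low, 7% perceived errors)
# and accuracy rises monotonically from below chance at rating 1 to ~0.94 at
# rating 6.  These are free calibration knobs of the generator, not empirical
# claims.
DEFAULT_CONFIDENCE_THRESHOLDS: tuple[float, ...] = (-2.1, -1.35, -0.5, 0.35, 1.7)


@dataclass(frozen=True)
class SlowDriftSpec:
    """Slow multiplicative behavioral-state fluctuation (1/f^-beta spectrum).

    ``beta`` is the log-log spectral slope (<= 0; 0 = white) and ``amplitude``
    the standard deviation of the log drift gain.  ``amplitude = 0`` disables
    the modulation (all gains exactly 1).  ``bound_amplitude`` (default 0:
    the slow state touches evidence quality only) additionally modulates the
    bound separation from the *same* latent series — the arousal/motivation
    scenario in which slow state drives both confidence and caution, which is
    the confound the trial_n+2 subtraction exists to remove.
    """

    beta: float = -0.6
    amplitude: float = 0.15
    bound_amplitude: float = 0.0

    def __post_init__(self) -> None:
        if self.beta > 0:
            raise ValueError("spectral exponent beta must be <= 0")
        if self.amplitude < 0 or self.bound_amplitude < 0:
            raise ValueError("amplitudes must be >= 0")


@dataclass(frozen=True)
class EEGModelSpec:
    """Linear maps from the post-decisional evidence variable to EEG amplitudes.

    ``pe_amp = pe_gain * (-e) + pe_noise * N(0,1)`` and analogously for the
    ERN, where ``e`` is the (noisy) choice-conditional post-decisional
    evidence.  Larger Pe for perceived errors, as for the error positivity.
    The default ERN noise is large so that the Pe-ERN trial-to-trial
    correlation is weak (~0.18 at default drift gains).

    ``bound_coupling`` selects what drives the next-trial bound: the previous
    trial's confidence *category* (default), its observed ``pe_amp``
    (standardized within participant at the true generative scale, slope
    ``pe_bound_gain`` per SD of Pe), or its objective *accuracy* (a
    discriminating control in which confidence carries no unique bound
    information; the bound rises by the cohort's ``error_bound_update`` after
    objective errors).
    """

    pe_gain: float = 1.0
    pe_noise: float = 1.4
    ern_gain: float = 1.0
    ern_noise: float = 5.8
    bound_coupling: str = "confidence"  # "pe" or "accuracy"
    pe_bound_gain: float = 0.15

    def __post_init__(self) -> None:
        if self.bound_coupling not in ("confidence", "pe", "accuracy"):
            raise ValueError(
                "bound_coupling must be 'confidence', 'pe' or 'accuracy'"
            )


@dataclass(frozen=True)
class CohortConfig:
    """Full generative configuration for a synthetic cohort.

    Defaults emulate the motion-discrimination study conditions: 28
    participants x 330 rated trials (6 blocks), coherences {0, .05, .1, .2,
    .4}, group bound 2.09 (between-participant SD 0.33), non-decision time
    0.38 s (SD 0.09), drift gain 5 per unit coherence, and next-trial bound
    increments of +0.083 after low confidence and +0.262 after perceived
    errors (high confidence is the reference).
    """

    n_participants: int = 28
    n_trials_per_participant: int = 330
    n_blocks: int = 6
    coherence_levels: tuple[float, ...] = (0.0, 0.05, 0.10, 0.20, 0.40)
    drift_gain: float = 5.0
    base_bound: float = 2.09
    t_er: float = 0.38
    bound_update: dict = field(
        default_factory=lambda: {"high": 0.0, "low": 0.083, "perceived_error": 0.262}
    )
    # between-participant heterogeneity (SDs of truncated normals)
    sd_bound: float = 0.33
    sd_t_er: float = 0.09
    sd_drift_gain_rel: float = 0.15
    postdecision_duration: float = 1.0
    confidence_thresholds: tuple[float, ...] = DEFAULT_CONFIDENCE_THRESHOLDS
    confidence_noise: float = 0.5
    error_bound_update: float = 0.26  # used only with bound_coupling="accuracy"
    slow_drift: SlowDriftSpec = field(default_factory=SlowDriftSpec)
    eeg_model: EEGModelSpec = field(default_factory=EEGModelSpec)
    sim_dt: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        th = np.asarray(self.confidence_thresholds, dtype=float)
        if th.size != 5 or np.any(np.diff(th) <= 0):
            raise ValueError("confidence_thresholds must be 5 strictly increasing cutpoints")
        if any(c < 0 for c in self.coherence_levels):
            raise ValueError("coherence levels must be >= 0")
        for k, d in self.bound_update.items():
            if k not in ("high", "low", "perceived_error"):
                raise ValueError(f"unknown confidence category {k!r} in bound_update")
            if not np.isfinite(d):
                raise ValueError("bound updates must be finite")
        if self.n_trials_per_participant % self.n_blocks:
            raise ValueError("n_trials_per_participant must be divisible by n_blocks")


def _slow_latent(n_trials: int, beta: float, rng: np.random.Generator) -> np.ndarray:
    """Standardized colored-noise latent series with a 1/f^-beta spectrum."""
    freqs = np.fft.rfftfreq(n_trials)
    spec = np.zeros(freqs.size, dtype=complex)
    k = freqs > 0
    phases = rng.uniform(0, 2 * np.pi, size=int(k.sum()))
    mags = freqs[k] ** (beta / 2.0) * rng.normal(1.0, 0.3, size=int(k.sum())).clip(0.1)
    spec[k] = mags * np.exp(1j * phases)
    series = np.fft.irfft(spec, n=n_trials)
    return (series - series.mean()) / series.std()


def apply_slow_drift(
    n_trials: int,
    beta: float,
    amplitude: float,
    rng: np.random.Generator,
    latent: np.ndarray | None = None,
) -> np.ndarray:
    """Positive multiplicative gain series with a 1/f^-beta log-log spectrum.

    The log-gain is colored Gaussian noise synthesized in the Fourier domain
    (spectral amplitudes |f|^(beta/2), random phases), standardized to SD
    ``amplitude`` and exponentiated; the series is then normalized to mean 1.
    ``amplitude = 0`` returns an all-ones series.  A precomputed ``latent``
    series may be supplied to couple several gain series to one slow state.
    """
    if beta > 0:
        raise ValueError("beta must be <= 0")
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if amplitude == 0.0:
        return np.ones(n_trials)
    if latent is None:
        latent = _slow_latent(n_trials, beta, rng)
    gains = np.exp(amplitude * latent)
    return gains / gains.mean()


def postdecision_confidence(
    decision_var_sign: np.ndarray,
    extra_evidence: np.ndarray,
    thresholds: tuple[float, ...] = DEFAULT_CONFIDENCE_THRESHOLDS,
    noise: float = 0.5,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Map post-decisional evidence to 6-point confidence ratings.

    Parameters
    ----------
    decision_var_sign :
        +1 where the upper (correct) bound was chosen, -1 for the lower bound.
    extra_evidence :
        Post-decisional evidence increment in the *accuracy* frame (positive
        toward the correct bound).
    thresholds :
        5 ordered cutpoints on the choice-conditional evidence variable.
    noise :
        SD of Gaussian rating noise added before thresholding.

    Returns
    -------
    Ratings 1..6 in the choice-conditional frame (6 = certain the choice was
    correct, 1 = certain it was wrong).
    """
    th = np.asarray(thresholds, dtype=float)
    if np.any(np.diff(th) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    sign = np.asarray(decision_var_sign, dtype=float)
    e = sign * np.asarray(extra_evidence, dtype=float)
    if noise > 0:
        if rng is None:
            raise ValueError("rng required when noise > 0")
        e = e + noise * rng.standard_normal(e.shape)
    return (np.searchsorted(th, e, side="right") + 1).astype(int)


_CATEGORY_OF_RATING = np.array(
    ["perceived_error", "perceived_error", "low", "low", "high", "high"]
)


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate the full cohort as one tidy trial table.

    Per trial: the drift is ``drift_gain_j * coherence * slow_gain_t`` and the
    bound is ``a0_j + bound_update(category_{t-1})`` (``a0_j`` on the first
    trial of every block); choice and RT come from the diffusion simulator;
    confidence from post-decisional accumulation over
    ``postdecision_duration``; EEG amplitudes from the linear Pe/ERN model.
    Ground-truth columns (``true_a``, ``true_v``, ``slow_gain``) are included
    for recovery tests.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    eeg = cfg.eeg_model
    n_pt = cfg.n_trials_per_participant
    block_len = n_pt // cfg.n_blocks
    tau = cfg.postdecision_duration
    rows: list[dict] = []

    for j in range(cfg.n_participants):
        a0 = max(0.5, rng.normal(cfg.base_bound, cfg.sd_bound))
        ter = max(0.05, rng.normal(cfg.t_er, cfg.sd_t_er))
        gain_j = max(
            0.5, rng.normal(cfg.drift_gain, cfg.sd_drift_gain_rel * cfg.drift_gain)
        )
        latent = _slow_latent(n_pt, cfg.slow_drift.beta, rng)
        slow = apply_slow_drift(
            n_pt, cfg.slow_drift.beta, cfg.slow_drift.amplitude, rng, latent=latent
        )
        slow_a = apply_slow_drift(
            n_pt, cfg.slow_drift.beta, cfg.slow_drift.bound_amplitude, rng,
            latent=latent,
        )
        coh = rng.choice(cfg.coherence_levels, size=n_pt)
        stim = rng.choice([-1, 1], size=n_pt)  # stimulus side (arbitrary for coh=0)
        prev_category: str | None = None
        prev_pe_z: float | None = None
        prev_accuracy: int | None = None
        pe_scale = None  # running scale for the "pe" coupling, set below

        if eeg.bound_coupling == "pe":
            # generative SD of pe_amp under this participant's parameters,
            # estimated once so the coupling is per-SD of Pe
            v_probe = gain_j * np.asarray(cfg.coherence_levels)
            e_sd = float(
                np.sqrt(
                    np.var(v_probe) * tau**2
                    + tau
                    + cfg.confidence_noise**2
                )
            )
            pe_scale = float(np.sqrt(eeg.pe_gain**2 * e_sd**2 + eeg.pe_noise**2))

        for t in range(n_pt):
            block = t // block_len
            if t % block_len == 0:
                prev_category = None
                prev_pe_z = None
                prev_accuracy = None
            base = a0 * slow_a[t]
            if eeg.bound_coupling == "pe" and prev_pe_z is not None:
                a_t = base + eeg.pe_bound_gain * prev_pe_z
            elif eeg.bound_coupling == "confidence" and prev_category is not None:
                a_t = base + cfg.bound_update.get(prev_category, 0.0)
            elif eeg.bound_coupling == "accuracy" and prev_accuracy is not None:
                a_t = base + cfg.error_bound_update * (1 - prev_accuracy)
            else:
                a_t = base
            if a_t <= 0:
                raise ValueError(
                    f"configuration produced a nonpositive bound ({a_t:.3f}) "
                    f"for participant {j}"
                )
            v_t = gain_j * coh[t] * slow[t]
            params = DiffusionParams(a=a_t, v=v_t, t_er=ter)
            rt, ch, cens = simulate_trials(
                params, 1, dt=cfg.sim_dt, rng=int(rng.integers(0, 2**31 - 1))
            )
            choice_correct = int(ch[0])  # 1 = upper (correct-designated) bound
            pseudo = coh[t] == 0.0
            if pseudo:
                # no objectively correct answer: pseudo-accuracy by random
                # (seeded) designation, flagged in the output
                accuracy = int(rng.integers(0, 2))
            else:
                accuracy = choice_correct
            # post-decisional accumulation: same drift and noise, duration tau
            extra = v_t * tau + np.sqrt(tau) * rng.standard_normal()
            sign = 1.0 if choice_correct else -1.0
            rating = int(
                postdecision_confidence(
                    np.array([sign]),
                    np.array([extra]),
                    cfg.confidence_thresholds,
                    cfg.confidence_noise,
                    rng,
                )[0]
            )
            category = str(_CATEGORY_OF_RATING[rating - 1])
            e_choice = sign * extra
            pe_amp = eeg.pe_gain * (-e_choice) + eeg.pe_noise * rng.standard_normal()
            ern_amp = eeg.ern_gain * (-e_choice) + eeg.ern_noise * rng.standard_normal()
            rows.append(
                {
                    "participant": j,
                    "block": block,
                    "trial": t,
                    "coherence": coh[t],
                    "stimulus": stim[t],
                    "choice": choice_correct,
                    "accuracy": accuracy,
                    "pseudo_accuracy": bool(pseudo),
                    "rt": float(rt[0]),
                    "censored": bool(cens[0]),
                    "confidence_rating": rating,
                    "confidence_category": category,
                    "pe_amp": pe_amp,
                    "ern_amp": ern_amp,
                    "true_a": a_t,
                    "true_v": v_t,
                    "slow_gain": slow[t],
                }
            )
            prev_category = category
            prev_accuracy = accuracy
            if pe_scale is not None:
                prev_pe_z = pe_amp / pe_scale
    return pd.DataFrame(rows)
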