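"""Hierarchical Bayesian regression DDM.

The model mirrors the hierarchical regression approach of the HDDM family:
each participant j has a parameter vector (bound coefficients ``alpha_j``,
drift coefficients ``beta_j``, non-decision time ``ter_j``); trial-level bound
and drift are linear in per-trial design rows,

    a_i = x_a(i) . alpha_j,     v_i = x_v(i) . beta_j,

with identity links and a positivity guard on the realized bound (likelihood
-inf when a_i <= 0).  Participant parameters are drawn from group-level
normals (mean mu_k, SD sigma_k); inference is meaningful at the group level
only, and participants with few trials in a condition are shrunk toward the
group mean.  Confidence factors use high confidence as the reference (its
coefficient is fixed at 0 by omission), with indicator columns for {low,
perceived_error} at lag n and lag n+2; evidence strength enters the drift as
a per-participant standardized covariate.

Estimation is adaptive Metropolis-within-Gibbs: single-site random-walk
Metropolis on participant parameters and group SDs (log scale), conjugate
Gibbs for group means, with proposal scales adapted during burn-in.  The
Wiener first-passage likelihood is the error-bounded series density from
:mod:`seqddm.ddm_core`, jit-compiled.  Convergence is monitored with the
classic Gelman-Rubin potential-scale-reduction statistic (required inside
[0.98, 1.02] for group-level parameters) and models are compared with DIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.optimize import minimize

from seqddm.ddm_core import _wfpt_logpdf

__all__ = [
    "RegressionSpec",
    "McmcSpec",
    "PriorSpec",
    "DesignMatrix",
    "PosteriorSet",
    "FitDiagnostics",
    "build_design",
    "fit_hierarchical",
    "rhat",
    "dic",
    "dic_from_deviances",
    "posterior_p",
    "fit_participant_mle",
]


# ---------------------------------------------------------------------------
# Specs and containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegressionSpec:
    """What enters the bound and drift regressions.

    ``bound_confidence`` / ``drift_confidence`` add {low, perceived_error}
    indicators at lag n and lag n+2 (reference: high confidence, fixed to 0).
    ``covariate`` names a trial column (evidence strength) standardized per
    participant and added to the drift; None for fixed-difficulty designs.
    """

    bound_confidence: bool = True
    drift_confidence: bool = True
    covariate: str | None = "coherence"
    lags: tuple[int, ...] = (1, -1)  # shifts of the predictor trial rel. to outcome


@dataclass(frozen=True)
class McmcSpec:
    """MCMC scale.  Desk default 4 chains x 2000; the reference full scale
    (10 chains x 10000, burn half, thin 2) is available via
    ``McmcSpec.full_scale()``."""

    n_chains: int = 4
    n_samples: int = 2000
    burn_frac: float = 0.5
    thin: int = 1

    @staticmethod
    def full_scale() -> "McmcSpec":
        return McmcSpec(n_chains=10, n_samples=10000, burn_frac=0.5, thin=2)


@dataclass(frozen=True)
class PriorSpec:
    """Weakly-informative priors (see methods note).

    Group means: bound intercept ~ N(2, 1), non-decision time ~ N(0.3, 0.2),
    all regression coefficients ~ N(0, 2).  Group SDs ~ half-normal with the
    listed scales.
    """

    bound_intercept: tuple[float, float] = (2.0, 1.0)
    t_er: tuple[float, float] = (0.3, 0.2)
    coefficient: tuple[float, float] = (0.0, 2.0)
    sd_scale_bound_intercept: float = 0.5
    sd_scale_t_er: float = 0.15
    sd_scale_drift_intercept: float = 1.0
    sd_scale_coefficient: float = 0.3


@dataclass
class DesignMatrix:
    """Per-trial design for the hierarchical fit (usable trials only)."""

    rt: np.ndarray  # total RT (s)
    response: np.ndarray  # 1 = upper/correct bound, 0 = lower
    participant_idx: np.ndarray  # codes 0..J-1, sorted contiguous
    participants: np.ndarray  # original labels per code
    Xa: np.ndarray  # (n, pa) bound design, col 0 = intercept
    Xv: np.ndarray  # (n, pv) drift design, col 0 = intercept
    a_names: list  # names of Xa columns (a0, a_<cat>_<lag>, ...)
    v_names: list
    log: dict = field(default_factory=dict)
    used_index: np.ndarray | None = None  # positions in the sorted input table

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    def param_names(self) -> list:
        return list(self.a_names) + list(self.v_names) + ["t_er"]

    def subset(self, mask: np.ndarray, drop_log_key: str = "subset") -> "DesignMatrix":
        """Row-subset of the design (participant codes recompacted)."""
        mask = np.asarray(mask, dtype=bool)
        if mask.shape[0] != self.rt.shape[0]:
            raise ValueError("mask length does not match design rows")
        old_labels = self.participants[self.participant_idx[mask]]
        parts, pidx = np.unique(old_labels, return_inverse=True)
        log = dict(self.log)
        log[drop_log_key] = {
            "n_before": int(self.rt.shape[0]),
            "n_after": int(mask.sum()),
            "participants_before": int(self.n_participants),
            "participants_after": int(len(parts)),
        }
        return DesignMatrix(
            rt=self.rt[mask],
            response=self.response[mask],
            participant_idx=pidx.astype(np.int64),
            participants=parts,
            Xa=self.Xa[mask],
            Xv=self.Xv[mask],
            a_names=list(self.a_names),
            v_names=list(self.v_names),
            log=log,
            used_index=None if self.used_index is None else self.used_index[mask],
        )


@dataclass
class FitDiagnostics:
    rhat: dict
    acceptance: dict
    invalid_fraction: float
    n_chains: int
    n_kept: int


@dataclass
class PosteriorSet:
    """MCMC draws with chain structure.

    ``group_mu`` / ``group_sd``: arrays (P, n_chains, n_kept) for the group
    means / SDs of every participant-level parameter; ``participant``: array
    (P, n_chains, n_kept, J).  Burn-in has already been removed and thinning
    applied.  Participant-level summaries are non-inferential (estimates are
    mutually dependent through the group prior).
    """

    names: list
    group_mu: np.ndarray
    group_sd: np.ndarray
    participant: np.ndarray
    participants: np.ndarray
    meta: dict

    def _ix(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown parameter {name!r}; have {self.names}") from None

    def group(self, name: str, kind: str = "mu") -> np.ndarray:
        """Flattened (chains concatenated) group-level draws for a parameter."""
        src = self.group_mu if kind == "mu" else self.group_sd
        return src[self._ix(name)].reshape(-1)

    def group_chains(self, name: str, kind: str = "mu") -> np.ndarray:
        """Group-level draws with chain structure, shape (chains, kept)."""
        src = self.group_mu if kind == "mu" else self.group_sd
        return src[self._ix(name)]

    def participant_draws(self, name: str) -> np.ndarray:
        """Participant-level draws, shape (chains*kept, J); non-inferential."""
        p = self.participant[self._ix(name)]
        return p.reshape(-1, p.shape[-1])

    def to_frame(self) -> pd.DataFrame:
        """Columnar draws table (chain, iter, parameter, value), group level."""
        rows = []
        n_chains, n_kept = self.group_mu.shape[1:]
        for k, name in enumerate(self.names):
            for c in range(n_chains):
                rows.append(
                    pd.DataFrame(
                        {
                            "chain": c,
                            "iter": np.arange(n_kept),
                            "parameter": f"mu_{name}",
                            "value": self.group_mu[k, c],
                        }
                    )
                )
                rows.append(
                    pd.DataFrame(
                        {
                            "chain": c,
                            "iter": np.arange(n_kept),
                            "parameter": f"sd_{name}",
                            "value": self.group_sd[k, c],
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------

_FACTOR_LEVELS = ("low", "perceived_error")
_LAG_TAG = {1: "n", -1: "n2"}


def build_design(trials: pd.DataFrame, spec: RegressionSpec) -> DesignMatrix:
    """Build the per-trial design for the confidence regression.

    Rows are *outcome* trials (trial n+1 in sequential terms); the lag-1
    predictor is the previous trial's confidence category ("confidence on
    trial n") and the lag -1 predictor the next trial's ("trial n+2").
    Edge trials without both lags, censored trials, and trials from other
    participants' boundaries are dropped and counted in ``log``.
    """
    req = {"participant", "trial", "rt", "accuracy", "confidence_category"}
    missing = req - set(trials.columns)
    if missing:
        raise ValueError(f"trials table lacks columns {sorted(missing)}")
    df = trials.sort_values(["participant", "trial"]).reset_index(drop=True)
    n0 = len(df)
    lag_cols = {}
    for lag in spec.lags:
        lag_cols[lag] = df.groupby("participant", sort=False)[
            "confidence_category"
        ].shift(lag)
    keep = np.ones(n0, dtype=bool)
    for lag in spec.lags:
        keep &= lag_cols[lag].notna().to_numpy()
    if "censored" in df.columns:
        keep &= ~df["censored"].to_numpy(dtype=bool)
    dropped_edges = int(n0 - keep.sum())
    df = df[keep]

    parts, pidx = np.unique(df["participant"].to_numpy(), return_inverse=True)
    a_cols = [np.ones(len(df))]
    a_names = ["a0"]
    v_cols = [np.ones(len(df))]
    v_names = ["v0"]
    for lag in spec.lags:
        cat = lag_cols[lag][keep]
        for lev in _FACTOR_LEVELS:
            ind = (cat == lev).to_numpy(dtype=float)
            tag = f"{'pe' if lev == 'perceived_error' else lev}_{_LAG_TAG[lag]}"
            if spec.bound_confidence:
                a_cols.append(ind)
                a_names.append(f"a_{tag}")
            if spec.drift_confidence:
                v_cols.append(ind)
                v_names.append(f"v_{tag}")
    if spec.covariate is not None:
        if spec.covariate not in df.columns:
            raise ValueError(f"covariate column {spec.covariate!r} not in trials")
        z = np.empty(len(df))
        cv = df[spec.covariate].to_numpy(dtype=float)
        for j in range(len(parts)):
            sel = pidx == j
            s = cv[sel].std()
            z[sel] = (cv[sel] - cv[sel].mean()) / (s if s > 0 else 1.0)
        v_cols.append(z)
        v_names.append(f"v_{spec.covariate}")

    # participants with empty cells are allowed (hierarchical pooling), logged
    empty_cells = {}
    for lag in spec.lags:
        cat = lag_cols[lag][keep]
        for lev in _FACTOR_LEVELS:
            cnt = (
                pd.DataFrame({"p": df["participant"].to_numpy(), "hit": (cat == lev)})
                .groupby("p")["hit"]
                .sum()
            )
            for p, c in cnt.items():
                if c == 0:
                    empty_cells.setdefault(p, []).append(f"{lev}@{_LAG_TAG[lag]}")

    return DesignMatrix(
        rt=df["rt"].to_numpy(dtype=float),
        response=df["accuracy"].to_numpy(dtype=np.int8),
        participant_idx=pidx.astype(np.int64),
        participants=parts,
        Xa=np.column_stack(a_cols),
        Xv=np.column_stack(v_cols),
        a_names=a_names,
        v_names=v_names,
        log={"n_input": n0, "n_used": len(df), "dropped_edge_or_censored": dropped_edges,
             "participants_with_empty_cells": empty_cells},
        used_index=np.flatnonzero(keep),
    )


# ---------------------------------------------------------------------------
# Likelihood and sampler kernels
# ---------------------------------------------------------------------------

_LIK_TOL = 1e-7


@njit(cache=True)
def _block_loglik(rt, resp, Xa, Xv, theta, pa, pv):
    """Log-likelihood of one participant's trials given theta=[alpha,beta,ter]."""
    n = rt.shape[0]
    ter = theta[pa + pv]
    total = 0.0
    for i in range(n):
        a = 0.0
        for k in range(pa):
            a += Xa[i, k] * theta[k]
        if a <= 0.0 or a > 20.0:
            return -np.inf
        v = 0.0
        for k in range(pv):
            v += Xv[i, k] * theta[pa + k]
        t = rt[i] - ter
        if t <= 0.0:
            return -np.inf
        ll = _wfpt_logpdf(t, v, a, 0.5, resp[i] == 1, _LIK_TOL)
        if ll == -np.inf:
            return -np.inf
        total += ll
    return total


@njit(cache=True)
def _seed_numba(seed):
    np.random.seed(seed)


@njit(cache=True)
def _run_chain(
    rt, resp, Xa, Xv, starts, counts,  # data, participant blocks
    theta0, mu0_prior, s0_prior, tau_prior,
    n_samples, n_burn, thin, seed,
):
    """One MCMC chain.  Returns (group_mu, group_sd, participant, acc, invalid)."""
    np.random.seed(seed)
    J, P = theta0.shape
    pa_pv = P - 1
    pv = Xv.shape[1]
    pa = Xa.shape[1]

    theta = theta0.copy()
    mu = np.empty(P)
    sig = np.empty(P)
    for k in range(P):
        mu[k] = theta[:, k].mean()
        s = theta[:, k].std()
        sig[k] = s if s > 0.05 else 0.05

    # proposal scales
    step = np.full((J, P), 0.08)
    step[:, P - 1] = 0.02
    sig_step = np.full(P, 0.3)

    cur_ll = np.empty(J)
    for j in range(J):
        cur_ll[j] = _block_loglik(
            rt[starts[j]:starts[j] + counts[j]],
            resp[starts[j]:starts[j] + counts[j]],
            Xa[starts[j]:starts[j] + counts[j]],
            Xv[starts[j]:starts[j] + counts[j]],
            theta[j], pa, pv,
        )

    n_kept = (n_samples - n_burn + thin - 1) // thin
    out_mu = np.empty((P, n_kept))
    out_sd = np.empty((P, n_kept))
    out_part = np.empty((P, n_kept, J))
    acc = np.zeros((J, P))
    tries = np.zeros((J, P))
    acc_win = np.zeros((J, P))
    tries_win = np.zeros((J, P))
    sig_acc = np.zeros(P)
    sig_tries = np.zeros(P)
    n_invalid = 0
    n_prop = 0
    kept = 0

    for it in range(n_samples):
        # participant-level single-site Metropolis
        for j in range(J):
            s0_, c0_ = starts[j], counts[j]
            for k in range(P):
                old = theta[j, k]
                prop = old + step[j, k] * np.random.normal()
                if k == P - 1 and prop <= 0.0:
                    tries[j, k] += 1
                    tries_win[j, k] += 1
                    n_prop += 1
                    continue
                theta[j, k] = prop
                ll = _block_loglik(
                    rt[s0_:s0_ + c0_], resp[s0_:s0_ + c0_],
                    Xa[s0_:s0_ + c0_], Xv[s0_:s0_ + c0_],
                    theta[j], pa, pv,
                )
                n_prop += 1
                tries[j, k] += 1
                tries_win[j, k] += 1
                if ll == -np.inf:
                    n_invalid += 1
                    theta[j, k] = old
                    continue
                dprior = (
                    (old - mu[k]) ** 2 - (prop - mu[k]) ** 2
                ) / (2.0 * sig[k] ** 2)
                if np.log(np.random.random()) < ll - cur_ll[j] + dprior:
                    cur_ll[j] = ll
                    acc[j, k] += 1
                    acc_win[j, k] += 1
                else:
                    theta[j, k] = old

        # group means: conjugate Gibbs
        for k in range(P):
            prec = 1.0 / s0_prior[k] ** 2 + J / sig[k] ** 2
            mean = (
                mu0_prior[k] / s0_prior[k] ** 2 + theta[:, k].sum() / sig[k] ** 2
            ) / prec
            mu[k] = mean + np.random.normal() / np.sqrt(prec)

        # group SDs: random-walk Metropolis on log scale, half-normal prior
        for k in range(P):
            ls = np.log(sig[k])
            lp = ls + sig_step[k] * np.random.normal()
            sp_ = np.exp(lp)
            ss = 0.0
            for j in range(J):
                ss += (theta[j, k] - mu[k]) ** 2
            logr = (
                -J * lp - ss / (2.0 * sp_ ** 2) - sp_ ** 2 / (2.0 * tau_prior[k] ** 2) + lp
            ) - (
                -J * ls - ss / (2.0 * sig[k] ** 2) - sig[k] ** 2 / (2.0 * tau_prior[k] ** 2) + ls
            )
            sig_tries[k] += 1
            if np.log(np.random.random()) < logr:
                sig[k] = sp_
                sig_acc[k] += 1

        # burn-in adaptation every 50 sweeps
        if it < n_burn and (it + 1) % 50 == 0:
            for j in range(J):
                for k in range(P):
                    if tries_win[j, k] > 0:
                        r = acc_win[j, k] / tries_win[j, k]
                        if r > 0.5:
                            step[j, k] *= 1.4
                        elif r < 0.25:
                            step[j, k] *= 0.7
                    acc_win[j, k] = 0.0
                    tries_win[j, k] = 0.0
            for k in range(P):
                r = sig_acc[k] / max(sig_tries[k], 1.0)
                if r > 0.6:
                    sig_step[k] *= 1.3
                elif r < 0.2:
                    sig_step[k] *= 0.75
            sig_acc[:] = 0.0
            sig_tries[:] = 0.0

        if it >= n_burn and (it - n_burn) % thin == 0:
            for k in range(P):
                out_mu[k, kept] = mu[k]
                out_sd[k, kept] = sig[k]
                for j in range(J):
                    out_part[k, kept, j] = theta[j, k]
            kept += 1

    acc_rate = acc.sum() / max(tries.sum(), 1.0)
    inv_frac = n_invalid / max(n_prop, 1)
    return out_mu[:, :kept], out_sd[:, :kept], out_part[:, :kept], acc_rate, inv_frac


def _init_theta(design: DesignMatrix, rng: np.random.Generator) -> np.ndarray:
    """Moment-based starting values, with overdispersion added per chain."""
    pa, pv = design.Xa.shape[1], design.Xv.shape[1]
    J = design.n_participants
    theta = np.zeros((J, pa + pv + 1))
    for j in range(J):
        sel = design.participant_idx == j
        acc = design.response[sel].mean()
        acc = min(max(acc, 0.52), 0.95)
        min_rt = design.rt[sel].min()
        theta[j, 0] = 2.0  # bound intercept
        theta[j, pa] = np.log(acc / (1 - acc)) / 2.0  # drift intercept
        theta[j, pa + pv] = min(0.3, 0.5 * min_rt)  # non-decision time
    return theta


def fit_hierarchical(
    design: DesignMatrix,
    mcmc: McmcSpec = McmcSpec(),
    priors: PriorSpec = PriorSpec(),
    seed: int = 0,
) -> tuple[PosteriorSet, FitDiagnostics]:
    """Sample the hierarchical regression DDM posterior.

    Chains are run sequentially with distinct seeds and overdispersed starts;
    the first ``burn_frac`` of each chain is discarded and the remainder
    thinned by ``thin``.  Group-level R-hat outside [0.98, 1.02] raises a
    convergence warning; an invalid-likelihood proposal fraction above 1%
    raises a hard warning.
    """
    order = np.argsort(design.participant_idx, kind="stable")
    rt = design.rt[order]
    resp = design.response[order]
    Xa = np.ascontiguousarray(design.Xa[order])
    Xv = np.ascontiguousarray(design.Xv[order])
    pidx = design.participant_idx[order]
    J = design.n_participants
    counts = np.bincount(pidx, minlength=J)
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]]).astype(np.int64)

    pa, pv = Xa.shape[1], Xv.shape[1]
    P = pa + pv + 1
    names = design.param_names()

    mu0 = np.zeros(P)
    s0 = np.zeros(P)
    tau = np.zeros(P)
    for k, name in enumerate(names):
        if name == "a0":
            mu0[k], s0[k] = priors.bound_intercept
            tau[k] = priors.sd_scale_bound_intercept
        elif name == "t_er":
            mu0[k], s0[k] = priors.t_er
            tau[k] = priors.sd_scale_t_er
        elif name == "v0":
            mu0[k], s0[k] = priors.coefficient
            tau[k] = priors.sd_scale_drift_intercept
        else:
            mu0[k], s0[k] = priors.coefficient
            tau[k] = priors.sd_scale_coefficient

    rng = np.random.default_rng(seed)
    n_burn = int(mcmc.n_samples * mcmc.burn_frac)
    mus, sds, parts = [], [], []
    accs, invs = [], []
    for c in range(mcmc.n_chains):
        theta0 = _init_theta(design, rng)
        # overdisperse chain starts
        theta0[:, 0] += rng.normal(0, 0.15)
        theta0[:, pa] += rng.normal(0, 0.15)
        chain_seed = int(rng.integers(0, 2**31 - 1))
        m, s, p, a, iv = _run_chain(
            rt, resp, Xa, Xv, starts, counts.astype(np.int64),
            theta0, mu0, s0, tau,
            mcmc.n_samples, n_burn, mcmc.thin, chain_seed,
        )
        mus.append(m)
        sds.append(s)
        parts.append(p)
        accs.append(a)
        invs.append(iv)

    group_mu = np.stack(mus, axis=1)  # (P, chains, kept)
    group_sd = np.stack(sds, axis=1)
    participant = np.stack(parts, axis=1)  # (P, chains, kept, J)

    rhats = {}
    for k, name in enumerate(names):
        rhats[f"mu_{name}"] = rhat(group_mu[k])
    bad = {k: v for k, v in rhats.items() if not (0.98 <= v <= 1.02)}
    if bad:
        warnings.warn(
            f"convergence warning: group-level R-hat outside [0.98, 1.02]: {bad}",
            stacklevel=2,
        )
    inv_frac = float(np.mean(invs))
    if inv_frac > 0.01:
        warnings.warn(
            f"hard warning: {inv_frac:.1%} of proposals had invalid likelihood",
            stacklevel=2,
        )

    posterior = PosteriorSet(
        names=names,
        group_mu=group_mu,
        group_sd=group_sd,
        participant=participant,
        participants=design.participants,
        meta={
            "n_chains": mcmc.n_chains,
            "n_samples": mcmc.n_samples,
            "burn": n_burn,
            "thin": mcmc.thin,
            "seed": seed,
            "design_log": design.log,
        },
    )
    diagnostics = FitDiagnostics(
        rhat=rhats,
        acceptance={"participant_level": float(np.mean(accs))},
        invalid_fraction=inv_frac,
        n_chains=mcmc.n_chains,
        n_kept=group_mu.shape[2],
    )
    return posterior, diagnostics


# ---------------------------------------------------------------------------
# Diagnostics, model comparison, posterior p-values
# ---------------------------------------------------------------------------


def rhat(draws: np.ndarray) -> float:
    """Classic Gelman-Rubin potential scale reduction, draws shape (chains, n).

    Compares within-chain and between-chain variance; ~1 at convergence.
    Invariant to permuting iterations within a chain.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2 or draws.shape[0] < 2:
        raise ValueError("rhat requires draws shaped (n_chains >= 2, n_iter)")
    m, n = draws.shape
    W = draws.var(axis=1, ddof=1).mean()
    B = n * draws.mean(axis=1).var(ddof=1)
    var_hat = (n - 1) / n * W + B / n
    return float(np.sqrt(var_hat / W))


def _total_loglik(design: DesignMatrix, theta_all: np.ndarray) -> float:
    """Summed log-likelihood over participants for one draw of theta (J, P)."""
    order = np.argsort(design.participant_idx, kind="stable")
    rt = design.rt[order]
    resp = design.response[order]
    Xa = np.ascontiguousarray(design.Xa[order])
    Xv = np.ascontiguousarray(design.Xv[order])
    pidx = design.participant_idx[order]
    total = 0.0
    pa, pv = Xa.shape[1], Xv.shape[1]
    for j in range(design.n_participants):
        sel = pidx == j
        total += _block_loglik(rt[sel], resp[sel], Xa[sel], Xv[sel], theta_all[j], pa, pv)
    return total


def dic_from_deviances(deviances: np.ndarray, deviance_at_mean: float) -> dict:
    """DIC from per-draw deviances and the deviance at the posterior mean.

    DIC = mean deviance + p_D, with effective parameter count
    p_D = mean deviance - deviance at the posterior mean.  Lower is better;
    a difference of ~10 is conventionally meaningful.
    """
    mean_dev = float(np.mean(deviances))
    p_d = mean_dev - float(deviance_at_mean)
    return {"dic": mean_dev + p_d, "mean_deviance": mean_dev, "p_d": p_d}


def dic(
    posterior: PosteriorSet,
    design: DesignMatrix,
    max_draws: int = 200,
    seed: int = 0,
) -> dict:
    """Deviance information criterion from the participant-level draws.

    DIC = mean deviance + p_D with p_D = mean deviance - deviance at the
    posterior mean.  The deviance average uses a random subsample of at most
    ``max_draws`` posterior draws.
    """
    P, n_chains, n_kept, J = posterior.participant.shape
    flat = posterior.participant.reshape(P, n_chains * n_kept, J)
    n_draws = flat.shape[1]
    rng = np.random.default_rng(seed)
    take = (
        np.arange(n_draws)
        if n_draws <= max_draws
        else rng.choice(n_draws, size=max_draws, replace=False)
    )
    devs = np.empty(len(take))
    for i, d in enumerate(take):
        devs[i] = -2.0 * _total_loglik(design, flat[:, d, :].T)
    mean_dev = float(np.mean(devs))
    theta_bar = flat.mean(axis=1).T  # (J, P)
    dev_at_mean = -2.0 * _total_loglik(design, theta_bar)
    return dic_from_deviances(devs, dev_at_mean)


def posterior_p(delta_draws: np.ndarray) -> float:
    """Two-sided posterior overlap p-value: 2 * min(Pr(d>0), Pr(d<0)).

    When no draw crosses zero, the Monte-Carlo floor 1/N is reported.
    """
    d = np.asarray(delta_draws, dtype=float)
    n = d.size
    if n == 0:
        raise ValueError("empty draws")
    p = 2.0 * min((d > 0).mean(), (d < 0).mean())
    return float(max(p, 1.0 / n))


def fit_participant_mle(design: DesignMatrix, j: int) -> np.ndarray:
    """No-pooling maximum-likelihood estimate for one participant.

    Used as the comparison point for the shrinkage (pooling) property; plain
    Nelder-Mead on the negative block log-likelihood.
    """
    sel = design.participant_idx == j
    rt = design.rt[sel]
    resp = design.response[sel]
    Xa = np.ascontiguousarray(design.Xa[sel])
    Xv = np.ascontiguousarray(design.Xv[sel])
    pa, pv = Xa.shape[1], Xv.shape[1]
    x0 = np.zeros(pa + pv + 1)
    x0[0] = 2.0
    acc = min(max(resp.mean(), 0.52), 0.95)
    x0[pa] = np.log(acc / (1 - acc)) / 2.0
    x0[-1] = min(0.3, 0.5 * rt.min())

    def nll(x):
        ll = _block_loglik(rt, resp, Xa, Xv, x, pa, pv)
        return np.inf if ll == -np.inf else -ll

    res = minimize(nll, x0, method="Nelder-Mead",
                   options={"maxiter": 4000, "xatol": 1e-4, "fatol": 1e-4})
    return res.x
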