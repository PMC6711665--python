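"""Shared fixtures: expensive cohorts and fits are built once per session."""

from __future__ import annotations

import pytest

from seqddm.hierarchical_fit import McmcSpec, RegressionSpec, build_design, fit_hierarchical
from seqddm.synthetic_cohort import CohortConfig, EEGModelSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Default-calibration cohort, 12 participants x 330 rated trials."""
    return generate_cohort(CohortConfig(n_participants=12, seed=7))


@pytest.fixture(scope="session")
def recovery_cohort():
    """Recovery cohort: 25 x 500 with bound shifts +0.08 (low) / +0.26 (pe)."""
    cfg = CohortConfig(
        n_participants=25,
        n_trials_per_participant=500,
        n_blocks=5,
        bound_update={"high": 0.0, "low": 0.08, "perceived_error": 0.26},
        seed=101,
    )
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def recovery_fit(recovery_cohort):
    """Hierarchical fit of the recovery cohort at reduced MCMC scale."""
    _, trials = recovery_cohort
    design = build_design(trials, RegressionSpec())
    posterior, diagnostics = fit_hierarchical(
        design, mcmc=McmcSpec(n_chains=3, n_samples=2000), seed=11
    )
    return design, posterior, diagnostics


@pytest.fixture(scope="session")
def pe_coupled_cohort():
    """Cohort whose next-trial bound follows the observed Pe amplitude."""
    cfg = CohortConfig(
        n_participants=14,
        n_trials_per_participant=400,
        n_blocks=4,
        eeg_model=EEGModelSpec(bound_coupling="pe", pe_bound_gain=0.15),
        seed=33,
    )
    return cfg, generate_cohort(cfg)
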