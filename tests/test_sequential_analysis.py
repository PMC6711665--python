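"""Drift-corrected effects, matched-trial control, accuracy-stratified fits."""

import numpy as np
import pandas as pd
import pytest

from seqddm.hierarchical_fit import McmcSpec, PosteriorSet, RegressionSpec
from seqddm.sequential_analysis import (
    drift_corrected_effect,
    matched_trial_subset,
    stratified_fit,
)
from seqddm.synthetic_cohort import CohortConfig, EEGModelSpec, generate_cohort


def _fake_posterior(values: dict) -> PosteriorSet:
    names = list(values)
    n = len(next(iter(values.values())))
    mu = np.stack([np.asarray(values[k], dtype=float).reshape(1, n) for k in names])
    return PosteriorSet(
        names=names,
        group_mu=mu,
        group_sd=np.full_like(mu, 0.1),
        participant=mu[..., None],
        participants=np.array([0]),
        meta={},
    )


class TestDriftCorrectedEffect:
    def test_identical_lags_give_exact_zero(self):
        d = np.linspace(-1, 1, 200)
        post = _fake_posterior({"a_low_n": d, "a_low_n2": d})
        eff = drift_corrected_effect(post)
        assert np.all(eff.effects["a_low"]["corrected"] == 0.0)

    def test_antisymmetric_under_lag_swap(self):
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal(300), rng.standard_normal(300)
        fwd = drift_corrected_effect(_fake_posterior({"a_pe_n": x, "a_pe_n2": y}))
        rev = drift_corrected_effect(_fake_posterior({"a_pe_n": y, "a_pe_n2": x}))
        np.testing.assert_allclose(
            fwd.effects["a_pe"]["corrected"], -rev.effects["a_pe"]["corrected"]
        )

    def test_missing_lag_partner_rejected(self):
        post = _fake_posterior({"a_low_n": np.zeros(10), "a0": np.ones(10)})
        with pytest.raises(ValueError, match="n\\+2"):
            drift_corrected_effect(post)

    def test_between_category_contrast_emitted(self):
        rng = np.random.default_rng(1)
        post = _fake_posterior(
            {
                "a_low_n": rng.normal(0.1, 0.02, 400),
                "a_low_n2": rng.normal(0.0, 0.02, 400),
                "a_pe_n": rng.normal(0.3, 0.02, 400),
                "a_pe_n2": rng.normal(0.0, 0.02, 400),
            }
        )
        eff = drift_corrected_effect(post)
        c = eff.contrasts[("a_pe", "a_low")]
        assert c["corrected"].mean() == pytest.approx(0.2, abs=0.02)
        assert c["p_corrected"] < 0.05
        report = eff.report()
        assert {"effect", "component", "mean", "sd", "p"} <= set(report.columns)


def _cat_trials(categories, participant=0, block=0):
    n = len(categories)
    return pd.DataFrame(
        {
            "participant": [participant] * n,
            "block": [block] * n,
            "trial": range(n),
            "confidence_category": categories,
            "rt": [0.8] * n,
            "accuracy": [1] * n,
        }
    )


class TestMatchedTrialSubset:
    def test_hand_enumerated_rule(self):
        t = _cat_trials(["high", "low", "low", "high", "low", "perceived_error"])
        out = matched_trial_subset(t, "low-vs-high")
        got = dict(zip(out["trial"], out["matched_role"]))
        # targets: the three low trials; control: trial 0 (high with low at
        # n+2); trial 3 excluded because trial 5 is a perceived error
        assert got == {0: "control", 1: "target", 2: "target", 4: "target"}

    def test_all_high_sequence_rejected(self):
        with pytest.raises(ValueError, match="no 'low' trials"):
            matched_trial_subset(_cat_trials(["high"] * 8), "low-vs-high")

    def test_missing_controls_rejected(self):
        with pytest.raises(ValueError, match="n\\+2"):
            matched_trial_subset(_cat_trials(["low", "low", "low"]), "low-vs-high")

    def test_block_labels_ignored(self):
        t = _cat_trials(["high", "low", "low", "high", "low", "perceived_error"])
        relabeled = t.copy()
        relabeled["block"] = [5, 1, 2, 2, 0, 9]
        a = matched_trial_subset(t, "low-vs-high")
        b = matched_trial_subset(relabeled, "low-vs-high")
        assert list(a["trial"]) == list(b["trial"])
        assert list(a["matched_role"]) == list(b["matched_role"])

    def test_counts_per_participant_emitted(self):
        t = pd.concat(
            [
                _cat_trials(["high", "low", "low", "high", "low", "high"], participant=0),
                _cat_trials(["low", "high", "low", "low", "high", "low"], participant=1),
            ]
        )
        out = matched_trial_subset(t, "low-vs-high")
        counts = out.attrs["counts"]
        assert set(counts.index) == {0, 1}
        assert (counts.sum(axis=1) > 0).all()


class TestStratifiedFit:
    def test_error_stratum_empty_on_all_correct_cohort(self):
        t = _cat_trials(["high", "low", "high", "low", "high"])
        with pytest.raises(ValueError, match="empty"):
            stratified_fit(t, "error-only", RegressionSpec(covariate=None))

    def test_unknown_stratum_rejected(self):
        t = _cat_trials(["high", "low", "high"])
        with pytest.raises(ValueError, match="stratum"):
            stratified_fit(t, "everything")

    def test_confidence_effect_survives_correct_only_stratum(self):
        # the generator couples the bound to confidence, not accuracy, so the
        # perceived-error bound shift persists within objectively correct
        # predictor trials
        cfg = CohortConfig(n_participants=12, n_trials_per_participant=400,
                           n_blocks=4, seed=61)
        trials = generate_cohort(cfg)
        eff, post = stratified_fit(
            trials, "correct-only", RegressionSpec(),
            mcmc=McmcSpec(n_chains=2, n_samples=1200), seed=62,
        )
        pe = eff.effects["a_pe"]
        assert np.mean(pe["corrected"]) > 0
        assert pe["p_raw_n"] < 0.05

    def test_accuracy_coupled_cohort_shows_no_confidence_effect(self):
        # discriminating control: when the bound follows objective accuracy
        # only, the within-stratum confidence coefficients cover zero
        cfg = CohortConfig(
            n_participants=10,
            n_trials_per_participant=300,
            n_blocks=2,
            eeg_model=EEGModelSpec(bound_coupling="accuracy"),
            seed=63,
        )
        trials = generate_cohort(cfg)
        eff, _ = stratified_fit(
            trials, "correct-only", RegressionSpec(),
            mcmc=McmcSpec(n_chains=2, n_samples=1200), seed=64,
        )
        for stem in ("a_low", "a_pe"):
            lo, hi = np.percentile(eff.effects[stem]["corrected"], [2.5, 97.5])
            assert lo < 0 < hi, stem
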