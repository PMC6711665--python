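# seqddm

**Confidence-dependent sequential adaptation of decision bounds.**

When people make perceptual decisions without feedback, the only signal
available for adjusting their decision policy is internal: their *confidence*
that the last choice was correct.  `seqddm` implements a complete analysis
chain for testing whether confidence on trial *n* predicts the
speed–accuracy tradeoff — the decision-bound separation of a drift diffusion
model (DDM) — on trial *n+1*, and whether a post-decisional EEG signature of
confidence (the error positivity, Pe) carries that prediction at the single
trial level.  It is written for computational cognitive neuroscientists who
work with trial-level behavioral tables (choice, RT, 6-point confidence
rating, optionally single-trial ERN/Pe amplitudes).

## The model

Evidence accumulates as a Wiener process with drift *v* between absorbing
bounds at 0 and *a* (start *a/2*, unit diffusion noise); the bound hit gives
the choice and the first-passage time plus a non-decision time *T_er* gives
the RT.  For the unbiased case,

    P(correct) = 1 / (1 + e^{-a v}),     E[DT] = (a / 2v) · tanh(a v / 2).

The trial-level regression DDM lets bound and drift vary with the previous
trial's confidence category (high = reference, low and perceived-error
indicators) *and* with the category of the trial after next (lag n+2):

    a_i = a0 + δa_low·1[conf_n = low] + δa_pe·1[conf_n = pe] + (lag n+2 terms)
    v_i = v0 + b·z(evidence strength) + (confidence terms as above)

Participant parameters are pooled through group-level normals (hierarchical
Bayes, MCMC), and the **drift-corrected effect** is the drawwise difference
between lag-n and lag-n+2 group posteriors — the lag-n+2 coefficient cannot
be causal and serves as a proxy for slow 1/f "scale-free" performance drift.
A matched-trial control and accuracy-stratified fits complete the causal
triangulation; a model-free caution statistic (median RT × accuracy) mirrors
the model-based result.  See `docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
from seqddm import (CohortConfig, RegressionSpec, McmcSpec,
                    generate_cohort, build_design, fit_hierarchical,
                    drift_corrected_effect)

# synthetic cohort with known ground truth: next-trial bound rises by
# 0.083 after low-confidence and 0.262 after perceived-error trials
cfg = CohortConfig(n_participants=20, n_trials_per_participant=500,
                   n_blocks=5, seed=7)
trials = generate_cohort(cfg)

design = build_design(trials, RegressionSpec())
posterior, diagnostics = fit_hierarchical(
    design, mcmc=McmcSpec(n_chains=3, n_samples=1500), seed=1)
effect = drift_corrected_effect(posterior)

for stem in ("a_low", "a_pe"):
    e = effect.effects[stem]
    print(f"{stem}: corrected delta-bound = {np.mean(e['corrected']):+.3f}"
          f"  (p = {e['p_corrected']:.3f})")
print(f"bound a0 = {np.mean(posterior.group('a0')):.2f}, "
      f"t_er = {np.mean(posterior.group('t_er')):.2f}")
```

Output (about two minutes on one core):

```
a_low: corrected delta-bound = +0.068  (p = 0.010)
a_pe: corrected delta-bound = +0.288  (p = 0.000)
bound a0 = 2.23, t_er = 0.37
```

The corrected bound shifts recover the generator's ground truth (+0.083 /
+0.262) within their credible intervals: after a perceived error the next
decision requires noticeably more evidence, and the effect survives the
lag-n+2 subtraction, so it is not an artifact of slow performance drift.
The group bound and non-decision time land near the generating values
(2.09 ± 0.33 across participants, and 0.38 s).

The same machinery runs from the shell:

```bash
seqddm simulate --seed 1 --out out/            # write a synthetic cohort
seqddm sequential --seed 1 --out out/          # caution + fit + effects report
seqddm eeg --seed 1 --out out/ --input out/trials.tsv   # Pe/ERN fits
```

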