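# Methods

`seqddm` studies a sequential-adaptation hypothesis about perceptual
decision-making: the decision-maker's *confidence* in one choice sets the
speed–accuracy tradeoff — concretely, the separation of the decision bounds —
for the next choice, even without external feedback.  The package provides
the full chain needed to test this on trial tables: a Wiener diffusion
kernel, a generative cohort simulator with known ground truth, model-free
caution statistics, a hierarchical Bayesian regression DDM, two bespoke
confound controls, and a single-trial EEG covariate pipeline.

## Diffusion kernel

The decision model is a plain drift diffusion: evidence `X(t)` starts at
`a·w` and diffuses with drift `v` and unit noise (`sigma = 1`, fixing the
units of `a` and `v`) between absorbing bounds at `0` and `a`.  Accuracy
coding is used: the upper bound is the objectively correct response and
`v > 0` drifts toward it.  RT = first-passage time + non-decision time
`t_er`.  No inter-trial variability parameters (`sv`, `sz`, `st`) are
included.

* **First-passage density.**  The density at either bound is evaluated with
  the classical small-time / large-time series pair in normalized time
  `t/a²`, choosing whichever representation needs fewer terms under an
  error-bounded term-count rule.  The tolerance (default `1e-7`) is stated on
  the *returned* density, i.e. the series budget is rescaled by the
  exponential drift prefactor.
* **Closed forms** (unbiased case, `sigma = 1`):
  `P(correct) = 1/(1+e^{-a v})` and
  `E[DT] = (a/2v)·tanh(av/2)`, with limit `a²/4` as `v → 0`.
* **Simulator.**  Euler–Maruyama with exact Gaussian increments plus a
  Brownian-bridge barrier-crossing probability
  `exp(-2(b-x₀)(b-x₁)/σ²Δt)` inside every step, with crossings stamped at
  mid-step.  This removes the `O(√Δt)` discrete-monitoring bias, so the
  default step `Δt = 10⁻³·a²` (scaled by the natural time unit of the
  process) is accurate to KS ≈ 10⁻³ against the analytic distribution.  The
  simulator shares no code with the series density and serves as its
  Monte-Carlo oracle.  Paths that fail to absorb within the cap (default
  20 s) are flagged `censored`, never silently truncated.
* **Zero-evidence trials.**  At zero coherence there is no objectively
  correct answer; a pseudo-accuracy label is assigned by seeded random
  designation and flagged (`pseudo_accuracy`).  Since `v = 0` makes the two
  bounds exchangeable this is innocuous for the likelihood.

## Synthetic cohort

The generator emulates a motion-discrimination study with 6-point confidence
ratings.  Defaults define the study conditions and are not tuned per
analysis:

| parameter | default | meaning |
|---|---|---|
| participants x trials | 28 x 330 | rated trials per participant (6 blocks) |
| coherence levels | 0, .05, .1, .2, .4 | evidence strengths, uniform |
| drift gain | 5.0 /coherence unit (15% between-participant SD) | `v = gain·coherence` |
| base bound `a₀` | 2.09 (SD 0.33) | between-participant truncated normal |
| non-decision time | 0.38 s (SD 0.09) | — |
| bound updates | +0.083 (low), +0.262 (perceived error) | added to the *next* trial's bound; high confidence is the reference |
| post-decision window | 1.0 s | continued accumulation after the bound hit |
| confidence cutpoints | −2.1, −1.35, −0.5, 0.35, 1.7 | on the noisy post-decisional evidence |
| rating noise | 0.5 SD | — |
| slow drift | β = −0.6, amplitude 0.15 | multiplicative 1/f gain on `v` |

**Confidence** is generated by post-decisional accumulation: after the bound
crossing the decision variable keeps integrating for 1 s with the trial's
drift and noise; the increment, signed into the choice-conditional frame and
perturbed by rating noise, is cut by 5 ordered thresholds into ratings 1–6
(6 = certain correct).  Because the post-decisional evidence can cross to
the unchosen side, ratings 1–2 ("perceived errors") carry genuinely
below-chance accuracy — the signature that distinguishes confidence from RT
as an accuracy predictor.  The cutpoints and noise were calibrated once so
that the default cohort produces roughly 58% high / 35% low / 7%
perceived-error trials, accuracy ≈ 0.94 at rating 6 and below 0.5 at
ratings 1–2; they are generator knobs, not empirical claims.  Ratings are
stored in canonical orientation only; counterbalanced scale direction is a
presentation detail handled at I/O time.

**Sequential coupling.**  The next trial's bound is
`a₀ + δ(category_{t−1})`, reset to `a₀` at block starts.  Alternative
couplings exist for discriminating tests: `bound_coupling="pe"` makes the
bound follow the previous trial's *observed* Pe amplitude (per-SD slope),
and `"accuracy"` makes it follow objective accuracy only — a cohort in which
confidence carries no unique bound information.

**Slow state.**  A 1/f^{-β} latent series modulates the drift gain
multiplicatively (mean-1 log-normal).  By default it touches evidence
quality only.  An optional `bound_amplitude` couples the *same* latent
series into the bound — the arousal/motivation scenario in which the slow
state drives both confidence and caution.  This is the data-generating
process under which the raw lag-n bound effect is genuinely confounded:
with drift-only modulation the lag-coded drift coefficients of the joint
regression absorb the slow state and the raw bound effect stays clean, so a
bound-coupled slow state is the right stress test for the correction
procedures.  The confound condition used in tests is β = −1.5, drift
amplitude 0.5, bound amplitude 0.35.

**EEG model.**  Pe- and ERN-like amplitudes are linear in the negated
choice-conditional post-decisional evidence plus independent noise
(`pe_gain = 1, pe_noise = 1.4; ern_gain = 1, ern_noise = 5.8`), making the
Pe a noisy readout of perceived error strength and leaving the Pe–ERN
trial-to-trial correlation weak (~0.18 at default drift gains).

**What the generator does not emulate:** evidence-volatility manipulations,
raw EEG time series (only window amplitudes), post-decisional *stimulus*
conditions (one post-decision regime), choice biases (`w` fixed at 0.5), and
any dependence of confidence on the bound itself.  Because the slow state
enters only through the drift gain, trial-level first-passage noise dominates
the RT and confidence series: their realized log–log spectral slopes stay
near 0 at any plausible amplitude, much shallower than the pronounced
scale-free structure of real behavioral series.  The slow *gain* series
itself has the configured slope (the estimator round-trip test covers this),
and the bound-coupled confound condition reproduces the practical
consequence of slow drift for sequential analyses.  Passing recovery tests
therefore show that the estimation machinery is unbiased under this
generative family — not that real data satisfy it.

## Model-free statistics

* **Binning**: ratings {5,6} → high, {3,4} → low, {1,2} → perceived error.
* **Caution** = central RT × mean accuracy of the trials *following* each
  confidence category, per participant, then averaged.  The central RT is
  the median by default with a mean option (both are defensible; the median
  is robust to the long RT tail).  A companion conditioning on the trial
  *after* next (lag n+2) is always emitted as the descriptive-level
  slow-drift control.  Empty cells are reported missing, never imputed.
* **Spectral slope**: raw periodogram (DC removed, linear detrend by
  default), log-power averaged within ~20 log-spaced frequency bins to
  equalize leverage across decades, least-squares slope in log–log
  coordinates.  White noise ≈ 0; 1/f^b ≈ −b.

## Hierarchical regression DDM

Trial-level bound and drift are linear in design rows with identity links:
indicator columns for {low, perceived error} at lag n and lag n+2 (high
confidence fixed to 0 as reference) on both bound and drift, plus a
per-participant standardized evidence-strength covariate on drift for
multi-difficulty designs.  A realized bound ≤ 0 gets likelihood −∞
(positivity guard).  Participant coefficient vectors are drawn from
group-level normals; inference is meaningful at the group level only.

**Priors** (weakly informative, configurable): group means — bound
intercept N(2, 1), non-decision time N(0.3, 0.2), all other coefficients
N(0, 2); group SDs — half-normal with scales 0.5 (bound intercept), 0.15
(t_er), 1.0 (drift intercept), 0.3 (coefficients).

**Sampler.**  Adaptive Metropolis-within-Gibbs, jit-compiled: single-site
Gaussian random-walk updates on every participant-level parameter (proposal
scales adapted toward ~0.3–0.5 acceptance during burn-in), conjugate Gibbs
draws for group means, and log-scale random-walk updates for group SDs.
Chains run sequentially with distinct seeds and overdispersed starts; the
first half of each chain is discarded and the rest optionally thinned.  The
desk default is 4 chains × 2000 samples; the reference full scale
(10 × 10000, burn half, thin 2) sits behind `McmcSpec.full_scale()`.
Invalid-likelihood proposals are rejected and counted (> 1% raises a hard
warning).

**Diagnostics.**  Classic Gelman–Rubin R-hat (within- vs between-chain
variance, no rank-normalization or chain-splitting, hence invariant to
permuting iterations within a chain) is required in [0.98, 1.02] for
group-level parameters, else a convergence warning.  Model comparison uses
DIC = mean deviance + p_D with p_D = mean deviance − deviance at the
posterior mean (deviance averaged over a posterior subsample).  Posterior
"overlap" p-values are two-sided, `2·min(Pr(δ>0), Pr(δ<0))`, floored at 1/N
when no draw crosses zero; one-sided probabilities are recoverable from the
draws.

## Sequential-effect procedures

* **Drift-corrected effects**: lag-n and lag-n+2 coefficients come from the
  *same joint fit*; the corrected effect is the drawwise difference of the
  group posteriors (preserving their correlation), with p-values from the
  difference distribution and a drawwise perceived-error − low contrast.
  The construction is antisymmetric under swapping the lag roles.
* **Matched trials**: for a target category, keep target trials plus
  high-confidence trials whose trial n+2 is in the target category, so both
  groups stem from statistically similar slow-state periods.  Depends only
  on the within-participant category sequence.
* **Stratified fits** re-run the full pipeline on trials whose *predictor*
  trial (trial n) was objectively correct (or an error); participants
  lacking any lag-n confidence cell within the stratum are dropped and
  counted.

## EEG covariates

Window amplitudes are the mean of a response-locked epoch inside the
component window (ERN: −10…90 ms at FCz; Pe: 250…350 ms at Pz), after a
zero-phase second-order Butterworth low-pass at 10 Hz; window endpoints are
inclusive with nearest-sample snapping.  No baseline correction is applied
by default.  Robust predictors are per-participant average ranks; the ERN is
regressed out of the Pe per participant (zero-variance ERN degrades to mean
centering with a warning) before equal-count quantile binning (k = 5;
remainder trials go to the lower bins, so n = 12 gives sizes 3,3,2,2,2; the
lowest-amplitude bin is the regression reference).  Designs come in a
continuous mode (standardized Pe and ERN ranks at both lags) and a binned
mode (bin 2–5 indicators at both lags) and feed the hierarchical fit
unchanged.  Missing amplitudes propagate as NaN and those trials (and their
lag neighbors) drop out of the design; more than 10% missing raises a hard
warning.

## Numerical and design choices

* Density tolerance 1e-7 (likelihood and user-facing default); series floor
  at 1e-300 before taking logs.
* Non-decision time proposals violating `rt − t_er > 0` are rejected via the
  likelihood; initialization uses `min(0.3, 0.5·min RT)` per participant.
* Sequential predictors never cross participant boundaries; they do cross
  block boundaries (the generator resets the bound at block starts, which
  only slightly dilutes lag-1 effects at the 5 block joints per participant).
* Tie handling is fixed and tested: average ranks for ties, stable sort for
  bin assignment, remainder to lower bins.
* Problem sizes used by the test suite and the acceptance script (recovery:
  25×500 at 3 chains × 2000; confound: 12×400 over batched seeds at 2×1200;
  EEG: 14×400 at 2×1200; kernel oracle: 10^6 trials per grid point) were
  chosen as the smallest scales at which the group-level posteriors are
  stable to well under one posterior SD (verified by the scale-robustness
  test).

## Known limitations

* Reported posterior numbers depend on the prior family; refits of external
  data are expected to agree approximately, not exactly, with results from
  other hierarchical DDM toolchains whose default priors differ.
* The p-value convention is two-sided; one-sided conventions differ by ~2×.
* Participant-level estimates are shrunken and mutually dependent; they are
  emitted for description only.
* The sampler is a random-walk scheme: it is robust but not efficient in
  high correlation regimes; the R-hat gate is the guard, and longer chains
  are the remedy.
* DIC is reported because it is the conventional comparison statistic for
  this model family, with its known optimism about effective parameters.
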