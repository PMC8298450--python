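# Methods

## The question and the statistical design

In a two-hemifield discrimination task, choices and stimuli are correlated
by construction, and so are choices and single-trial stimulus noise (that
is what makes psychophysical reverse correlation work). Any claim that a
neuron's trial-to-trial rate covaries with *choice* therefore has to
remove the stimulus-induced component first, and any claim that this
covariation is spatially unselective has to show it for neurons whose
receptive-field stimulus is irrelevant to the behavior. The package
implements that chain: stimulus correction → signed choice
probability/correlation per relevance condition → an encoding model that
attributes count variance jointly to stimulus, choice and slow drift →
population-level geometry of the stimulus and choice axes.

## Stimulus and task conventions

* Disparities in degrees; the noise grid is nine equally spaced values
  (−0.4…0.4), signal disparities are grid members (defaults ∓0.2).
* Signed signal strength in %: negative = near. A trial at s% signal has
  exactly `round(|s|/100 · frames)` signal frames, randomly interleaved;
  the rest are i.i.d. uniform over the grid. Levels that do not resolve
  to a whole number of frames are rejected.
* 200 frames at 100 Hz = 2 s stimulus; four 500 ms bins for behavioral
  kernels; trial indices 0-based; choices −1 (near) / +1 (far).
* Blocks of 50 completed trials alternate the relevant hemifield,
  starting left; `n_block_cycles` counts left+right pairs. Three cue
  trials per block are bookkeeping only (recorded in the bundle metadata,
  never analyzed), since all analyses operate on completed two-stimulus
  trials.
* 0%-signal trials are over-represented (`zero_signal_fraction`, default
  0.35) because every choice-correlation estimate lives on them.

## Observer model

Choices are generated from the relevant stimulus only: per 500 ms bin,
the evidence is the count of far-signal frames minus near-signal frames;
bins are combined with weights (1, 0.6, 0.3, 0.1) — early-weighted
temporal integration — plus a bias and Gaussian decision noise (SD 4
evidence units), and the choice is the sign. This yields psychometric
thresholds of a few % signal and reverse-correlation kernels that decay
across bins for the relevant stimulus and vanish for the irrelevant one.
The quantitative temporal weighting of real observers is not constrained
here; the weights are a free parameter of the simulator.

## Neural populations and feedback architectures

Each hemisphere carries `n_units_per_side` units responding to the
contralateral stimulus. Per trial the expected rate (spikes/s) is

    g_att · [ base + slope·pref·mean(disparity) + choice term ] + drift + shared + private

* Linear disparity tuning with per-unit slope 18–42 spikes/s/deg and a
  random preferred sign; this scale puts d′ at the highest signal near 1
  and keeps a realistic fraction of units below the screening gates.
* The spatial-attention gain (default 1.2) multiplies the whole visually
  driven response, feedback modulation included. Because AI is a rate
  contrast of 0%-signal responses, pure rate scaling gives
  AI = (g−1)/(g+1) ≈ 0.091, which the simulator recovers.
* Choice term: `gain_u · pref_u · choice`, with per-unit gains drawn
  uniformly in `choice_gain·(1 ± 0.9)` around a mean of 0.9 spikes/s.
  The mean puts corrected choice correlations on the 0.1–0.3 scale of
  mid-level visual cortex; the wide spread produces genuine
  across-unit heterogeneity, which is what makes relevant and irrelevant
  choice correlations rank-correlate under unselective feedback.
  Architecture masks: *selective* — term active only when the unit's
  stimulus is relevant; *unselective* — always; *feedforward* — never
  (instead the decision adds `feedforward_coupling` × the z-scored,
  preference-weighted mean rate noise of the relevant-side units to the
  observer's evidence, so relevant-side choice correlations arise without
  any feedback).
* Drift: a per-unit random walk sampled at one anchor per block cycle,
  linearly interpolated, normalized to SD `drift_amplitude`
  (2 spikes/s) — matching the resolution at which the encoding model's
  tent basis can capture it.
* Shared variability: within-hemisphere and global Gaussian latents with
  loadings signed by each unit's preferred disparity, so covariability
  follows tuning similarity. Loadings are solved from the target count
  correlations (defaults: 0.10 within, 0 across). Across-hemisphere
  coupling defaults to zero deliberately: in this model, task-state
  across-hemisphere covariability is supposed to *emerge* from the
  choice-feedback loop, which is exactly the dissociation the pairwise
  analysis tests (fixation = `choice_gain 0`).
* Counts are Poisson on the rate × 2 s, clipped at zero (clip events are
  counted in the ground truth; at the default operating point they are
  rare).

With `frozen_noise` the frame sequence is a deterministic function of
(seed, signal level), giving repeats of identical stimuli for
noise-correlation analyses.

## Analysis choices worth knowing

* **Subspace map**: ordinary least squares of 0%-signal trial counts on
  frames-per-disparity histograms, one map per relevance condition, with
  a tiny ridge (1e−8 of the design scale) that only matters for
  rank-deficient designs (flagged). Trials for each condition are those
  where the stimulus in the unit's hemifield is at 0% signal.
* **CP**: rank-based aROC with ties counted ½ (tie-corrected
  Mann–Whitney); ≥5 trials per choice class required. Signing uses the
  unit's preferred disparity (ground-truth/fixation tuning when
  available; `preferred_sign_from_tuning` otherwise). The conversion
  CP↔c is the exact arctangent pair; its inverse is
  `c = √2·sin(π/2·(CP−1/2))`, and the small-c slope is √2/π.
* **Time-resolved cc**: 300 ms windows, 10 ms steps, with a
  window-specific subspace map built from the frames shown `latency_ms`
  (default 50 ms, configurable — a physiological response latency, not
  estimated from data) before the window.
* **Nonstationarity trimming**: trailing (causal) 20-trial running mean
  per attention condition, each condition compared against its own
  smoothed peak; boundary trials use the shorter available window.
* **d′** (not otherwise defined by convention):
  (μ_pref − μ_null)/√((σ²_pref+σ²_null)/2) on highest-|signal| trials.
* **Behavioral GLM**: probit link (the model is a cumulative-normal
  choice model even though the linear predictor is often written bare);
  covariates z-scored; L1 penalty selected by 10-fold CV minimum
  deviance, with the intercept unpenalized. Degenerate folds (separation)
  are scored as infinitely bad rather than crashing the path.
* **Psychometric fit**: binomial ML, which weights levels by trial count
  automatically; the unweighted-levels alternative was considered and
  rejected because low-n levels would otherwise dominate the tails.
  Perfect separation is flagged `degenerate` with bounded parameters.
* **Type-II regression**: major-axis (first principal axis), chosen over
  standardized major axis because both variables are correlations on a
  common scale; bootstrap CIs resample pairs. Same-probe pairs closer
  than 100 μm are excluded.
* **Encoding model**: identity link (weights in spikes/trial; negative
  predictions permitted), Laplacian (second-difference) penalty on the
  two tuning blocks only. The objective is a convex quadratic; it is
  minimized by conjugate-gradient iterations from a deterministic zero
  start. Plain steepest descent was tried first and abandoned: the
  design carries an exact null direction (a constant shift of all tuning
  weights trades perfectly against the drift offsets, since histograms
  sum to the frame count and the tent basis sums to one) plus
  near-degenerate curvature, and steepest descent stalls far from the
  least-squares solution. CG from zero stays in the row space of the
  design, so the penalty→0 fit coincides with the minimum-norm OLS
  solution; choice weights are identified despite the degeneracy, and
  tuning curves are reported up to a constant offset shared with drift.
* **Drift anchors**: one per relevant+irrelevant cycle at the cycle
  center, plus boundary anchors clamped to the first/last trial so d(t)
  is defined on every trial.
* **Cross-validation**: 5 contiguous-in-time folds so drift cannot leak;
  drift inside a held-out block is linearly interpolated from the
  training trials' fitted drift trace (its own anchors are unconstrained
  by training data). The smoothness weight can be selected on a CV grid
  (`select_laplacian_weight`).
* **Drift fraction**: var(drift component)/var(model prediction) across
  trials; units above 0.5 are dropped from the geometry analysis. This
  variance-ratio reading is one admissible formalization of "majority of
  the response explained by drift".
* **Geometry**: angles in degrees, cosine clamped to [−1,1]; CIs
  resample *units* (the vector's dimensions), not trials. Note the
  near-minus-far convention makes positive choice feedback anti-parallel
  to the stimulus axis, so stimulus–choice angles cluster near 180°
  rather than 0° in feedback simulations; all alignment statistics are
  rank-based across sessions and unaffected by the convention.

## What the simulator does and does not emulate

It reproduces the statistical structure the analyses rely on: block-cued
relevance, frame-wise stimulus noise with embedded signal, choices driven
only by the relevant stimulus, attention gain, architecture-dependent
choice coupling, slow drift, tuning-signed shared variability, Poisson
spiking. It does **not** emulate: spike waveforms or sorting artifacts,
receptive-field structure and eccentricity, nonlinear or
non-monotonic disparity tuning, spike-history or bursting dynamics,
eye-position covariates, reward/history dependence of behavior, or
realistic cross-areal latencies. Passing tests therefore validate the
*estimators* (unbiasedness, separation, calibration) under the model's
assumptions — they do not certify conclusions on real data where those
assumptions (linearity, Poisson noise, stationary tuning) can fail.

## Problem sizes

Batch analyses in the tests and acceptance checks use 40 sessions per
feedback mode at 400 trials and 12 units per session, four 600-trial
frozen-noise sessions per condition for the pairwise dissociation, and a
2000-trial unit for encoding-model recovery; these sizes make every
qualitative signature statistically stable while keeping a full run on a
single CPU in minutes.

## Known limitations

* The minimum-norm resolution of the tuning/drift degeneracy means
  absolute tuning offsets are not interpretable; only differences across
  disparities (and hence the stimulus population vectors) are.
* The behavioral GLM's lasso path uses a fixed small grid of penalties.
* `opposite_field_modulation` fits an additive two-way ANOVA (no
  interaction term).
* The feedforward architecture couples the choice to a single pooled
  noise mode; richer read-out geometries are out of scope.
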