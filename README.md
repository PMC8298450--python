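# vischoice

Analysis toolkit for asking whether decision-related feedback in visual
cortex is *spatially selective*: when an animal discriminates one of two
simultaneously shown stimuli, do neurons whose receptive field contains the
task-**irrelevant** stimulus still carry choice signals?

The package is aimed at systems neuroscientists working with
two-hemifield discrimination experiments (e.g. coarse disparity
discrimination with dynamic random-dot stereograms). It bundles a
generative session simulator with the full analysis chain, so every stage
can be validated against ground truth before touching real recordings.

## What it computes

**Choice correlations.** For each unit, responses on 0%-signal trials are
corrected for stimulus-induced fluctuations with a *subspace map* `s(x)`
(least-squares per-frame spike weights over the disparity grid; the
predicted count `⟨s, n_t⟩` is subtracted from each trial's count). The
residuals, grouped by the animal's choice, give a signed choice
probability (aROC, preferred-disparity choice as the positive class),
converted to a Pearson choice correlation via

    CP = 1/2 + (2/π) · atan( c / √(2 − c²) ),   c = √2 · sin(π/2 · (CP − 1/2))

computed separately for trials where the unit's stimulus was relevant or
irrelevant. A sliding-window variant gives cc(t).

**Behavior.** Cumulative-Gaussian psychometric fits, psychophysical
reverse correlation (choice-triggered frame-frequency kernels in four
500 ms bins), and a probit GLM
`P(far) = Φ(β₀ + β₁ s_rel + β₂ s_irr + β₃ s_rel·s_irr)` with lasso
regularization (10-fold CV) that tests whether the irrelevant stimulus
leaks into choices.

**Screening.** Nonstationarity trimming (running 20-trial mean per
attention condition, 20%-of-peak floor, longest surviving segment), rate /
d′ / behavioral gates, spatial attention index
`AI = (R_rel − R_irr)/(R_rel + R_irr)`, and a fixation-task two-way ANOVA
control for opposite-hemifield stimulus effects.

**Pairwise structure.** Noise correlations (≥20 repeats per identical
stimulus) vs signal correlations (tuning-curve Pearson), summarized by
major-axis (type-II) regression with 1000-resample bootstrap CIs, within
and across hemispheres.

**Encoding model.** Per-unit linear model of the whole-trial spike count,

    R(t) = Σₓ f_r(x) n_t^(r)(x) + Σₓ f_i(x) n_t^(i)(x) + w_r c_t^(r) + w_i c_t^(i) + d(t)

with tent-basis drift `d(t) = Σⱼ dⱼ ξⱼ(t)` (one anchor per
relevant/irrelevant block cycle), fit jointly by conjugate-gradient
descent on the MSE with a Laplacian smoothness penalty on the tuning
weights — separating stimulus, choice and drift despite their
correlation.

**Population geometry.** Stimulus vectors `f(near) − f(far)` and choice
vectors `w` across units; angles `Θ = cos⁻¹(v₁·v₂ / |v₁||v₂|)` with
unit-resampling 90% CIs, and Spearman statistics across sessions.

**Simulator.** Sessions with 50-trial block-cued relevance, nine-value
uniform disparity-noise frames with embedded signal frames, an
early-weighted noisy-integrator observer that sees only the relevant
stimulus, and spiking populations with attention gain, slow drift,
tuning-signed shared variability and a selectable feedback architecture:
`selective` (choice gain only when the unit's stimulus is relevant),
`unselective` (both conditions), or `feedforward` (choices couple to
pooled relevant-side noise, no feedback term).

## Worked example

```python
from vischoice.config import SimConfig
from vischoice.pipeline import run_pipeline

cfg = SimConfig(seed=42, n_block_cycles=4, n_units_per_side=6)  # unselective feedback
summary = run_pipeline(cfg, "demo_run")
print(summary["choicecorr"], summary["screen"]["mean_AI"])
```

prints (abridged from `demo_run/summary.json`):

```
choicecorr:  n_units 12   mean_cc_rel 0.224   mean_cc_irr 0.215
screen:      mean_AI 0.097
behavior:    psychometric sigma 6.71 %signal; GLM beta1 2.39, beta2 -0.095
geometry:    Θ(stim_r, stim_i) 13.5°, Θ(choice_r, choice_i) 21.4°
```

Read: under unselective feedback the simulated units carry comparable
choice correlations whether their stimulus is relevant (0.224) or
irrelevant (0.215); attention modulates rates by AI ≈ 0.097 (gain 1.2
implies (g−1)/(g+1) ≈ 0.091); the behavioral GLM loads on the relevant
stimulus only (β₂ ≈ 0); and the stimulus and choice population axes are
each consistent across relevance conditions (small Θ). A
`feedback_mode="selective"` run instead drives `mean_cc_irr` to 0.

The same pipeline is scriptable from the shell:

```
vischoice simulate --seed 7 --out bundle/
vischoice run --bundle bundle/ --stages behavior,screen,choicecorr --out results/
```

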