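"""Simulation configuration.

All tunable parameters of the synthetic-session generator live in
:class:`SimConfig`.  Defaults describe a "typical" session of the coarse
disparity discrimination task: 50-trial blocks with the task-relevant
hemifield alternating between blocks, 2 s dynamic random-dot stimuli whose
center disparity is redrawn every frame from a nine-value uniform grid with
embedded signal frames, and two small populations of disparity-tuned units
(one per hemisphere / hemifield).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Tuple

import numpy as np

FEEDBACK_MODES = ("selective", "unselective", "feedforward")


@dataclass
class SimConfig:
    """Parameters of the synthetic discrimination session.

    Stimulus / task structure
    -------------------------
    n_block_cycles:
        Number of relevant-left + relevant-right block pairs.
    trials_per_block:
        Completed two-stimulus trials per block (cue trials are extra,
        metadata-only).
    disparity_grid:
        Noise-frame disparities in degrees, uniform over this grid.
    near_signal, far_signal:
        Signal disparities (deg); must be members of the grid convention
        near < 0 < far.
    signal_levels:
        Signed % signal levels sampled per trial and stimulus
        (negative = near).
    zero_signal_fraction:
        Probability that a trial's signed signal is 0% (no-signal trials
        carry the choice-correlation analysis, so they are over-represented
        relative to a uniform draw over levels).
    frames_per_trial, frame_rate:
        200 frames at 100 Hz give the 2 s stimulus.

    Observer (behaviour generator)
    ------------------------------
    observer_temporal_weights:
        Four weights, one per 500 ms bin, applied to net far-minus-near
        signal-frame evidence; early-weighted by default.
    decision_noise_sd, bias:
        Gaussian decision noise and additive bias, in evidence units
        (net signal frames).

    Neural populations
    ------------------
    n_units_per_side:
        Units per hemisphere (each hemisphere sees the contralateral
        stimulus).
    base_rate:
        Mean stimulus-independent firing rate (spikes/s).
    tuning_slope_range:
        Per-unit tuning slope magnitude (spikes/s per degree of frame
        disparity) drawn uniformly from this range; sign of the preferred
        disparity is random per unit.
    attention_gain:
        Multiplicative rate gain applied when the stimulus in a unit's
        hemifield is task-relevant (spatial attention).
    choice_gain:
        Mean additive choice modulation (spikes/s per choice unit); signed
        by each unit's preferred disparity so positive gains produce
        positive signed choice correlations.
    choice_gain_spread:
        Relative spread of per-unit choice gains (uniform in
        ``choice_gain * (1 ± spread)``); heterogeneity across units is what
        makes relevant/irrelevant choice correlations co-vary across units
        under unselective feedback.
    feedback_mode:
        ``selective`` — choice modulation only while the unit's stimulus is
        relevant; ``unselective`` — in both conditions; ``feedforward`` —
        no additive choice term, choices instead couple to pooled
        relevant-side response noise.
    feedforward_coupling:
        Evidence units per standard deviation of the pooled relevant-side
        noise (feedforward mode only).
    private_noise_sd:
        Per-unit, per-trial Gaussian rate jitter (spikes/s) on top of
        Poisson spiking.
    shared_noise_within, shared_noise_across:
        Target spike-count noise correlations induced by shared latents
        within a hemisphere and across hemispheres; loadings are signed by
        disparity preference so shared variability follows tuning
        similarity.
    drift_amplitude:
        Standard deviation (spikes/s) of the slow random-walk rate drift,
        resampled once per block cycle and linearly interpolated.

    frozen_noise:
        If set, the noise-frame sequence is a deterministic function of
        (seed, signal level), so repeated trials of a level replay an
        identical stimulus.
    """

    n_block_cycles: int = 4
    trials_per_block: int = 50
    disparity_grid: Tuple[float, ...] = (
        -0.4, -0.3, -0.2, -0.1, 0.0, 0.1, 0.2, 0.3, 0.4)
    near_signal: float = -0.2
    far_signal: float = 0.2
    signal_levels: Tuple[float, ...] = (
        -40.0, -20.0, -10.0, -5.0, 0.0, 5.0, 10.0, 20.0, 40.0)
    zero_signal_fraction: float = 0.35
    frames_per_trial: int = 200
    frame_rate: float = 100.0
    n_cue_trials_per_block: int = 3

    observer_temporal_weights: Tuple[float, ...] = (1.0, 0.6, 0.3, 0.1)
    decision_noise_sd: float = 4.0
    bias: float = 0.0

    n_units_per_side: int = 8
    base_rate: float = 20.0
    tuning_slope_range: Tuple[float, float] = (18.0, 42.0)
    attention_gain: float = 1.2
    choice_gain: float = 0.9
    choice_gain_spread: float = 0.9
    feedback_mode: str = "unselective"
    feedforward_coupling: float = 3.0
    private_noise_sd: float = 2.0
    shared_noise_within: float = 0.10
    shared_noise_across: float = 0.0
    drift_amplitude: float = 2.0

    frozen_noise: bool = False
    seed: int = 0
    area: str = "V2"

    def __post_init__(self) -> None:
        if self.trials_per_block <= 0:
            raise ValueError("trials_per_block must be positive")
        if self.n_block_cycles <= 0:
            raise ValueError("n_block_cycles must be positive")
        if self.feedback_mode not in FEEDBACK_MODES:
            raise ValueError(
                f"feedback_mode must be one of {FEEDBACK_MODES}, "
                f"got {self.feedback_mode!r}")
        grid = np.asarray(self.disparity_grid, dtype=float)
        if not (self.near_signal < 0.0 < self.far_signal):
            raise ValueError("require near_signal < 0 < far_signal")
        for name, val in (("near_signal", self.near_signal),
                          ("far_signal", self.far_signal)):
            if not np.isclose(grid, val).any():
                raise ValueError(f"{name}={val} is not on the disparity grid")
        if len(self.observer_temporal_weights) != 4:
            raise ValueError("observer_temporal_weights must have 4 entries "
                             "(one per 500 ms bin)")
        for name in ("attention_gain", "choice_gain", "decision_noise_sd",
                     "drift_amplitude", "private_noise_sd"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        for name in ("shared_noise_within", "shared_noise_across"):
            if not abs(getattr(self, name)) < 1.0:
                raise ValueError(f"|{name}| must be < 1")
        if not 0.0 <= self.zero_signal_fraction <= 1.0:
            raise ValueError("zero_signal_fraction must be in [0, 1]")

    @property
    def trial_duration_s(self) -> float:
        return self.frames_per_trial / self.frame_rate

    @property
    def n_trials(self) -> int:
        """Completed analysis trials (cue trials are metadata-only)."""
        return 2 * self.n_block_cycles * self.trials_per_block

    @property
    def n_units(self) -> int:
        return 2 * self.n_units_per_side

    @property
    def support(self) -> np.ndarray:
        """Disparity support: grid plus signal disparities (sorted, unique)."""
        vals = np.union1d(np.asarray(self.disparity_grid, dtype=float),
                          [self.near_signal, self.far_signal])
        return vals

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key in ("disparity_grid", "signal_levels",
                    "observer_temporal_weights", "tuning_slope_range"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)
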