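"""Generative model of two-stimulus disparity discrimination sessions.

The simulator reproduces the statistical structure the downstream analyses
assume: block-cued relevance alternating every 50 trials, frame-wise
disparity noise on a nine-value grid with randomly interleaved signal
frames, choices driven only by the relevant stimulus through an
early-weighted noisy temporal integrator, and spiking populations (one per
hemisphere) with linear disparity tuning, multiplicative spatial-attention
gain, additive choice modulation under a selectable feedback architecture,
slow rate drift and tuning-signed shared variability.

Spike counts are Poisson draws around a per-trial rate; the rate is clipped
at zero (clip events are counted and reported in the ground truth).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd

from vischoice.config import SimConfig

__all__ = [
    "StimulusSequence",
    "SimulatedSession",
    "generate_stimulus",
    "simulate_choice",
    "simulate_population",
    "generate_session",
    "disparity_histogram",
    "simulate_binned_counts",
    "generate_fixation_block",
]


@dataclass
class StimulusSequence:
    """Per-frame disparity sequence of one stimulus on one trial."""

    frame_disparities: np.ndarray
    signed_signal: float

    def histogram(self, support: np.ndarray) -> np.ndarray:
        """Frames per disparity, ``n_t(x)`` on the given support."""
        return disparity_histogram(self.frame_disparities, support)

    @property
    def n_frames(self) -> int:
        return len(self.frame_disparities)


def disparity_histogram(frames: np.ndarray, support: np.ndarray) -> np.ndarray:
    """Count frames at each disparity of ``support`` (exact matching).

    Raises if a frame disparity is not on the support.
    """
    frames = np.asarray(frames, dtype=float)
    support = np.asarray(support, dtype=float)
    idx = np.searchsorted(support, frames)
    idx = np.clip(idx, 0, len(support) - 1)
    # searchsorted may land one off for values equal to a support point
    lower = np.clip(idx - 1, 0, len(support) - 1)
    use_lower = np.abs(support[lower] - frames) < np.abs(support[idx] - frames)
    idx = np.where(use_lower, lower, idx)
    if not np.allclose(support[idx], frames, atol=1e-9):
        bad = frames[~np.isclose(support[idx], frames, atol=1e-9)]
        raise ValueError(f"frame disparities off support: {np.unique(bad)}")
    return np.bincount(idx, minlength=len(support)).astype(float)


def _signal_frame_count(signed_signal: float, n_frames: int) -> int:
    n_exact = abs(signed_signal) / 100.0 * n_frames
    n_sig = int(round(n_exact))
    if abs(n_exact - n_sig) > 1e-6:
        raise ValueError(
            f"signal level {signed_signal}% is not representable with "
            f"{n_frames} frames (needs {n_exact} signal frames)")
    return n_sig


def generate_stimulus(signed_signal: float, cfg: SimConfig,
                      rng: np.random.Generator) -> StimulusSequence:
    """Draw one stimulus: signal frames randomly interleaved with noise frames.

    Exactly ``round(|signal|/100 * frames)`` frames carry the signal
    disparity (near for negative, far for positive signals); the remaining
    frames are i.i.d. uniform over the noise grid.  With
    ``cfg.frozen_noise`` the sequence is a deterministic function of
    ``(cfg.seed, signed_signal)`` and ``rng`` is ignored.
    """
    if abs(signed_signal) > 100:
        raise ValueError("|signed_signal| must be <= 100")
    if cfg.frozen_noise:
        key = int(round(signed_signal * 100)) + 20000
        rng = np.random.default_rng([int(cfg.seed) % (2**31), key])
    n = cfg.frames_per_trial
    n_sig = _signal_frame_count(signed_signal, n)
    grid = np.asarray(cfg.disparity_grid, dtype=float)
    frames = rng.choice(grid, size=n)
    if n_sig:
        sig_disp = cfg.near_signal if signed_signal < 0 else cfg.far_signal
        pos = rng.choice(n, size=n_sig, replace=False)
        frames[pos] = sig_disp
    return StimulusSequence(frame_disparities=frames,
                            signed_signal=float(signed_signal))


def _bin_evidence(seq: StimulusSequence, cfg: SimConfig) -> np.ndarray:
    """Net far-minus-near signal-frame count in each of 4 equal time bins."""
    frames = seq.frame_disparities
    n_bins = len(cfg.observer_temporal_weights)
    parts = np.array_split(frames, n_bins)
    ev = np.empty(n_bins)
    for b, part in enumerate(parts):
        far = np.isclose(part, cfg.far_signal).sum()
        near = np.isclose(part, cfg.near_signal).sum()
        ev[b] = far - near
    return ev


def simulate_choice(relevant: StimulusSequence, cfg: SimConfig,
                    rng: np.random.Generator,
                    extra_evidence: float = 0.0) -> int:
    """Observer choice (-1 near, +1 far) from the relevant stimulus only.

    Evidence is the temporally weighted net count of far- minus near-signal
    frames, plus bias, optional extra evidence (feedforward coupling) and
    Gaussian decision noise; the choice is its sign.
    """
    ev = _bin_evidence(relevant, cfg)
    w = np.asarray(cfg.observer_temporal_weights, dtype=float)
    total = float(w @ ev) + cfg.bias + extra_evidence
    if cfg.decision_noise_sd > 0:
        total += rng.normal(0.0, cfg.decision_noise_sd)
    return 1 if total >= 0 else -1


@dataclass
class SimulatedSession:
    """A complete simulated session with ground truth.

    Attributes
    ----------
    trials:
        One row per completed two-stimulus trial: ``trial``, ``cycle``,
        ``block``, ``relevant_side`` (left/right), ``signal_left``,
        ``signal_right`` (signed %), ``choice`` (-1 near / +1 far),
        ``reward`` (0/1).
    frames:
        side -> (n_trials, frames_per_trial) array of frame disparities.
    spike_counts:
        (n_units, n_trials) integer spike counts per trial.
    unit_meta:
        One row per unit: ``unit``, ``side``, ``area``, ``pref_sign``
        (+1 far / -1 near), ``tuning_slope``, ``choice_gain``, ``depth_um``.
    ground_truth:
        Generative parameters and internals for recovery tests.
    """

    cfg: SimConfig
    trials: pd.DataFrame
    frames: Dict[str, np.ndarray]
    spike_counts: np.ndarray
    unit_meta: pd.DataFrame
    ground_truth: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def signed_signal(self, side_label: str) -> np.ndarray:
        """Signed % signal of the relevant/irrelevant stimulus per trial."""
        left = self.trials["signal_left"].to_numpy()
        right = self.trials["signal_right"].to_numpy()
        rel_is_left = (self.trials["relevant_side"] == "left").to_numpy()
        if side_label == "relevant":
            return np.where(rel_is_left, left, right)
        if side_label == "irrelevant":
            return np.where(rel_is_left, right, left)
        raise ValueError("side_label must be 'relevant' or 'irrelevant'")

    def unit_condition_mask(self, unit: int, condition: str) -> np.ndarray:
        """Trials on which the stimulus in the unit's hemifield is
        relevant (``condition='relevant'``) or irrelevant."""
        side = self.unit_meta.loc[self.unit_meta["unit"] == unit,
                                  "side"].item()
        rel = (self.trials["relevant_side"] == side).to_numpy()
        return rel if condition == "relevant" else ~rel

    def unit_frames(self, unit: int) -> np.ndarray:
        side = self.unit_meta.loc[self.unit_meta["unit"] == unit,
                                  "side"].item()
        return self.frames[side]


def _make_units(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_units
    lo, hi = cfg.tuning_slope_range
    spread = cfg.choice_gain_spread
    gains = cfg.choice_gain * rng.uniform(1 - spread, 1 + spread, size=n)
    return pd.DataFrame({
        "unit": np.arange(n),
        "side": ["left"] * cfg.n_units_per_side
                + ["right"] * cfg.n_units_per_side,
        "area": cfg.area,
        "pref_sign": rng.choice([-1, 1], size=n),
        "tuning_slope": rng.uniform(lo, hi, size=n),
        "choice_gain": gains,
        # contact depth: 100 um spacing within each probe (hemisphere)
        "depth_um": np.concatenate([np.arange(cfg.n_units_per_side),
                                    np.arange(cfg.n_units_per_side)]) * 100.0,
    })


def _drift_traces(cfg: SimConfig, rng: np.random.Generator,
                  n_units: int, n_trials: int) -> np.ndarray:
    """Smooth random-walk drift (spikes/s), one anchor per block cycle."""
    n_anchor = cfg.n_block_cycles + 1
    steps = rng.normal(0.0, 1.0, size=(n_units, n_anchor))
    walk = np.cumsum(steps, axis=1)
    walk -= walk.mean(axis=1, keepdims=True)
    sd = walk.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    walk = walk / sd * cfg.drift_amplitude
    t_anchor = np.linspace(0, n_trials - 1, n_anchor)
    t = np.arange(n_trials)
    return np.vstack([np.interp(t, t_anchor, walk[u]) for u in range(n_units)])


def _shared_loadings(cfg: SimConfig) -> tuple[float, float]:
    """Loading magnitudes (spikes/s) for within- and across-hemisphere
    latents so that count correlations approximate the configured targets."""
    T = cfg.trial_duration_s
    mean_count = cfg.base_rate * T
    # rate-units variance of a count, excluding shared terms
    v0 = mean_count / T**2 + cfg.private_noise_sd**2
    c_w, c_a = cfg.shared_noise_within, cfg.shared_noise_across
    c_w_extra = max(c_w - c_a, 0.0)
    a2 = c_w_extra * v0 / (1 - c_w_extra) if c_w_extra < 1 else 0.0
    b2 = c_a * (v0 + a2) / (1 - c_a) if c_a > 0 else 0.0
    return float(np.sqrt(a2)), float(np.sqrt(b2))


def simulate_population(session_trials: pd.DataFrame,
                        frames: Dict[str, np.ndarray],
                        choices: np.ndarray,
                        unit_meta: pd.DataFrame,
                        cfg: SimConfig,
                        rng: np.random.Generator,
                        noise: Optional[dict] = None) -> tuple[np.ndarray, dict]:
    """Draw spike counts for every unit given stimuli and choices.

    Per unit the expected rate (spikes/s) is::

        gain_att * (base + tuning drive) + choice term + drift + shared
        + private noise

    where the attention gain applies when the stimulus in the unit's
    hemifield is relevant, and the choice term follows the feedback
    architecture (see :class:`vischoice.config.SimConfig`).  Counts are
    Poisson on the rate clipped at zero.

    ``noise`` may carry pre-drawn latents (from :func:`_draw_noise`) so
    feedforward simulations can couple the choice to the same noise that
    enters the counts.
    """
    n_trials = len(session_trials)
    n_units = len(unit_meta)
    T = cfg.trial_duration_s
    if noise is None:
        noise = _draw_noise(cfg, rng, n_units, n_trials)
        _assemble_rate_noise(noise, unit_meta)
    mean_disp = {side: fr.mean(axis=1) for side, fr in frames.items()}
    rel_side = session_trials["relevant_side"].to_numpy()
    choices = np.asarray(choices)

    rates = np.empty((n_units, n_trials))
    clip_events = 0
    for u in range(n_units):
        row = unit_meta.iloc[u]
        side, pref, slope = row["side"], row["pref_sign"], row["tuning_slope"]
        drive = cfg.base_rate + slope * pref * mean_disp[side]
        if cfg.feedback_mode == "unselective":
            drive = drive + row["choice_gain"] * pref * choices
        elif cfg.feedback_mode == "selective":
            mask = (rel_side == side)
            drive = drive + np.where(mask,
                                     row["choice_gain"] * pref * choices, 0.0)
        # feedforward: no additive choice term
        # attention scales the whole visually driven response, feedback
        # modulation included
        att = np.where(rel_side == side, cfg.attention_gain, 1.0)
        rate = att * drive + noise["drift"][u] + noise["rate_noise"][u]
        clipped = np.maximum(rate, 0.0)
        clip_events += int((rate < 0).sum())
        rates[u] = clipped
    counts = rng.poisson(rates * T).astype(float)
    info = {"clip_events": clip_events, "rates": rates}
    return counts, info


def _draw_noise(cfg: SimConfig, rng: np.random.Generator,
                n_units: int, n_trials: int) -> dict:
    """Pre-draw drift, shared and private rate noise (spikes/s)."""
    drift = _drift_traces(cfg, rng, n_units, n_trials)
    a, b = _shared_loadings(cfg)
    z_left = rng.normal(size=n_trials)
    z_right = rng.normal(size=n_trials)
    z_glob = rng.normal(size=n_trials)
    eps = rng.normal(0.0, cfg.private_noise_sd, size=(n_units, n_trials))
    return {"drift": drift, "a": a, "b": b, "z_left": z_left,
            "z_right": z_right, "z_glob": z_glob, "eps": eps}


def _assemble_rate_noise(noise: dict, unit_meta: pd.DataFrame) -> None:
    """Combine latents into per-unit rate noise, loadings signed by
    disparity preference (so shared variability follows tuning)."""
    n_units = len(unit_meta)
    n_trials = len(noise["z_left"])
    out = np.empty((n_units, n_trials))
    for u in range(n_units):
        row = unit_meta.iloc[u]
        z_h = noise["z_left"] if row["side"] == "left" else noise["z_right"]
        out[u] = (row["pref_sign"] * (noise["a"] * z_h
                                      + noise["b"] * noise["z_glob"])
                  + noise["eps"][u])
    noise["rate_noise"] = out


def generate_session(cfg: SimConfig) -> SimulatedSession:
    """Generate a full session: stimuli, choices, spike counts, ground truth.

    Blocks alternate the relevant side each block (starting left); the two
    stimuli's signed signals are sampled independently.  Identical configs
    (including seed) give identical sessions.
    """
    rng = np.random.default_rng(int(cfg.seed) % (2**31))
    unit_meta = _make_units(cfg, rng)
    n_trials = cfg.n_trials

    rows = []
    frames = {"left": np.empty((n_trials, cfg.frames_per_trial)),
              "right": np.empty((n_trials, cfg.frames_per_trial))}
    seqs_rel = []
    t = 0
    n_blocks = 2 * cfg.n_block_cycles
    for block in range(n_blocks):
        side = "left" if block % 2 == 0 else "right"
        cycle = block // 2
        for _ in range(cfg.trials_per_block):
            sig = {}
            for s in ("left", "right"):
                sig[s] = _draw_signal_level(cfg, rng)
                seq = generate_stimulus(sig[s], cfg, rng)
                frames[s][t] = seq.frame_disparities
                if s == side:
                    seqs_rel.append(seq)
            rows.append({"trial": t, "cycle": cycle, "block": block,
                         "relevant_side": side,
                         "signal_left": sig["left"],
                         "signal_right": sig["right"]})
            t += 1
    trials = pd.DataFrame(rows)

    noise = _draw_noise(cfg, rng, cfg.n_units, n_trials)
    _assemble_rate_noise(noise, unit_meta)

    choices = np.empty(n_trials, dtype=int)
    if cfg.feedback_mode == "feedforward":
        pooled = _pooled_relevant_noise(trials, unit_meta, noise)
        for i, seq in enumerate(seqs_rel):
            choices[i] = simulate_choice(
                seq, cfg, rng,
                extra_evidence=cfg.feedforward_coupling * pooled[i])
    else:
        for i, seq in enumerate(seqs_rel):
            choices[i] = simulate_choice(seq, cfg, rng)
    trials["choice"] = choices

    sig_rel = np.where(trials["relevant_side"] == "left",
                       trials["signal_left"], trials["signal_right"])
    correct = np.sign(sig_rel) == choices
    random_reward = rng.random(n_trials) < 0.5
    trials["reward"] = np.where(sig_rel == 0, random_reward, correct
                                ).astype(int)

    counts, info = simulate_population(trials, frames, choices, unit_meta,
                                       cfg, rng, noise=noise)

    ground_truth = {
        "config": cfg.to_dict(),
        "clip_events": info["clip_events"],
        "unit_pref_sign": unit_meta["pref_sign"].tolist(),
        "unit_tuning_slope": unit_meta["tuning_slope"].tolist(),
        "unit_choice_gain": unit_meta["choice_gain"].tolist(),
        "n_cue_trials": cfg.n_cue_trials_per_block * n_blocks,
    }
    return SimulatedSession(cfg=cfg, trials=trials, frames=frames,
                            spike_counts=counts, unit_meta=unit_meta,
                            ground_truth=ground_truth)


def _draw_signal_level(cfg: SimConfig, rng: np.random.Generator) -> float:
    levels = np.asarray(cfg.signal_levels, dtype=float)
    nonzero = levels[levels != 0]
    if len(nonzero) == 0 or rng.random() < cfg.zero_signal_fraction:
        return 0.0
    return float(rng.choice(nonzero))


def _pooled_relevant_noise(trials: pd.DataFrame, unit_meta: pd.DataFrame,
                           noise: dict) -> np.ndarray:
    """Preference-weighted mean of relevant-side unit rate noise, z-scored.

    The feedforward architecture couples the decision to this pooled
    fluctuation: units on the relevant side whose noise leans toward their
    preferred disparity push the choice the same way.
    """
    rel_side = trials["relevant_side"].to_numpy()
    n_trials = len(trials)
    pooled = np.zeros(n_trials)
    for side in ("left", "right"):
        units = unit_meta.index[unit_meta["side"] == side].to_numpy()
        pref = unit_meta.loc[units, "pref_sign"].to_numpy()
        contrib = (pref[:, None] * noise["rate_noise"][units]).mean(axis=0)
        pooled = np.where(rel_side == side, contrib, pooled)
    sd = pooled.std()
    return pooled / sd if sd > 0 else pooled


def simulate_binned_counts(session: SimulatedSession, units: np.ndarray,
                           bin_ms: float = 10.0,
                           choice_onset_ms: float = 0.0,
                           rng: Optional[np.random.Generator] = None
                           ) -> np.ndarray:
    """Time-resolved Poisson counts for selected units.

    Returns a (len(units), n_trials, n_bins) array of counts in ``bin_ms``
    bins.  Rates follow the frame-by-frame stimulus drive; the additive
    choice term switches on at ``choice_onset_ms`` (0 = whole trial),
    allowing time-courses with late-emerging choice signals.  Drawn
    independently of the whole-trial counts stored on the session.
    """
    cfg = session.cfg
    if rng is None:
        rng = np.random.default_rng(int(cfg.seed) % (2**31) + 1)
    n_trials = session.n_trials
    bin_s = bin_ms / 1000.0
    n_bins = int(round(cfg.trial_duration_s / bin_s))
    frame_of_bin = np.minimum(
        (np.arange(n_bins) * bin_s * cfg.frame_rate).astype(int),
        cfg.frames_per_trial - 1)
    t_bin = np.arange(n_bins) * bin_ms
    choices = session.trials["choice"].to_numpy()
    rel_side = session.trials["relevant_side"].to_numpy()
    out = np.empty((len(units), n_trials, n_bins))
    for k, u in enumerate(np.asarray(units)):
        row = session.unit_meta.iloc[int(u)]
        side, pref, slope = row["side"], row["pref_sign"], row["tuning_slope"]
        disp = session.frames[side][:, frame_of_bin]  # trials x bins
        rate = cfg.base_rate + slope * pref * disp
        gate = (t_bin >= choice_onset_ms).astype(float)[None, :]
        if cfg.feedback_mode == "unselective":
            rate = rate + row["choice_gain"] * pref * choices[:, None] * gate
        elif cfg.feedback_mode == "selective":
            mask = (rel_side == side)[:, None]
            rate = rate + np.where(
                mask, row["choice_gain"] * pref * choices[:, None] * gate, 0.0)
        att = np.where(rel_side == side, cfg.attention_gain, 1.0)[:, None]
        rate = att * rate
        out[k] = rng.poisson(np.maximum(rate, 0.0) * bin_s)
    return out


def generate_fixation_block(cfg: SimConfig,
                            rng: Optional[np.random.Generator] = None,
                            disparities: Optional[np.ndarray] = None,
                            n_repeats: int = 20,
                            duration_s: float = 0.45,
                            opposite_disparities: Optional[np.ndarray] = None,
                            opposite_effect: float = 0.0) -> pd.DataFrame:
    """Fixation-task tuning measurement: brief 100%-signal presentations.

    Each presentation shows one disparity inside the units' receptive
    fields (and optionally an independent disparity in the opposite
    hemifield, with an additive rate effect of ``opposite_effect``
    spikes/s per degree for control simulations).  Returns a long-format
    frame with columns ``disp_in``, ``disp_opp``, ``repeat`` and one count
    column per unit (``u0``, ``u1``, ...).
    """
    if rng is None:
        rng = np.random.default_rng(int(cfg.seed) % (2**31) + 2)
    if disparities is None:
        disparities = np.arange(-1.0, 1.0001, 0.2)
    if opposite_disparities is None:
        opposite_disparities = np.array([0.0])
    unit_meta = _make_units(cfg, rng)
    rows = []
    for d_in in disparities:
        for d_opp in opposite_disparities:
            for rep in range(n_repeats):
                rec = {"disp_in": d_in, "disp_opp": d_opp, "repeat": rep}
                for u in range(len(unit_meta)):
                    row = unit_meta.iloc[u]
                    rate = (cfg.base_rate
                            + row["tuning_slope"] * row["pref_sign"] * d_in
                            + opposite_effect * d_opp)
                    rec[f"u{u}"] = rng.poisson(max(rate, 0.0) * duration_s)
                rows.append(rec)
    return pd.DataFrame(rows)
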