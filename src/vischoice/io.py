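"""Session-bundle on-disk format: diff-able TSV tables plus JSON metadata.

A bundle directory contains::

    trials.tsv        trial, cycle, block, relevant_side, signal_left,
                      signal_right, choice, reward
    frames_left.tsv   trial, frame, disparity   (long format)
    frames_right.tsv  likewise
    spikes.tsv        unit x trial counts (units as rows, first col 'unit')
    units.tsv         unit, side, area, pref_sign, tuning_slope,
                      choice_gain, depth_um
    meta.json         disparity grid, frame rate, seed, dialect notes and
                      (for synthetic sessions) the full ground truth

Conventions (also recorded in meta.json): 0-based trial indices, time in
ms from stimulus onset, disparities in degrees, signed signal in % with
negative = near, choices -1 (near) / +1 (far).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from vischoice.config import SimConfig
from vischoice.synth import SimulatedSession

__all__ = ["write_bundle", "read_bundle", "BundleValidationError"]

REQUIRED_FILES = ("trials.tsv", "frames_left.tsv", "frames_right.tsv",
                  "spikes.tsv", "units.tsv", "meta.json")


class BundleValidationError(ValueError):
    """A session bundle violates the on-disk schema."""


def write_bundle(session: SimulatedSession, path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    session.trials.to_csv(path / "trials.tsv", sep="\t", index=False)
    for side in ("left", "right"):
        fr = session.frames[side]
        n_trials, n_frames = fr.shape
        long = pd.DataFrame({
            "trial": np.repeat(np.arange(n_trials), n_frames),
            "frame": np.tile(np.arange(n_frames), n_trials),
            "disparity": fr.ravel(),
        })
        long.to_csv(path / f"frames_{side}.tsv", sep="\t", index=False,
                    float_format="%.4f")
    spikes = pd.DataFrame(session.spike_counts.astype(int),
                          columns=[str(t) for t in range(session.n_trials)])
    spikes.insert(0, "unit", np.arange(session.spike_counts.shape[0]))
    spikes.to_csv(path / "spikes.tsv", sep="\t", index=False)
    session.unit_meta.to_csv(path / "units.tsv", sep="\t", index=False)
    meta = {
        "config": session.cfg.to_dict(),
        "ground_truth": _jsonable(session.ground_truth),
        "dialect": {
            "trial_index": "0-based",
            "time": "ms from stimulus onset",
            "disparity": "degrees",
            "signal": "signed %, negative = near",
            "choice": "-1 near / +1 far",
        },
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def read_bundle(path) -> SimulatedSession:
    """Read and validate a session bundle.

    Raises :class:`BundleValidationError` naming the offending file (and
    rows, for value-level violations).
    """
    path = Path(path)
    for fname in REQUIRED_FILES:
        if not (path / fname).exists():
            raise BundleValidationError(f"missing required file: {fname}")
    meta = json.loads((path / "meta.json").read_text())
    cfg = SimConfig.from_dict(meta["config"])
    trials = pd.read_csv(path / "trials.tsv", sep="\t")
    units = pd.read_csv(path / "units.tsv", sep="\t")
    spikes = pd.read_csv(path / "spikes.tsv", sep="\t")

    bad_choice = ~trials["choice"].isin([-1, 1])
    if bad_choice.any():
        rows = trials.index[bad_choice].tolist()
        raise BundleValidationError(
            f"trials.tsv: choice not in {{-1, 1}} at rows {rows}")

    counts = spikes.drop(columns="unit").to_numpy(dtype=float)
    if counts.shape[1] != len(trials):
        raise BundleValidationError(
            "spikes.tsv: trial columns do not match trials.tsv rows")
    if (counts < 0).any() or not np.allclose(counts, np.round(counts)):
        raise BundleValidationError(
            "spikes.tsv: counts must be non-negative integers")

    allowed = cfg.support
    frames = {}
    n_frames = cfg.frames_per_trial
    for side in ("left", "right"):
        fname = f"frames_{side}.tsv"
        long = pd.read_csv(path / fname, sep="\t")
        disp = long["disparity"].to_numpy()
        on_grid = np.isclose(disp[:, None], allowed[None, :],
                             atol=1e-6).any(axis=1)
        if not on_grid.all():
            rows = long.index[~on_grid].tolist()[:20]
            raise BundleValidationError(
                f"{fname}: disparity off declared grid at rows {rows}")
        missing = set(trials["trial"]) - set(long["trial"])
        if missing:
            raise BundleValidationError(
                f"{fname}: missing trials {sorted(missing)[:10]}")
        fr = np.full((len(trials), n_frames), np.nan)
        fr[long["trial"].to_numpy(), long["frame"].to_numpy()] = disp
        if np.isnan(fr).any():
            raise BundleValidationError(f"{fname}: incomplete frame rows")
        frames[side] = fr

    gt = meta.get("ground_truth", {})
    return SimulatedSession(cfg=cfg, trials=trials, frames=frames,
                            spike_counts=counts, unit_meta=units,
                            ground_truth=gt)
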