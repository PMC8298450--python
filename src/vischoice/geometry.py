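"""Population stimulus/choice vector geometry.

For each session, the encoding-model weights define four vectors in unit
space: the stimulus vectors (difference of tuning weights at the near and
far signal disparities, per relevance condition) and the choice vectors
(the per-unit choice weights).  Angles between vectors are the arccosine
of the normalized dot product, reported in degrees with unit-resampling
confidence intervals; across sessions the alignment of stimulus and
choice axes is summarized by Spearman rank correlations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from vischoice.encoding import EncodingFit

__all__ = [
    "PopulationVectorSet", "vector_angle", "population_vectors",
    "angle_ci", "cross_session_stats", "ANGLE_PAIRS",
]

MIN_UNITS = 5

ANGLE_PAIRS = (
    ("stim_r", "stim_i"),
    ("choice_r", "choice_i"),
    ("stim_r", "choice_r"),
    ("stim_r", "choice_i"),
)


@dataclass
class PopulationVectorSet:
    vectors: Dict[str, np.ndarray]   # stim_r, stim_i, choice_r, choice_i
    angles: Dict[tuple, float]       # degrees
    ci90: Dict[tuple, tuple]
    n_units: int


def vector_angle(v1: np.ndarray, v2: np.ndarray) -> float:
    """Angle in degrees: arccos(v1.v2 / (|v1||v2|)), cosine clamped."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("angle undefined for a zero vector")
    cos = np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cos)))


def _vectors_from_fits(fits: Sequence[EncodingFit], near_signal: float,
                       far_signal: float) -> Dict[str, np.ndarray]:
    support = fits[0].support
    i_near = int(np.argmin(np.abs(support - near_signal)))
    i_far = int(np.argmin(np.abs(support - far_signal)))
    return {
        "stim_r": np.array([f.f_r[i_near] - f.f_r[i_far] for f in fits]),
        "stim_i": np.array([f.f_i[i_near] - f.f_i[i_far] for f in fits]),
        "choice_r": np.array([f.w_r for f in fits]),
        "choice_i": np.array([f.w_i for f in fits]),
    }


def population_vectors(fits: Sequence[EncodingFit], near_signal: float,
                       far_signal: float, n_resamples: int = 1000,
                       seed: int = 0,
                       max_drift_fraction: float = 0.5,
                       drift_fracs: Sequence[float] | None = None
                       ) -> PopulationVectorSet:
    """Session-level population vectors and their pairwise angles.

    Units whose drift fraction exceeds ``max_drift_fraction`` are dropped
    (when fractions are supplied); sessions with fewer than 5 valid units
    are excluded (raises).  Angle CIs resample units with replacement.
    """
    fits = list(fits)
    if drift_fracs is not None:
        fits = [f for f, d in zip(fits, drift_fracs)
                if d is not None and d <= max_drift_fraction]
    if len(fits) < MIN_UNITS:
        raise ValueError(
            f"need >= {MIN_UNITS} valid units, got {len(fits)}")
    vecs = _vectors_from_fits(fits, near_signal, far_signal)
    angles = {pair: vector_angle(vecs[pair[0]], vecs[pair[1]])
              for pair in ANGLE_PAIRS}
    ci = {pair: angle_ci(fits, pair, near_signal, far_signal,
                         n_resamples=n_resamples, seed=seed)
          for pair in ANGLE_PAIRS}
    return PopulationVectorSet(vectors=vecs, angles=angles, ci90=ci,
                               n_units=len(fits))


def angle_ci(fits: Sequence[EncodingFit], pair: tuple, near_signal: float,
             far_signal: float, n_resamples: int = 1000,
             seed: int = 0) -> tuple:
    """90% CI (5th-95th percentile) of an angle by resampling units."""
    fits = list(fits)
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(max(n_resamples, 1)):
        idx = rng.integers(0, len(fits), size=len(fits))
        vecs = _vectors_from_fits([fits[i] for i in idx],
                                  near_signal, far_signal)
        try:
            vals.append(vector_angle(vecs[pair[0]], vecs[pair[1]]))
        except ValueError:
            continue
    if not vals:
        return (np.nan, np.nan)
    return tuple(np.percentile(vals, [5.0, 95.0]))


def cross_session_stats(angle_table: pd.DataFrame) -> dict:
    """Across-session alignment summaries.

    ``angle_table`` has one row per session with columns named
    ``'stim_r-choice_r'``, ``'stim_r-choice_i'``, ``'choice_r-choice_i'``,
    ``'stim_r-stim_i'``.  Returns Spearman rho and p for the two
    comparisons: stimulus-choice alignment in the relevant vs irrelevant
    condition, and choice-axis vs stimulus-axis consistency across
    conditions.
    """
    if len(angle_table) < 5:
        raise ValueError("need >= 5 sessions")
    out = {}
    for name, (a, b) in {
            "stim_choice_alignment": ("stim_r-choice_r", "stim_r-choice_i"),
            "axis_consistency": ("choice_r-choice_i", "stim_r-stim_i")}.items():
        x = angle_table[a].to_numpy()
        y = angle_table[b].to_numpy()
        if np.unique(x).size < 2 or np.unique(y).size < 2:
            out[name] = {"rho": np.nan, "p": np.nan, "n": len(x),
                         "note": "ties-only input"}
            continue
        rho, p = stats.spearmanr(x, y)
        out[name] = {"rho": float(rho), "p": float(p), "n": len(x)}
    return out
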