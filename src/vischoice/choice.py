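"""Stimulus-corrected, signed choice probabilities and choice correlations.

Choice probability (CP) is the area under the ROC curve separating a unit's
trial responses grouped by the animal's eventual choice, with the
preferred-disparity choice as the positive class; CP = 0.5 means no choice
relation.  Because frame-wise stimulus noise itself covaries with choice,
responses are first corrected by subtracting the spike count predicted from
each trial's disparity histogram through a per-condition "subspace map"
(per-frame spike weights obtained by least squares).  CPs convert to
Pearson choice correlations through a closed-form arctangent mapping::

    CP = 1/2 + (2/pi) * atan( c / sqrt(2 - c^2) )

whose exact inverse is ``c = sqrt(2) * sin( (pi/2) * (CP - 1/2) )``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from vischoice.synth import disparity_histogram

__all__ = [
    "SubspaceMap", "ChoiceStats", "CCTimecourse",
    "subspace_map", "stimulus_correct", "choice_probability",
    "cp_to_cc", "cc_to_cp", "timecourse_cc", "unit_choice_stats",
]

MIN_TRIALS_PER_CHOICE = 5


@dataclass
class SubspaceMap:
    """Per-frame spike weights ``s(x)`` on a disparity support."""

    weights: np.ndarray
    support: np.ndarray
    rank_deficient: bool = False

    def predict(self, histograms: np.ndarray) -> np.ndarray:
        """Predicted spike count per trial, ``<s, n_t>``."""
        return np.asarray(histograms, dtype=float) @ self.weights


@dataclass
class ChoiceStats:
    CP: float
    c_choice: float
    n_pref_choice: int
    n_null_choice: int
    condition: str = ""


@dataclass
class CCTimecourse:
    time_ms: np.ndarray          # window centers, ms after stimulus onset
    cc: np.ndarray
    window_ms: float
    step_ms: float
    latency_ms: float
    underflow: np.ndarray        # True where a window lacked >=5 trials/class


def subspace_map(histograms: np.ndarray, counts: np.ndarray,
                 support: Optional[np.ndarray] = None,
                 ridge: float = 1e-8) -> SubspaceMap:
    """Least-squares map from disparity histograms to spike counts.

    ``histograms`` is (n_trials, k): frames per disparity on 0%-signal
    trials (all trials of one relevance condition, not separated by
    choice).  A tiny ridge (scaled by the design's mean squared magnitude)
    keeps degenerate designs solvable; such fits are flagged.
    """
    H = np.asarray(histograms, dtype=float)
    y = np.asarray(counts, dtype=float)
    if H.ndim != 2 or len(H) != len(y):
        raise ValueError("histograms must be (n_trials, k) matching counts")
    gram = H.T @ H
    scale = np.trace(gram) / max(gram.shape[0], 1)
    rank = np.linalg.matrix_rank(H)
    deficient = rank < H.shape[1]
    w = np.linalg.solve(gram + ridge * scale * np.eye(H.shape[1]), H.T @ y)
    if support is None:
        support = np.arange(H.shape[1], dtype=float)
    return SubspaceMap(weights=w, support=np.asarray(support, dtype=float),
                       rank_deficient=bool(deficient))


def stimulus_correct(counts: np.ndarray, smap: SubspaceMap,
                     histograms: np.ndarray) -> np.ndarray:
    """Residual counts after subtracting the stimulus-predicted count."""
    return np.asarray(counts, dtype=float) - smap.predict(histograms)


def _auroc(pos: np.ndarray, neg: np.ndarray) -> float:
    """Area under the ROC curve via the rank-sum statistic, ties as 1/2."""
    from scipy.stats import rankdata
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    n1, n2 = len(pos), len(neg)
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n2))


def choice_probability(residuals: np.ndarray, choices: np.ndarray,
                       preferred_sign: int,
                       condition: str = "") -> ChoiceStats:
    """Signed CP: aROC with preferred-disparity-choice trials as positives.

    CP > 0.5 means the unit fires more when the animal chooses the unit's
    preferred disparity.  Requires at least 5 trials per choice class.
    """
    residuals = np.asarray(residuals, dtype=float)
    choices = np.asarray(choices)
    if preferred_sign not in (-1, 1):
        raise ValueError("preferred_sign must be -1 (near) or +1 (far)")
    pref = residuals[choices == preferred_sign]
    null = residuals[choices == -preferred_sign]
    if len(pref) < MIN_TRIALS_PER_CHOICE or len(null) < MIN_TRIALS_PER_CHOICE:
        raise ValueError(
            f"need >= {MIN_TRIALS_PER_CHOICE} trials per choice class, got "
            f"{len(pref)} preferred-choice and {len(null)} null-choice")
    cp = _auroc(pref, null)
    return ChoiceStats(CP=cp, c_choice=cp_to_cc(cp),
                       n_pref_choice=len(pref), n_null_choice=len(null),
                       condition=condition)


def cc_to_cp(c_choice):
    """Choice correlation -> CP: ``1/2 + (2/pi) atan(c / sqrt(2 - c^2))``."""
    c = np.asarray(c_choice, dtype=float)
    if np.any(np.abs(c) > 1):
        raise ValueError("|c_choice| must be <= 1")
    out = 0.5 + (2.0 / np.pi) * np.arctan2(c, np.sqrt(2.0 - c * c))
    return float(out) if np.isscalar(c_choice) else out


def cp_to_cc(cp):
    """CP -> choice correlation, the exact inverse of :func:`cc_to_cp`."""
    p = np.asarray(cp, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("CP must lie in [0, 1]")
    out = np.sqrt(2.0) * np.sin(np.pi / 2.0 * (p - 0.5))
    return float(out) if np.isscalar(cp) else out


def unit_choice_stats(counts: np.ndarray, choices: np.ndarray,
                      histograms: np.ndarray, preferred_sign: int,
                      condition: str = "") -> ChoiceStats:
    """Full per-unit pipeline on 0%-signal trials of one relevance
    condition: subspace map, stimulus correction, signed CP and cc."""
    smap = subspace_map(histograms, counts)
    resid = stimulus_correct(counts, smap, histograms)
    return choice_probability(resid, choices, preferred_sign, condition)


def timecourse_cc(binned_counts: np.ndarray, choices: np.ndarray,
                  frame_disparities: np.ndarray, support: np.ndarray,
                  preferred_sign: int, frame_rate: float,
                  bin_ms: float = 10.0, window_ms: float = 300.0,
                  step_ms: float = 10.0,
                  latency_ms: float = 50.0) -> CCTimecourse:
    """Time-resolved choice correlation in a sliding window.

    ``binned_counts`` is (n_trials, n_bins) in ``bin_ms`` bins.  For each
    window the counts are corrected with a window-specific subspace map
    built from the frames shown ``latency_ms`` earlier (latency-adjusted
    stimulus drive), then converted CP -> cc.  Windows in which either
    choice class has fewer than 5 trials yield NaN and are flagged.
    """
    counts = np.asarray(binned_counts, dtype=float)
    n_trials, n_bins = counts.shape
    frames = np.asarray(frame_disparities, dtype=float)
    w_bins = int(round(window_ms / bin_ms))
    s_bins = max(int(round(step_ms / bin_ms)), 1)
    n_frames = frames.shape[1]
    starts = np.arange(0, n_bins - w_bins + 1, s_bins)
    cc = np.full(len(starts), np.nan)
    under = np.zeros(len(starts), dtype=bool)
    centers = (starts + w_bins / 2.0) * bin_ms
    for i, s0 in enumerate(starts):
        win = counts[:, s0:s0 + w_bins].sum(axis=1)
        t0 = s0 * bin_ms - latency_ms
        t1 = (s0 + w_bins) * bin_ms - latency_ms
        f0 = int(np.clip(np.floor(t0 / 1000.0 * frame_rate), 0, n_frames))
        f1 = int(np.clip(np.ceil(t1 / 1000.0 * frame_rate), 0, n_frames))
        if f1 > f0:
            H = np.vstack([disparity_histogram(frames[t, f0:f1], support)
                           for t in range(n_trials)])
        else:
            H = np.zeros((n_trials, len(support)))
        try:
            smap = subspace_map(H, win, support)
            resid = stimulus_correct(win, smap, H)
            stats = choice_probability(resid, choices, preferred_sign)
            cc[i] = stats.c_choice
        except ValueError:
            under[i] = True
    return CCTimecourse(time_ms=centers, cc=cc, window_ms=window_ms,
                        step_ms=step_ms, latency_ms=latency_ms,
                        underflow=under)
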