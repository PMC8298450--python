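"""Pairwise correlation structure: noise vs signal correlations.

Noise correlations are trial-to-trial Pearson correlations of two units'
spike counts over repeats of an identical stimulus, averaged over stimulus
conditions with at least 20 repeats (with a z-scoring variant as a
robustness check).  Signal correlations are Pearson correlations of the
two units' tuning curves along the signed-% -signal axis.  Their relation
is summarized by type-II (major-axis) regression with bootstrap confidence
intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairStats", "RegressionFit",
    "noise_correlation", "signal_correlation",
    "major_axis_regression", "typeII_regress", "pair_table",
]

MIN_REPEATS = 20
MIN_SEPARATION_UM = 100.0


@dataclass
class PairStats:
    unit_a: int
    unit_b: int
    same_hemisphere: bool
    contact_separation_um: float
    noise_r: float
    signal_r: float
    n_conditions: int


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    ci_slope: tuple
    ci_intercept: tuple
    n_pairs: int
    n_resamples: int
    method: str = "major-axis"


def noise_correlation(resp_a: np.ndarray, resp_b: np.ndarray,
                      condition: np.ndarray,
                      min_repeats: int = MIN_REPEATS,
                      estimator: str = "average") -> tuple[float, int]:
    """Mean within-condition Pearson correlation of a pair's counts.

    ``estimator='average'`` computes r per condition (>= ``min_repeats``
    repeats) and averages; ``estimator='zscore'`` z-scores counts within
    each condition and pools a single r across all retained trials.
    Returns (r, number of conditions used); raises if no condition has
    enough repeats.
    """
    a = np.asarray(resp_a, dtype=float)
    b = np.asarray(resp_b, dtype=float)
    condition = np.asarray(condition)
    rs, zs_a, zs_b = [], [], []
    for cond in pd.unique(condition):
        m = condition == cond
        if m.sum() < min_repeats:
            continue
        xa, xb = a[m], b[m]
        if xa.std() == 0 or xb.std() == 0:
            continue
        if estimator == "average":
            rs.append(stats.pearsonr(xa, xb)[0])
        else:
            zs_a.append((xa - xa.mean()) / xa.std())
            zs_b.append((xb - xb.mean()) / xb.std())
    if estimator == "average":
        if not rs:
            raise ValueError(
                f"no stimulus condition with >= {min_repeats} repeats")
        return float(np.mean(rs)), len(rs)
    if estimator == "zscore":
        if not zs_a:
            raise ValueError(
                f"no stimulus condition with >= {min_repeats} repeats")
        za, zb = np.concatenate(zs_a), np.concatenate(zs_b)
        return float(stats.pearsonr(za, zb)[0]), len(zs_a)
    raise ValueError("estimator must be 'average' or 'zscore'")


def signal_correlation(tuning_a: np.ndarray,
                       tuning_b: np.ndarray) -> float:
    """Pearson correlation between two mean-rate tuning curves.

    Raises for flat (zero-variance) tuning, which leaves the correlation
    undefined; callers exclude such pairs.
    """
    a = np.asarray(tuning_a, dtype=float)
    b = np.asarray(tuning_b, dtype=float)
    if len(a) < 3 or len(a) != len(b):
        raise ValueError("tuning curves need >= 3 matching levels")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("flat tuning: signal correlation undefined")
    return float(stats.pearsonr(a, b)[0])


def major_axis_regression(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Major-axis (type-II) slope and intercept.

    The major axis is the first principal axis of the (x, y) scatter:
    slope = (Syy - Sxx + sqrt((Syy - Sxx)^2 + 4 Sxy^2)) / (2 Sxy).
    Appropriate when both variables carry error on the same scale.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sxx = x.var(ddof=1)
    syy = y.var(ddof=1)
    sxy = np.cov(x, y, ddof=1)[0, 1]
    if sxx == 0 and syy == 0:
        raise ValueError("degenerate scatter: zero variance in both axes")
    if sxy == 0:
        # principal axis aligns with the higher-variance coordinate
        slope = 0.0 if sxx >= syy else np.inf
    else:
        slope = (syy - sxx + np.sqrt((syy - sxx) ** 2 + 4 * sxy ** 2)) \
            / (2 * sxy)
    intercept = y.mean() - slope * x.mean() if np.isfinite(slope) else np.nan
    return float(slope), float(intercept)


def typeII_regress(signal_r: Sequence[float], noise_r: Sequence[float],
                   n_resamples: int = 1000,
                   seed: int = 0,
                   min_pairs: int = 10) -> RegressionFit:
    """Major-axis regression of noise on signal correlations with a
    pair-resampling bootstrap 95% CI (percentile)."""
    x = np.asarray(signal_r, dtype=float)
    y = np.asarray(noise_r, dtype=float)
    if len(x) < min_pairs:
        raise ValueError(f"need >= {min_pairs} pairs, got {len(x)}")
    slope, intercept = major_axis_regression(x, y)
    rng = np.random.default_rng(seed)
    boot_s = np.empty(n_resamples)
    boot_i = np.empty(n_resamples)
    for b in range(n_resamples):
        idx = rng.integers(0, len(x), size=len(x))
        try:
            boot_s[b], boot_i[b] = major_axis_regression(x[idx], y[idx])
        except ValueError:
            boot_s[b], boot_i[b] = np.nan, np.nan
    ci_s = tuple(np.nanpercentile(boot_s, [2.5, 97.5]))
    ci_i = tuple(np.nanpercentile(boot_i, [2.5, 97.5]))
    return RegressionFit(slope=slope, intercept=intercept,
                         ci_slope=ci_s, ci_intercept=ci_i,
                         n_pairs=len(x), n_resamples=n_resamples)


def pair_table(counts: np.ndarray, condition: np.ndarray,
               tuning: np.ndarray, unit_meta: pd.DataFrame,
               min_repeats: int = MIN_REPEATS,
               min_separation_um: float = MIN_SEPARATION_UM
               ) -> pd.DataFrame:
    """All valid pairs of a session.

    ``counts`` is (units, trials), ``condition`` labels each trial's
    stimulus (only conditions with >= ``min_repeats`` repeats enter the
    noise correlation), ``tuning`` is (units, levels) mean rates along the
    signed-signal axis.  Same-probe pairs closer than
    ``min_separation_um`` are excluded, as are pairs with flat tuning or
    no valid condition.
    """
    n_units = counts.shape[0]
    rows = []
    for i in range(n_units):
        for j in range(i + 1, n_units):
            ri, rj = unit_meta.iloc[i], unit_meta.iloc[j]
            same = ri["side"] == rj["side"]
            sep = abs(ri["depth_um"] - rj["depth_um"]) if same else np.inf
            if same and sep < min_separation_um:
                continue
            try:
                nr, ncond = noise_correlation(counts[i], counts[j],
                                              condition, min_repeats)
                sr = signal_correlation(tuning[i], tuning[j])
            except ValueError:
                continue
            rows.append(PairStats(
                unit_a=int(ri["unit"]), unit_b=int(rj["unit"]),
                same_hemisphere=bool(same),
                contact_separation_um=float(sep) if same else np.nan,
                noise_r=nr, signal_r=sr, n_conditions=ncond))
    return pd.DataFrame([r.__dict__ for r in rows])
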