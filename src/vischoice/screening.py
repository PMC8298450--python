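"""Per-unit quality screening, nonstationarity trimming, attention index.

Gates applied before the choice-correlation analysis:

* nonstationarity trimming — a running 20-trial mean spike count is
  computed separately per attention condition; trials where it falls below
  20% of that condition's smoothed peak are dropped and the longest
  continuous run of surviving trials is kept;
* mean 0%-signal response > 4 spikes/s;
* d' discriminating the highest-|signal| near vs far stimuli > 0.5;
* session performance > 70% at the highest |signal| and 0%-signal choice
  bias < 75%;
* at least 5 near- and 5 far-choice 0%-signal trials after trimming.

The spatial attention index AI = (R_rel - R_irr)/(R_rel + R_irr) contrasts
0%-signal responses between relevant- and irrelevant-stimulus conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

__all__ = [
    "ScreeningResult", "running_mean", "trim_nonstationarity",
    "dprime", "attention_index", "screen_unit", "opposite_field_modulation",
]

MIN_RATE_HZ = 4.0
MIN_DPRIME = 0.5
MIN_PERFORMANCE = 0.70
MAX_BIAS = 0.75
MIN_CHOICE_TRIALS = 5
TRIM_WINDOW = 20
TRIM_FLOOR = 0.20


@dataclass
class ScreeningResult:
    include: bool
    exclusion_reasons: list
    trial_mask: np.ndarray
    mean_rate_0signal: float
    dprime: float
    AI: Optional[float] = None


def running_mean(x: np.ndarray, window: int = TRIM_WINDOW) -> np.ndarray:
    """Trailing running mean; early entries average what is available."""
    x = np.asarray(x, dtype=float)
    c = np.concatenate([[0.0], np.cumsum(x)])
    n = len(x)
    idx = np.arange(1, n + 1)
    lo = np.maximum(idx - window, 0)
    return (c[idx] - c[lo]) / (idx - lo)


def trim_nonstationarity(counts: np.ndarray, condition: np.ndarray,
                         window: int = TRIM_WINDOW,
                         floor: float = TRIM_FLOOR) -> np.ndarray:
    """Boolean mask of retained trials (longest continuous segment).

    The running mean is computed over each condition's own trial sequence
    (trailing window, causal); a trial is provisionally dropped when the
    smoothed count falls below ``floor`` times the peak of its condition's
    smoothed series.  The returned mask is the longest run of consecutive
    retained trials in the original trial order.
    """
    counts = np.asarray(counts, dtype=float)
    condition = np.asarray(condition)
    keep = np.zeros(len(counts), dtype=bool)
    for cond in np.unique(condition):
        idx = np.where(condition == cond)[0]
        sm_ = running_mean(counts[idx], window)
        peak = sm_.max()
        keep[idx] = sm_ >= floor * peak if peak > 0 else True
    return _longest_run(keep)


def _longest_run(keep: np.ndarray) -> np.ndarray:
    best_len, best_start = 0, 0
    cur_len, cur_start = 0, 0
    for i, k in enumerate(keep):
        if k:
            if cur_len == 0:
                cur_start = i
            cur_len += 1
            if cur_len > best_len:
                best_len, best_start = cur_len, cur_start
        else:
            cur_len = 0
    out = np.zeros(len(keep), dtype=bool)
    out[best_start:best_start + best_len] = True
    return out


def dprime(pref: np.ndarray, null: np.ndarray) -> float:
    """d' with pooled SD: (mu_p - mu_n) / sqrt((var_p + var_n) / 2)."""
    pref = np.asarray(pref, dtype=float)
    null = np.asarray(null, dtype=float)
    pooled = np.sqrt((pref.var(ddof=1) + null.var(ddof=1)) / 2.0)
    if pooled == 0:
        return 0.0 if pref.mean() == null.mean() else np.inf * np.sign(
            pref.mean() - null.mean())
    return float((pref.mean() - null.mean()) / pooled)


def attention_index(r_relevant: float, r_irrelevant: float) -> float:
    """AI = (R_rel - R_irr) / (R_rel + R_irr); undefined when both are 0."""
    tot = r_relevant + r_irrelevant
    if tot <= 0:
        raise ValueError("attention index undefined: both rates are zero")
    return float((r_relevant - r_irrelevant) / tot)


def screen_unit(counts: np.ndarray,
                signed_signal: np.ndarray,
                choices: np.ndarray,
                condition: np.ndarray,
                preferred_sign: int,
                trial_duration_s: float,
                performance_highest: float,
                bias_0signal: float) -> ScreeningResult:
    """Apply all inclusion gates to one unit; always returns a decision.

    ``condition`` labels each trial 'relevant'/'irrelevant' for this unit's
    hemifield (the attention condition used for trimming and AI);
    ``performance_highest`` and ``bias_0signal`` are session-level
    behavioral summaries shared by all units.
    """
    counts = np.asarray(counts, dtype=float)
    signed_signal = np.asarray(signed_signal, dtype=float)
    choices = np.asarray(choices)
    reasons = []

    mask = trim_nonstationarity(counts, condition)
    zero = mask & (signed_signal == 0)
    n_near = int(((choices == -1) & zero).sum())
    n_far = int(((choices == 1) & zero).sum())
    if min(n_near, n_far) < MIN_CHOICE_TRIALS:
        reasons.append("nonstationarity")

    rate0 = counts[zero].mean() / trial_duration_s if zero.any() else 0.0
    if not rate0 > MIN_RATE_HZ:
        reasons.append("min-rate")

    top = np.max(np.abs(signed_signal))
    hi = mask & (np.abs(signed_signal) == top) & (signed_signal != 0)
    pref = counts[hi & (np.sign(signed_signal) == preferred_sign)]
    null = counts[hi & (np.sign(signed_signal) == -preferred_sign)]
    if len(pref) >= 2 and len(null) >= 2:
        dp = dprime(pref, null)
    else:
        dp = np.nan
    if not (np.isfinite(dp) and dp > MIN_DPRIME):
        reasons.append("dprime")

    if not performance_highest > MIN_PERFORMANCE:
        reasons.append("performance")
    if not bias_0signal < MAX_BIAS:
        reasons.append("bias")

    ai = None
    rel0 = zero & (np.asarray(condition) == "relevant")
    irr0 = zero & (np.asarray(condition) == "irrelevant")
    if rel0.any() and irr0.any():
        r_rel = counts[rel0].mean() / trial_duration_s
        r_irr = counts[irr0].mean() / trial_duration_s
        if r_rel + r_irr > 0:
            ai = attention_index(r_rel, r_irr)

    return ScreeningResult(include=not reasons, exclusion_reasons=reasons,
                           trial_mask=mask, mean_rate_0signal=float(rate0),
                           dprime=float(dp) if np.isfinite(dp) else np.nan,
                           AI=ai)


def opposite_field_modulation(responses: pd.DataFrame,
                              rate_col: str = "rate",
                              min_repeats: int = 2,
                              require_tuning: bool = True) -> dict:
    """Fixation-task control: does the opposite-hemifield stimulus matter?

    ``responses`` has columns ``disp_in`` (disparity in the receptive
    field), ``disp_opp`` (opposite hemifield) and ``rate_col``.  A unit
    must first show significant disparity tuning (one-way ANOVA over
    ``disp_in``, p < 0.05); the test proper is a two-way ANOVA with both
    factors, reporting the main-effect p-value of the opposite factor and
    the preferred/null rate ratio against the opposite-disparity axis.
    """
    df = responses.copy()
    groups = [g[rate_col].to_numpy() for _, g in df.groupby("disp_in")]
    if len(groups) < 2:
        raise ValueError("need >= 2 in-RF disparities")
    counts_per_cell = df.groupby(["disp_in", "disp_opp"]).size()
    if (counts_per_cell < min_repeats).any():
        return {"included": False, "reason": "unbalanced-cells"}
    f_tune, p_tune = stats.f_oneway(*groups)
    if require_tuning and not (np.isfinite(p_tune) and p_tune < 0.05):
        return {"included": False, "reason": "not-tuned", "p_tuning": p_tune}

    if df[rate_col].var() == 0:
        return {"included": True, "p_opposite": 1.0, "F_in": 0.0,
                "F_opposite": 0.0, "p_tuning": p_tune, "rate_ratio_opp": 1.0}
    model = smf.ols(f"{rate_col} ~ C(disp_in) + C(disp_opp)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    p_opp = float(table.loc["C(disp_opp)", "PR(>F)"])
    f_opp = float(table.loc["C(disp_opp)", "F"])
    f_in = float(table.loc["C(disp_in)", "F"])

    by_opp = df.groupby("disp_opp")[rate_col].mean()
    ratio = float(by_opp.max() / by_opp.min()) if by_opp.min() > 0 else np.inf
    return {"included": True, "p_opposite": p_opp, "F_opposite": f_opp,
            "F_in": f_in, "p_tuning": float(p_tune), "rate_ratio_opp": ratio}
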