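"""Session-level drivers tying the per-unit statistics together."""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from vischoice.synth import SimulatedSession, disparity_histogram
from vischoice.behavior import fit_psychometric
from vischoice.screening import screen_unit
from vischoice.choice import unit_choice_stats

__all__ = [
    "behavior_summary", "session_choice_table", "architecture_batch",
    "preferred_sign_from_tuning",
]


def behavior_summary(session: SimulatedSession) -> dict:
    """Session performance at the highest |signal| and 0%-signal bias."""
    sig = session.signed_signal("relevant")
    choices = session.trials["choice"].to_numpy()
    top = np.max(np.abs(sig))
    hi = (np.abs(sig) == top) & (sig != 0)
    correct = (np.sign(sig[hi]) == choices[hi]).mean() if hi.any() else np.nan
    zero = sig == 0
    if zero.any():
        p_far = (choices[zero] == 1).mean()
        bias = max(p_far, 1 - p_far)
    else:
        bias = np.nan
    return {"performance_highest": float(correct),
            "bias_0signal": float(bias)}


def preferred_sign_from_tuning(levels: np.ndarray,
                               mean_rates: np.ndarray) -> int:
    """Preferred disparity sign (+1 far / -1 near) from a tuning curve."""
    levels = np.asarray(levels, dtype=float)
    rates = np.asarray(mean_rates, dtype=float)
    slope = np.polyfit(levels, rates, 1)[0]
    return 1 if slope >= 0 else -1


def session_choice_table(session: SimulatedSession,
                         apply_screen: bool = True) -> pd.DataFrame:
    """Per-unit signed choice statistics for both relevance conditions.

    For each unit, 0%-signal trials of the stimulus in its hemifield are
    split by relevance condition; counts are stimulus-corrected with a
    per-condition subspace map and converted to signed CP / cc.  Units
    failing the inclusion gates (when ``apply_screen``) are returned with
    ``include=False`` and NaN statistics.
    """
    cfg = session.cfg
    beh = behavior_summary(session)
    choices = session.trials["choice"].to_numpy()
    support = cfg.support
    rows = []
    for u in range(len(session.unit_meta)):
        meta = session.unit_meta.iloc[u]
        pref = int(meta["pref_sign"])
        rel_mask = session.unit_condition_mask(int(meta["unit"]), "relevant")
        condition = np.where(rel_mask, "relevant", "irrelevant")
        counts = session.spike_counts[u]
        sig_own = np.where(session.unit_meta.iloc[u]["side"] == "left",
                           session.trials["signal_left"],
                           session.trials["signal_right"]).astype(float)
        scr = screen_unit(counts, sig_own, choices, condition, pref,
                          cfg.trial_duration_s,
                          beh["performance_highest"], beh["bias_0signal"])
        row = {"unit": int(meta["unit"]), "side": meta["side"],
               "include": scr.include,
               "reasons": ";".join(scr.exclusion_reasons),
               "AI": scr.AI, "dprime": scr.dprime,
               "rate_0signal": scr.mean_rate_0signal,
               "CP_rel": np.nan, "cc_rel": np.nan,
               "CP_irr": np.nan, "cc_irr": np.nan,
               "n_rel": 0, "n_irr": 0}
        keep = scr.trial_mask if apply_screen else np.ones(len(counts), bool)
        if scr.include or not apply_screen:
            frames = session.unit_frames(int(meta["unit"]))
            for cond_name, cond_mask in (("rel", rel_mask),
                                         ("irr", ~rel_mask)):
                m = keep & cond_mask & (sig_own == 0)
                if m.sum() < 10:
                    continue
                H = np.vstack([disparity_histogram(frames[t], support)
                               for t in np.where(m)[0]])
                try:
                    st = unit_choice_stats(counts[m], choices[m], H, pref,
                                           condition=cond_name)
                except ValueError:
                    continue
                row[f"CP_{cond_name}"] = st.CP
                row[f"cc_{cond_name}"] = st.c_choice
                row[f"n_{cond_name}"] = st.n_pref_choice + st.n_null_choice
        rows.append(row)
    return pd.DataFrame(rows)


def architecture_batch(base_cfg, n_sessions: int, seed: int = 0,
                       apply_screen: bool = True) -> pd.DataFrame:
    """Choice tables pooled over independently seeded sessions."""
    from dataclasses import replace
    from vischoice.synth import generate_session
    tables = []
    for s in range(n_sessions):
        cfg = replace(base_cfg, seed=(seed + 104729 * (s + 1)) % (2**31))
        session = generate_session(cfg)
        tab = session_choice_table(session, apply_screen=apply_screen)
        tab.insert(0, "session", s)
        tables.append(tab)
    return pd.concat(tables, ignore_index=True)
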