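"""End-to-end pipeline driver: simulate -> behavior -> screen -> choice
correlations -> pairwise correlations -> encoding -> geometry.

Every stage writes its outputs under a run directory; a JSON summary
collects the headline numbers.  All randomness flows from the single seed
in the configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from vischoice.config import SimConfig
from vischoice.synth import SimulatedSession, generate_session
from vischoice.io import write_bundle, read_bundle
from vischoice.analysis import (behavior_summary, session_choice_table)
from vischoice.behavior import (fit_psychometric, psychophysical_kernel,
                                fit_behavior_glm)
from vischoice.pairs import pair_table, typeII_regress
from vischoice.encoding import (build_design, fit_encoding, cross_validate,
                                drift_fraction)
from vischoice.geometry import population_vectors

log = logging.getLogger("vischoice")

ALL_STAGES = ("behavior", "screen", "choicecorr", "paircorr", "encode",
              "geometry")


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage '{stage}' failed: {err}")
        self.stage = stage


def run_pipeline(cfg: SimConfig, out_dir,
                 stages: Optional[Sequence[str]] = None,
                 bundle: Optional[str] = None,
                 laplacian_weight: float = 1.0,
                 kernel_both_zero: bool = False) -> dict:
    """Run the analysis chain on a simulated session (or existing bundle).

    Returns the JSON-ready summary; per-stage tables are written as TSV
    under ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = tuple(stages) if stages else ALL_STAGES
    summary: dict = {"stages": list(stages),
                     "config": cfg.to_dict() if bundle is None else None}

    if bundle is not None:
        session = read_bundle(bundle)
        cfg = session.cfg
        summary["config"] = cfg.to_dict()
    else:
        session = generate_session(cfg)
        write_bundle(session, out / "bundle")
    choices = session.trials["choice"].to_numpy()

    fits_cache: dict = {}
    for stage in stages:
        try:
            if stage == "behavior":
                summary["behavior"] = _stage_behavior(session, out,
                                                      kernel_both_zero)
            elif stage == "screen":
                tab = session_choice_table(session)
                tab.to_csv(out / "screening.tsv", sep="\t", index=False)
                summary["screen"] = {
                    "n_units": int(len(tab)),
                    "n_included": int(tab["include"].sum()),
                    "mean_AI": float(np.nanmean(
                        tab["AI"].to_numpy(dtype=float))),
                }
            elif stage == "choicecorr":
                tab = session_choice_table(session)
                tab.to_csv(out / "cc.tsv", sep="\t", index=False)
                inc = tab[tab["include"] & tab["cc_rel"].notna()
                          & tab["cc_irr"].notna()]
                summary["choicecorr"] = {
                    "n_units": int(len(inc)),
                    "mean_cc_rel": float(inc["cc_rel"].mean()),
                    "mean_cc_irr": float(inc["cc_irr"].mean()),
                }
            elif stage == "paircorr":
                summary["paircorr"] = _stage_paircorr(session, out)
            elif stage == "encode":
                summary["encode"] = _stage_encode(session, out,
                                                  laplacian_weight,
                                                  fits_cache)
            elif stage == "geometry":
                summary["geometry"] = _stage_geometry(session, out,
                                                      laplacian_weight,
                                                      fits_cache)
        except Exception as err:  # noqa: BLE001 - stage-tagged re-raise
            raise StageError(stage, err) from err

    (out / "summary.json").write_text(json.dumps(summary, indent=1,
                                                 sort_keys=True))
    return summary


def _stage_behavior(session: SimulatedSession, out: Path,
                    kernel_both_zero: bool = False) -> dict:
    sig_rel = session.signed_signal("relevant")
    sig_irr = session.signed_signal("irrelevant")
    choices = session.trials["choice"].to_numpy()
    psy = fit_psychometric(sig_rel, choices)
    glm = fit_behavior_glm(sig_rel, sig_irr, choices)
    res = {"psychometric": {"mu": psy.mu, "sigma": psy.sigma,
                            "degenerate": psy.degenerate},
           "glm": {"beta0": glm.beta0, "beta1": glm.beta1,
                   "beta2": glm.beta2, "beta3": glm.beta3,
                   "alpha": glm.alpha},
           **behavior_summary(session)}
    cfg = session.cfg
    kernels = {}
    for side_label in ("relevant", "irrelevant"):
        sig_side = session.signed_signal(side_label)
        m = sig_side == 0
        if kernel_both_zero:
            # stricter variant: both stimuli at 0% signal
            other = ("irrelevant" if side_label == "relevant"
                     else "relevant")
            m = m & (session.signed_signal(other) == 0)
        frames = _frames_by_label(session, side_label)[m]
        try:
            k = psychophysical_kernel(frames, choices[m], cfg.support,
                                      cfg.trial_duration_s * 1000.0)
            df = pd.DataFrame(k.values, index=cfg.support)
            df.to_csv(out / f"kernel_{side_label}.tsv", sep="\t")
            kernels[side_label] = float(np.abs(k.values).max())
        except ValueError as err:
            kernels[side_label] = None
            log.warning("kernel %s: %s", side_label, err)
    res["kernel_peak_abs"] = kernels
    return res


def _frames_by_label(session: SimulatedSession, label: str) -> np.ndarray:
    rel_left = (session.trials["relevant_side"] == "left").to_numpy()
    pick_left = rel_left if label == "relevant" else ~rel_left
    out = np.where(pick_left[:, None], session.frames["left"],
                   session.frames["right"])
    return out


def _stage_paircorr(session: SimulatedSession, out: Path) -> dict:
    # conditions for noise correlations: identical stimuli only exist with
    # frozen noise; otherwise fall back to signal level as the condition
    cfg = session.cfg
    sig_l = session.trials["signal_left"].astype(float)
    sig_r = session.trials["signal_right"].astype(float)
    condition = (sig_l.astype(str) + "/" + sig_r.astype(str)).to_numpy()
    levels = np.unique(np.concatenate([sig_l, sig_r]))
    tuning = np.vstack([
        [session.spike_counts[u][_own_signal(session, u) == lev].mean()
         if (_own_signal(session, u) == lev).any() else np.nan
         for lev in levels]
        for u in range(len(session.unit_meta))])
    tab = pair_table(session.spike_counts, condition, tuning,
                     session.unit_meta)
    tab.to_csv(out / "pairs.tsv", sep="\t", index=False)
    res = {"n_pairs": int(len(tab))}
    for scope, m in (("within", tab.get("same_hemisphere")),
                     ("across", None)):
        if len(tab) == 0:
            continue
        sub = tab[tab["same_hemisphere"]] if scope == "within" \
            else tab[~tab["same_hemisphere"]]
        if len(sub) >= 10:
            fit = typeII_regress(sub["signal_r"], sub["noise_r"])
            res[scope] = {"slope": fit.slope, "ci": list(fit.ci_slope),
                          "n": fit.n_pairs}
    return res


def _own_signal(session: SimulatedSession, u: int) -> np.ndarray:
    side = session.unit_meta.iloc[u]["side"]
    return session.trials[f"signal_{side}"].to_numpy(dtype=float)


def _fit_all_units(session: SimulatedSession, laplacian_weight: float,
                   fits_cache: dict) -> list:
    if "fits" in fits_cache:
        return fits_cache["fits"]
    fits = []
    for u in range(len(session.unit_meta)):
        design = build_design(session, u)
        fit = fit_encoding(design, session.spike_counts[u], laplacian_weight)
        fit.drift_frac = drift_fraction(fit, design)
        fits.append((fit, design))
    fits_cache["fits"] = fits
    return fits


def _stage_encode(session: SimulatedSession, out: Path,
                  laplacian_weight: float, fits_cache: dict) -> dict:
    pairs = _fit_all_units(session, laplacian_weight, fits_cache)
    fits = []
    for u, (fit, design) in enumerate(pairs):
        if fit.cv_r2 is None:
            fit.cv_r2 = cross_validate(design, session.spike_counts[u],
                                       laplacian_weight)
        fits.append(fit)
    recs = [{"unit": u, "w_r": f.w_r, "w_i": f.w_i,
             "cv_r2": f.cv_r2, "drift_frac": f.drift_frac,
             "converged": f.converged,
             "f_r": f.f_r.tolist(), "f_i": f.f_i.tolist(),
             "d_j": f.d_j.tolist(),
             "support": f.support.tolist()}
            for u, f in enumerate(fits)]
    (out / "fits.json").write_text(json.dumps(recs, indent=1))
    return {"mean_cv_r2": float(np.nanmean([f.cv_r2 for f in fits])),
            "n_converged": int(sum(f.converged for f in fits))}


def _stage_geometry(session: SimulatedSession, out: Path,
                    laplacian_weight: float, fits_cache: dict) -> dict:
    cfg = session.cfg
    pairs = _fit_all_units(session, laplacian_weight, fits_cache)
    fits = [f for f, _ in pairs]
    fracs = [f.drift_frac for f in fits]
    pv = population_vectors(fits, cfg.near_signal, cfg.far_signal,
                            n_resamples=200, drift_fracs=fracs)
    rows = [{"pair": f"{a}-{b}", "theta_deg": pv.angles[(a, b)],
             "ci_lo": pv.ci90[(a, b)][0], "ci_hi": pv.ci90[(a, b)][1]}
            for (a, b) in pv.angles]
    pd.DataFrame(rows).to_csv(out / "angles.tsv", sep="\t", index=False)
    return {f"{a}-{b}": pv.angles[(a, b)] for (a, b) in pv.angles}
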