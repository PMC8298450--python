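"""Behavioral analyses: psychometric fit, reverse correlation, choice GLM.

These establish the behavioral prerequisites of the neural analyses — in
particular that choices are driven by the task-relevant stimulus only, so
that choice correlations for the irrelevant stimulus cannot be inherited
from the behavior itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.stats import norm

__all__ = [
    "PsychometricFit", "KernelMatrix", "BehavioralGLMFit",
    "fit_psychometric", "psychophysical_kernel", "aggregate_kernels",
    "fit_behavior_glm",
]


@dataclass
class PsychometricFit:
    """Cumulative-Gaussian fit of proportion-far vs signed % signal.

    ``mu`` is the bias and ``sigma`` the psychophysical threshold (mean and
    SD of the fitted cumulative Gaussian).
    """

    mu: float
    sigma: float
    levels: np.ndarray
    prop_far: np.ndarray
    n_trials: np.ndarray
    converged: bool = True
    degenerate: bool = False

    def predict(self, signal: np.ndarray) -> np.ndarray:
        return norm.cdf((np.asarray(signal, dtype=float) - self.mu)
                        / self.sigma)


def fit_psychometric(signed_signal: np.ndarray,
                     choices: np.ndarray) -> PsychometricFit:
    """Maximum-likelihood cumulative-Gaussian psychometric fit.

    Choices are coded -1 (near) / +1 (far).  Levels enter the binomial
    likelihood with their observed trial counts, which weights the fit by
    trials per level.  A responder who (almost) always gives the same
    answer produces perfect separation; the fit is then flagged degenerate
    and parameters come from a bounded fallback.
    """
    s = np.asarray(signed_signal, dtype=float)
    c = np.asarray(choices)
    if set(np.unique(c)) - {-1, 1}:
        raise ValueError("choices must be coded -1/+1")
    levels, inv = np.unique(s, return_inverse=True)
    if len(levels) < 2:
        raise ValueError("need >= 2 distinct signal levels")
    n = np.bincount(inv, minlength=len(levels)).astype(float)
    k_far = np.bincount(inv, weights=(c == 1), minlength=len(levels))
    prop = k_far / n
    degenerate = len(np.unique(c)) < 2

    span = levels.max() - levels.min()
    bounds = [(levels.min() - span, levels.max() + span),
              (span * 1e-3, span * 10)]

    def nll(theta):
        mu, sigma = theta
        p = norm.cdf((levels - mu) / sigma)
        p = np.clip(p, 1e-9, 1 - 1e-9)
        return -(k_far * np.log(p) + (n - k_far) * np.log1p(-p)).sum()

    x0 = np.array([0.0, max(span / 4.0, 1e-3)])
    res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
    mu, sigma = res.x
    at_bound = (np.isclose(sigma, bounds[1][0]) or
                np.isclose(sigma, bounds[1][1]))
    return PsychometricFit(mu=float(mu), sigma=float(sigma), levels=levels,
                           prop_far=prop, n_trials=n,
                           converged=bool(res.success),
                           degenerate=bool(degenerate or at_bound))


@dataclass
class KernelMatrix:
    """Psychophysical kernel: disparities x time-bins.

    Entries are the difference in mean proportion-of-frames matrices
    between near-choice and far-choice 0%-signal trials, in proportion of
    frames per 500 ms bin.
    """

    values: np.ndarray
    support: np.ndarray
    bin_edges_ms: np.ndarray
    n_trials: int


def _frame_proportion_matrix(frames: np.ndarray, support: np.ndarray,
                             n_bins: int = 4) -> np.ndarray:
    """(n_trials, k, n_bins) proportion of frames per disparity and bin."""
    from vischoice.synth import disparity_histogram
    frames = np.asarray(frames, dtype=float)
    n_trials, n_frames = frames.shape
    out = np.empty((n_trials, len(support), n_bins))
    splits = np.array_split(np.arange(n_frames), n_bins)
    for b, idx in enumerate(splits):
        for t in range(n_trials):
            out[t, :, b] = (disparity_histogram(frames[t, idx], support)
                            / len(idx))
    return out


def psychophysical_kernel(frames: np.ndarray, choices: np.ndarray,
                          support: np.ndarray, trial_duration_ms: float,
                          n_bins: int = 4,
                          min_per_choice: int = 5) -> KernelMatrix:
    """Choice-triggered stimulus average on 0%-signal trials.

    For each of ``n_bins`` consecutive equal time bins, the kernel is the
    mean frame-proportion matrix over near-choice trials minus over
    far-choice trials.  Callers are responsible for restricting the input
    to 0%-signal trials on the analyzed stimulus.
    """
    choices = np.asarray(choices)
    for label, sign in (("near", -1), ("far", 1)):
        if (choices == sign).sum() < min_per_choice:
            raise ValueError(
                f"need >= {min_per_choice} {label}-choice trials, got "
                f"{(choices == sign).sum()}")
    mats = _frame_proportion_matrix(frames, support, n_bins)
    kernel = (mats[choices == -1].mean(axis=0)
              - mats[choices == 1].mean(axis=0))
    edges = np.linspace(0, trial_duration_ms, n_bins + 1)
    return KernelMatrix(values=kernel, support=np.asarray(support),
                        bin_edges_ms=edges, n_trials=len(choices))


def aggregate_kernels(kernels: Sequence[KernelMatrix]) -> KernelMatrix:
    """Session average weighted by trials per session."""
    if not kernels:
        raise ValueError("no kernels to aggregate")
    w = np.array([k.n_trials for k in kernels], dtype=float)
    vals = np.average(np.stack([k.values for k in kernels]), axis=0,
                      weights=w)
    k0 = kernels[0]
    return KernelMatrix(values=vals, support=k0.support,
                        bin_edges_ms=k0.bin_edges_ms, n_trials=int(w.sum()))


@dataclass
class BehavioralGLMFit:
    """Probit choice GLM on z-scored covariates with lasso regularization.

    Covariates: relevant signal, irrelevant signal and their interaction;
    coefficients are on the z-scored scale so they are directly
    comparable.
    """

    beta0: float
    beta1: float
    beta2: float
    beta3: float
    alpha: float                       # selected lasso penalty
    alpha_path: np.ndarray = field(default_factory=lambda: np.empty(0))
    cv_deviance: np.ndarray = field(default_factory=lambda: np.empty(0))
    covariate_means: np.ndarray = field(default_factory=lambda: np.empty(0))
    covariate_sds: np.ndarray = field(default_factory=lambda: np.empty(0))
    dropped: tuple = ()

    @property
    def coef(self) -> np.ndarray:
        return np.array([self.beta0, self.beta1, self.beta2, self.beta3])


def _probit_deviance(y, X, params):
    eta = X @ params
    p = np.clip(norm.cdf(eta), 1e-9, 1 - 1e-9)
    return -2.0 * (y * np.log(p) + (1 - y) * np.log1p(-p)).sum()


def fit_behavior_glm(s_rel: np.ndarray, s_irrel: np.ndarray,
                     choices: np.ndarray,
                     alphas: Optional[np.ndarray] = None,
                     n_folds: int = 10,
                     seed: int = 0) -> BehavioralGLMFit:
    """Probit GLM P(far) = Phi(b0 + b1 s_rel + b2 s_irr + b3 s_rel s_irr).

    Covariates are z-scored, the lasso penalty is chosen by ``n_folds``-fold
    cross-validated deviance (minimum-deviance rule), and the final fit
    uses all trials at the selected penalty.  Constant covariates are
    dropped with a warning and their coefficient reported as 0.
    """
    s_rel = np.asarray(s_rel, dtype=float)
    s_irrel = np.asarray(s_irrel, dtype=float)
    y = (np.asarray(choices) == 1).astype(float)
    raw = np.column_stack([s_rel, s_irrel, s_rel * s_irrel])
    means = raw.mean(axis=0)
    sds = raw.std(axis=0)
    dropped = tuple(i for i in range(3) if sds[i] == 0)
    for i in dropped:
        warnings.warn(f"covariate {i} is constant; dropped from the GLM")
    keep = [i for i in range(3) if i not in dropped]
    sds_safe = np.where(sds == 0, 1.0, sds)
    Z = (raw - means) / sds_safe
    X = sm.add_constant(Z[:, keep], has_constant="add")

    if alphas is None:
        alphas = np.concatenate([[0.0], np.logspace(-4, -0.5, 8)])
    alphas = np.asarray(alphas, dtype=float)

    rng = np.random.default_rng(seed)
    n = len(y)
    order = rng.permutation(n)
    folds = np.array_split(order, n_folds)
    cv_dev = np.zeros(len(alphas))
    for a_i, a in enumerate(alphas):
        for fold in folds:
            mask = np.ones(n, dtype=bool)
            mask[fold] = False
            try:
                params = _fit_probit_lasso(y[mask], X[mask], a)
                cv_dev[a_i] += _probit_deviance(y[fold], X[fold], params)
            except Exception:  # separation / bracketing failures at this a
                cv_dev[a_i] += np.inf
    best = int(np.argmin(cv_dev))
    try:
        params = _fit_probit_lasso(y, X, alphas[best])
    except Exception:
        params = _fit_probit_lasso(y, X, 0.0)
        best = 0

    betas = np.zeros(4)
    betas[0] = params[0]
    for j, i in enumerate(keep):
        betas[i + 1] = params[j + 1]
    return BehavioralGLMFit(beta0=float(betas[0]), beta1=float(betas[1]),
                            beta2=float(betas[2]), beta3=float(betas[3]),
                            alpha=float(alphas[best]), alpha_path=alphas,
                            cv_deviance=cv_dev, covariate_means=means,
                            covariate_sds=sds, dropped=dropped)


def _fit_probit_lasso(y: np.ndarray, X: np.ndarray,
                      alpha: float) -> np.ndarray:
    """Probit fit with an L1 penalty (intercept unpenalized)."""
    model = sm.GLM(y, X, family=sm.families.Binomial(
        link=sm.families.links.Probit()))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if alpha <= 0:
            return np.asarray(model.fit(maxiter=200).params)
        pen = np.ones(X.shape[1]) * alpha
        pen[0] = 0.0
        res = model.fit_regularized(alpha=pen, L1_wt=1.0, maxiter=400)
    return np.asarray(res.params)
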