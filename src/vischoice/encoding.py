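"""Per-unit linear encoding model separating stimulus, choice and drift.

The model predicts the whole-trial spike count from (identity link)::

    R(t) = sum_x f_r(x) n_t_r(x) + sum_x f_i(x) n_t_i(x)
           + w_r c_t_r + w_i c_t_i + d(t),      d(t) = sum_j d_j xi_j(t)

where ``n_t_r`` / ``n_t_i`` are frames-per-disparity histograms of the
stimulus in the unit's receptive field routed by that trial's relevance
(the inactive block is all-zero), ``c_t_r`` / ``c_t_i`` are the choice
(-1 near / +1 far) routed likewise, and ``d(t)`` is a slow drift built
from a tent (piecewise-linear) basis with one anchor per
relevant+irrelevant block cycle plus clamped boundary anchors.  All terms
are fit simultaneously by gradient descent on the mean-squared error with
a Laplacian (second-difference) smoothness penalty on the tuning weights
only, so the model can attribute variance to stimulus, choice and drift
even though they are correlated across trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from vischoice.synth import SimulatedSession, disparity_histogram

__all__ = [
    "EncodingDesign", "EncodingFit", "tent_basis", "build_design",
    "fit_encoding", "cross_validate", "drift_fraction",
]


@dataclass
class EncodingDesign:
    """Design matrix blocks for one unit.

    ``X`` columns: k relevant-histogram entries, k irrelevant-histogram
    entries, c_r, c_i, then one column per drift anchor.
    """

    X: np.ndarray
    support: np.ndarray
    n_anchors: int
    anchor_trials: np.ndarray
    k: int

    @property
    def slices(self) -> dict:
        k = self.k
        return {"f_r": slice(0, k), "f_i": slice(k, 2 * k),
                "w_r": 2 * k, "w_i": 2 * k + 1,
                "d": slice(2 * k + 2, 2 * k + 2 + self.n_anchors)}


@dataclass
class EncodingFit:
    f_r: np.ndarray
    f_i: np.ndarray
    w_r: float
    w_i: float
    d_j: np.ndarray
    support: np.ndarray
    laplacian_weight: float
    converged: bool
    n_iter: int
    mse: float
    cv_r2: Optional[float] = None
    drift_frac: Optional[float] = None

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([self.f_r, self.f_i,
                               [self.w_r, self.w_i], self.d_j])

    def predict(self, design: EncodingDesign) -> np.ndarray:
        return design.X @ self.params


def tent_basis(trial_index: np.ndarray,
               anchor_trials: np.ndarray) -> np.ndarray:
    """Piecewise-linear (tent) basis values, (n_trials, n_anchors).

    Each basis function is 1 at its anchor, descends linearly to 0 at the
    neighbouring anchors, and is 0 elsewhere; between the first and last
    anchor the functions sum to 1, so the drift term linearly interpolates
    the anchor offsets.
    """
    t = np.asarray(trial_index, dtype=float)
    a = np.asarray(anchor_trials, dtype=float)
    if np.any(np.diff(a) <= 0):
        raise ValueError("anchor trials must be strictly increasing")
    B = np.zeros((len(t), len(a)))
    for j in range(len(a)):
        left = a[j - 1] if j > 0 else a[j]
        right = a[j + 1] if j < len(a) - 1 else a[j]
        up = (t - left) / (a[j] - left) if a[j] > left else (t >= a[j]) * 1.0
        down = (right - t) / (right - a[j]) if right > a[j] \
            else (t <= a[j]) * 1.0
        B[:, j] = np.clip(np.minimum(up, down), 0.0, 1.0)
    return B


def anchor_points(trials_cycle: np.ndarray,
                  trial_index: np.ndarray) -> np.ndarray:
    """One anchor at the centre of each block cycle, plus boundary anchors
    clamped to the first and last trial so d(t) is defined everywhere."""
    cycles = np.unique(trials_cycle)
    centers = np.array([trial_index[trials_cycle == c].mean()
                        for c in cycles])
    first, last = trial_index.min(), trial_index.max()
    anchors = centers
    if anchors[0] > first:
        anchors = np.concatenate([[first], anchors])
    if anchors[-1] < last:
        anchors = np.concatenate([anchors, [last]])
    return anchors.astype(float)


def build_design(session: SimulatedSession, unit: int) -> EncodingDesign:
    """Assemble the design matrix for one unit of a simulated session."""
    cfg = session.cfg
    support = cfg.support
    k = len(support)
    frames = session.unit_frames(unit)
    n_trials = session.n_trials
    rel_mask = session.unit_condition_mask(unit, "relevant")
    choices = session.trials["choice"].to_numpy().astype(float)
    H = np.vstack([disparity_histogram(frames[t], support)
                   for t in range(n_trials)])
    t_idx = session.trials["trial"].to_numpy().astype(float)
    anchors = anchor_points(session.trials["cycle"].to_numpy(), t_idx)
    B = tent_basis(t_idx, anchors)
    X = np.zeros((n_trials, 2 * k + 2 + len(anchors)))
    X[rel_mask, :k] = H[rel_mask]
    X[~rel_mask, k:2 * k] = H[~rel_mask]
    X[rel_mask, 2 * k] = choices[rel_mask]
    X[~rel_mask, 2 * k + 1] = choices[~rel_mask]
    X[:, 2 * k + 2:] = B
    return EncodingDesign(X=X, support=support, n_anchors=len(anchors),
                          anchor_trials=anchors, k=k)


def _penalty_matrix(design: EncodingDesign) -> np.ndarray:
    """Quadratic-penalty matrix for the Laplacian of f_r and f_i only."""
    k = design.k
    p = design.X.shape[1]
    D = np.zeros((0, p))
    if k >= 3:
        d2 = np.zeros((k - 2, k))
        for i in range(k - 2):
            d2[i, i:i + 3] = [1.0, -2.0, 1.0]
        rows = np.zeros((2 * (k - 2), p))
        rows[:k - 2, :k] = d2
        rows[k - 2:, k:2 * k] = d2
        D = rows
    return D.T @ D


def fit_encoding(design: EncodingDesign, counts: np.ndarray,
                 laplacian_weight: float = 1.0,
                 tol: float = 1e-13, max_iter: int = 100_000) -> EncodingFit:
    """Fit all model terms simultaneously by gradient descent.

    Minimizes ``mean((X p - y)^2) + laplacian_weight * ||D2 f||^2`` by
    conjugate-gradient descent on the (convex quadratic) objective from a
    deterministic zero initialization, so the fit is reproducible and
    terminates in at most ``dim(p)`` iterations up to round-off.
    Convergence: gradient norm below ``tol`` relative to the data term;
    hitting the iteration cap flags the fit.  The design has one exact
    degeneracy (a common shift of all tuning weights traded against the
    drift offsets); starting at zero keeps the solution in the row space
    of the design, matching the minimum-norm least-squares solution as the
    penalty goes to zero.
    """
    y = np.asarray(counts, dtype=float)
    X = design.X
    n = len(y)
    G = X.T @ X / n
    Xty = X.T @ y / n
    P = _penalty_matrix(design)
    A = G + laplacian_weight * P
    const = y @ y / n

    def objective(p):
        return p @ (A @ p) - 2.0 * (Xty @ p) + const

    # CG on the normal equations A p = Xty (restarted every dim(p) steps
    # to shed round-off); b is in range(A), so the zero start converges to
    # the minimum-norm solution even when A is singular.
    p = np.zeros(X.shape[1])
    b = Xty
    bnorm = max(np.linalg.norm(b), 1e-30)
    r = b - A @ p
    d = r.copy()
    rr = r @ r
    converged = np.sqrt(rr) / bnorm < tol
    it = 0
    dim = len(p)
    while not converged and it < max_iter:
        it += 1
        Ad = A @ d
        dAd = d @ Ad
        if dAd <= 0:
            break
        alpha = rr / dAd
        p = p + alpha * d
        r = r - alpha * Ad
        new_rr = r @ r
        if np.sqrt(new_rr) / bnorm < tol:
            converged = True
            break
        if it % dim == 0:
            r = b - A @ p
            new_rr = r @ r
            d = r.copy()
        else:
            d = r + (new_rr / rr) * d
        rr = new_rr
    obj = objective(p)
    sl = design.slices
    return EncodingFit(f_r=p[sl["f_r"]].copy(), f_i=p[sl["f_i"]].copy(),
                       w_r=float(p[sl["w_r"]]), w_i=float(p[sl["w_i"]]),
                       d_j=p[sl["d"]].copy(), support=design.support,
                       laplacian_weight=laplacian_weight,
                       converged=converged, n_iter=it, mse=float(obj))


def cross_validate(design: EncodingDesign, counts: np.ndarray,
                   laplacian_weight: float = 1.0,
                   n_folds: int = 5) -> float:
    """Held-out variance explained, contiguous-in-time folds.

    Folds are consecutive trial blocks so the drift term cannot leak
    across the train/test split.  Returns pooled R^2 over held-out trials
    (1 - SSE/SST around the training means).
    """
    y = np.asarray(counts, dtype=float)
    n = len(y)
    edges = np.linspace(0, n, n_folds + 1).astype(int)
    sl = design.slices
    t_all = np.arange(n, dtype=float)
    sse, sst = 0.0, 0.0
    for f in range(n_folds):
        test = np.zeros(n, dtype=bool)
        test[edges[f]:edges[f + 1]] = True
        sub = EncodingDesign(X=design.X[~test], support=design.support,
                             n_anchors=design.n_anchors,
                             anchor_trials=design.anchor_trials, k=design.k)
        fit = fit_encoding(sub, y[~test], laplacian_weight)
        # drift anchors inside the held-out block are unconstrained by the
        # training rows; carry the drift into the block by interpolating
        # the fitted drift trace over trial index instead
        params_nd = fit.params.copy()
        params_nd[sl["d"]] = 0.0
        drift_train = design.X[~test][:, sl["d"]] @ fit.d_j
        drift_test = np.interp(t_all[test], t_all[~test], drift_train)
        pred = design.X[test] @ params_nd + drift_test
        sse += ((y[test] - pred) ** 2).sum()
        sst += ((y[test] - y[~test].mean()) ** 2).sum()
    return float(1.0 - sse / sst) if sst > 0 else np.nan


def select_laplacian_weight(design: EncodingDesign, counts: np.ndarray,
                            grid: tuple = (0.03, 0.3, 3.0, 30.0),
                            n_folds: int = 5) -> float:
    """Smoothness penalty maximizing 5-fold held-out variance explained."""
    scores = [cross_validate(design, counts, lam, n_folds) for lam in grid]
    return float(grid[int(np.argmax(scores))])


def drift_fraction(fit: EncodingFit, design: EncodingDesign) -> float:
    """Fraction of model-prediction variance carried by the drift term.

    var(d(t)) / var(R(t)) across trials; units above 0.5 are excluded from
    the population-geometry analysis.  Undefined (raises) when the full
    prediction has zero variance.
    """
    sl = design.slices
    drift = design.X[:, sl["d"]] @ fit.d_j
    full = fit.predict(design)
    v_full = full.var()
    if v_full == 0:
        raise ValueError("zero prediction variance: drift fraction undefined")
    return float(drift.var() / v_full)
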