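"""Encoding model: tent basis, design assembly, fitting, CV, drift."""

import numpy as np
import pytest

from vischoice.config import SimConfig
from vischoice.synth import generate_session
from vischoice.encoding import (tent_basis, anchor_points, build_design,
                                fit_encoding, cross_validate,
                                drift_fraction, EncodingDesign)


class TestTentBasis:
    def test_anchor_identity(self):
        B = tent_basis(np.array([10.0]), np.array([0.0, 10.0, 20.0]))
        assert np.allclose(B, [[0, 1, 0]])

    def test_midpoint_interpolation(self):
        B = tent_basis(np.array([15.0]), np.array([0.0, 10.0, 20.0]))
        assert np.allclose(B, [[0, 0.5, 0.5]])

    def test_partition_of_unity_between_anchors(self):
        t = np.linspace(0, 30, 121)
        B = tent_basis(t, np.array([0.0, 12.0, 19.0, 30.0]))
        assert np.allclose(B.sum(axis=1), 1.0)

    def test_four_cycle_session_anchor_layout(self):
        cfg = SimConfig(n_block_cycles=4, n_units_per_side=1,
                        trials_per_block=47)
        s = generate_session(cfg)
        a = anchor_points(s.trials["cycle"].to_numpy(),
                          s.trials["trial"].to_numpy().astype(float))
        # 4 cycle-center anchors plus 2 clamped boundary anchors
        assert len(a) == 6
        assert a[0] == 0.0 and a[-1] == s.n_trials - 1
        # interior anchor spacing = one relevant+irrelevant period
        assert np.allclose(np.diff(a[1:-1]), 2 * 47)


class TestDesign:
    def test_exclusive_blocks(self, small_session):
        design = build_design(small_session, 0)
        k = design.k
        rel = design.X[:, :k].sum(axis=1)
        irr = design.X[:, k:2 * k].sum(axis=1)
        frames = small_session.cfg.frames_per_trial
        # exactly one histogram block active per trial, summing to frames
        assert np.all((rel == frames) ^ (irr == frames))
        assert np.all((rel == 0) | (irr == 0))
        c_r = design.X[:, 2 * k]
        c_i = design.X[:, 2 * k + 1]
        assert np.all((c_r == 0) | (c_i == 0))
        assert np.all(np.abs(c_r + c_i) == 1)


class TestFitting:
    def _design_with_truth(self, seed=0, n_cycles=3, tpb=60):
        cfg = SimConfig(n_block_cycles=n_cycles, trials_per_block=tpb,
                        n_units_per_side=1, seed=seed)
        sess = generate_session(cfg)
        design = build_design(sess, 0)
        k = design.k
        support = design.support
        f_r = 0.30 + 0.25 * support            # smooth tuning, spikes/frame
        f_i = 0.28 + 0.18 * support
        w_r, w_i = 3.0, 2.0
        rng = np.random.default_rng(seed + 1)
        d_j = rng.normal(0, 2.0, design.n_anchors)
        p_true = np.concatenate([f_r, f_i, [w_r, w_i], d_j])
        return design, p_true

    def test_noiseless_recovery_matches_least_squares(self):
        design, p_true = self._design_with_truth()
        y = design.X @ p_true
        fit = fit_encoding(design, y, laplacian_weight=0.0)
        assert fit.converged
        # predictions exact; parameters agree with the minimum-norm
        # least-squares oracle (the design has one null direction, so raw
        # parameters are compared against lstsq, not p_true)
        assert np.allclose(fit.predict(design), y, atol=1e-6)
        ls, *_ = np.linalg.lstsq(design.X, y, rcond=None)
        assert np.allclose(fit.params, ls, atol=1e-6)
        # choice weights are identified despite the degeneracy
        assert fit.w_r == pytest.approx(3.0, abs=1e-6)
        assert fit.w_i == pytest.approx(2.0, abs=1e-6)

    def test_penalty_zero_equals_ols_on_noisy_data(self, rng):
        design, p_true = self._design_with_truth(seed=2)
        y = rng.poisson(np.maximum(design.X @ p_true, 0.1)).astype(float)
        fit = fit_encoding(design, y, laplacian_weight=0.0)
        ls, *_ = np.linalg.lstsq(design.X, y, rcond=None)
        assert np.allclose(design.X @ fit.params, design.X @ ls, atol=1e-6)

    def test_constant_count_shift_moves_only_offset_terms(self, rng):
        design, p_true = self._design_with_truth(seed=3)
        y = rng.poisson(np.maximum(design.X @ p_true, 0.1)).astype(float)
        f0 = fit_encoding(design, y, laplacian_weight=0.5)
        f1 = fit_encoding(design, y + 50.0, laplacian_weight=0.5)
        # choice weights unchanged; tuning changes only by a constant
        # offset (absorbed jointly with the drift anchors)
        assert f1.w_r == pytest.approx(f0.w_r, abs=1e-4)
        assert f1.w_i == pytest.approx(f0.w_i, abs=1e-4)
        d_fr = f1.f_r - f0.f_r
        d_fi = f1.f_i - f0.f_i
        assert np.ptp(d_fr) < 1e-4
        assert np.ptp(d_fi) < 1e-4

    def test_roughness_decreases_with_penalty(self, rng):
        design, p_true = self._design_with_truth(seed=4)
        y = rng.poisson(np.maximum(design.X @ p_true, 0.1)).astype(float)

        def rough(fit):
            return (np.diff(fit.f_r, 2) ** 2).sum() \
                + (np.diff(fit.f_i, 2) ** 2).sum()

        r = [rough(fit_encoding(design, y, lam))
             for lam in (0.0, 0.1, 1.0, 10.0, 100.0)]
        assert all(a >= b - 1e-12 for a, b in zip(r, r[1:]))

    def test_choice_weight_recovery_under_stimulus_choice_correlation(self):
        # the core separation claim: with choices strongly correlated with
        # the stimulus, the jointly fit model still attributes the right
        # weight to choice
        cfg = SimConfig(n_block_cycles=5, trials_per_block=200,
                        n_units_per_side=1, seed=8, decision_noise_sd=11.0)
        sess = generate_session(cfg)
        design = build_design(sess, 0)
        support = design.support
        f_r = 0.35 + 0.30 * support
        f_i = 0.35 + 0.30 * support
        w_r, w_i = 4.0, 4.0
        d_j = np.linspace(-2, 2, design.n_anchors)
        p_true = np.concatenate([f_r, f_i, [w_r, w_i], d_j])
        rng = np.random.default_rng(9)
        y = rng.poisson(np.maximum(design.X @ p_true, 0.1)).astype(float)
        # confirm the stimulus-choice correlation is substantial
        sig = sess.signed_signal("relevant")
        r_sc = np.corrcoef(sig, sess.trials["choice"])[0, 1]
        assert 0.35 < abs(r_sc) < 0.65
        fit = fit_encoding(design, y, laplacian_weight=0.1)
        assert fit.w_r == pytest.approx(w_r, rel=0.10)
        assert fit.w_i == pytest.approx(w_i, rel=0.10)


class TestCVAndDrift:
    def test_pure_noise_unit_has_zero_cv(self, rng):
        # held-out R^2 of a pure-noise unit is zero up to the usual
        # -p/n fitting bias, so use enough trials to make that small
        cfg = SimConfig(n_block_cycles=4, trials_per_block=150,
                        n_units_per_side=1, seed=12)
        sess = generate_session(cfg)
        design = build_design(sess, 0)
        y = rng.poisson(30, size=sess.n_trials).astype(float)
        assert abs(cross_validate(design, y, 1.0)) < 0.05

    def test_noiseless_unit_has_unit_cv(self):
        cfg = SimConfig(n_block_cycles=3, trials_per_block=60,
                        n_units_per_side=1, seed=13)
        sess = generate_session(cfg)
        design = build_design(sess, 0)
        k = design.k
        p = np.concatenate([0.3 + 0.3 * design.support,
                            0.3 + 0.3 * design.support,
                            [3.0, 3.0], np.zeros(design.n_anchors)])
        y = design.X @ p
        assert cross_validate(design, y, 0.0) > 0.99

    def test_known_signal_fraction(self):
        # Poisson unit whose explainable variance fraction is known by
        # construction: cv_r2 matches it
        cfg = SimConfig(n_block_cycles=4, trials_per_block=150,
                        n_units_per_side=1, seed=14)
        sess = generate_session(cfg)
        design = build_design(sess, 0)
        k = design.k
        p_true = np.concatenate([0.2 + 0.6 * design.support,
                                 0.2 + 0.6 * design.support,
                                 [5.0, 5.0], np.zeros(design.n_anchors)])
        mu = np.maximum(design.X @ p_true, 0.1)
        rng = np.random.default_rng(15)
        y = rng.poisson(mu).astype(float)
        frac = mu.var() / (mu.var() + mu.mean())
        cv = cross_validate(design, y, 0.1)
        assert cv == pytest.approx(frac, abs=0.05)

    def test_drift_fraction_extremes_and_half(self):
        cfg = SimConfig(n_block_cycles=3, trials_per_block=60,
                        n_units_per_side=1, seed=16)
        sess = generate_session(cfg)
        design = build_design(sess, 0)
        k = design.k
        n_a = design.n_anchors

        def make_fit(f_scale, d_vec):
            p = np.concatenate([np.full(k, f_scale), np.full(k, f_scale),
                                [2.0 * f_scale, 2.0 * f_scale], d_vec])
            fit = fit_encoding(design, design.X @ p, laplacian_weight=0.0)
            return fit

        # constant drift offsets: zero drift variance
        fit = make_fit(0.4, np.full(n_a, 7.0))
        assert drift_fraction(fit, design) == pytest.approx(0.0, abs=1e-6)
        # drift-only unit
        p = np.concatenate([np.zeros(2 * k + 2),
                            np.linspace(-5, 5, n_a)])
        fit_d = fit_encoding(design, design.X @ p, laplacian_weight=0.0)
        assert drift_fraction(fit_d, design) > 0.95

    def test_mixed_equal_variance_construction(self):
        # two orthogonal components with equal variance give fraction 1/2
        n = 200
        X = np.zeros((n, 4))
        X[:, 0] = np.tile([1.0, -1.0], n // 2)       # "stimulus"
        X[:, 2] = 0.0
        anchors = np.array([0.0, n - 1.0])
        from vischoice.encoding import tent_basis
        B = tent_basis(np.arange(n, dtype=float), anchors)
        Xfull = np.column_stack([X[:, :1], np.zeros((n, 1)),
                                 np.zeros((n, 2)), B])
        design = EncodingDesign(X=Xfull, support=np.array([0.0]),
                                n_anchors=2, anchor_trials=anchors, k=1)
        # drift ramps -a..a with the same variance as the +-1 component
        t = np.linspace(-1, 1, n)
        a = 1.0 / t.std()
        p = np.concatenate([[1.0], [0.0], [0.0, 0.0], [-a, a]])
        y = design.X @ p
        fit = fit_encoding(design, y, laplacian_weight=0.0)
        assert drift_fraction(fit, design) == pytest.approx(0.5, abs=0.01)
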