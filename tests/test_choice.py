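"""Choice-probability / choice-correlation machinery and its oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vischoice.choice import (subspace_map, stimulus_correct,
                              choice_probability, cp_to_cc, cc_to_cp,
                              timecourse_cc, SubspaceMap)


def auroc_exhaustive(pos, neg):
    """Independent oracle: exhaustive pair counting with ties as 1/2."""
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / (len(pos) * len(neg))


class TestConversion:
    @pytest.mark.parametrize("c,cp2", [(0.11, 0.55), (0.07, 0.53),
                                       (0.09, 0.54)])
    def test_printed_pairings(self, c, cp2):
        # mean choice correlations and the aROCs they correspond to
        assert round(cc_to_cp(c), 2) == cp2

    @pytest.mark.parametrize("c,cp", [(0.0, 0.5), (1.0, 1.0), (-1.0, 0.0)])
    def test_boundary_points(self, c, cp):
        assert cc_to_cp(c) == pytest.approx(cp, abs=1e-12)
        assert cp_to_cc(cp) == pytest.approx(c, abs=1e-12)

    @given(st.floats(min_value=0.001, max_value=0.999))
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_round_trip_identity(self, cp):
        assert cc_to_cp(cp_to_cc(cp)) == pytest.approx(cp, abs=1e-12)

    def test_strictly_monotone(self):
        c = np.linspace(-1, 1, 1001)
        assert np.all(np.diff(cc_to_cp(c)) > 0)

    def test_small_c_linear_slope(self):
        # linear approximation CP ~ 0.5 + (sqrt(2)/pi) c
        eps = 1e-6
        slope = (cc_to_cp(eps) - 0.5) / eps
        assert slope == pytest.approx(np.sqrt(2) / np.pi, rel=1e-4)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            cp_to_cc(1.2)
        with pytest.raises(ValueError):
            cc_to_cp(1.5)


class TestChoiceProbability:
    def test_identical_distributions_give_half(self, rng):
        x = np.tile(np.arange(10.0), 2)
        choices = np.repeat([1, -1], 10)
        st_ = choice_probability(x, choices, preferred_sign=1)
        assert st_.CP == pytest.approx(0.5)
        assert st_.c_choice == pytest.approx(0.0, abs=1e-12)

    def test_hand_counted_example(self):
        # pref {2,3,4} vs null {1,2,3}: 7 of 9 weighted pairs favor pref
        # padded to the 5-trial minimum with symmetric extremes
        resid = np.array([2., 3, 4, 0, 9, 1, 2, 3, 0, 9])
        choices = np.array([1, 1, 1, 1, 1, -1, -1, -1, -1, -1])
        st_ = choice_probability(resid, choices, preferred_sign=1)
        assert st_.CP == pytest.approx(
            auroc_exhaustive(resid[:5], resid[5:]))

    def test_matches_exhaustive_oracle_on_random_instances(self, rng):
        for _ in range(100):
            n1 = rng.integers(5, 12)
            n2 = rng.integers(5, 12)
            pos = rng.integers(0, 6, size=n1).astype(float)
            neg = rng.integers(0, 6, size=n2).astype(float)
            resid = np.concatenate([pos, neg])
            choices = np.concatenate([np.ones(n1), -np.ones(n2)])
            st_ = choice_probability(resid, choices, preferred_sign=1)
            assert st_.CP == pytest.approx(auroc_exhaustive(pos, neg),
                                           abs=1e-12)

    def test_label_swap_maps_cp_to_complement(self, rng):
        resid = rng.normal(size=40)
        choices = np.sign(rng.normal(size=40))
        choices[choices == 0] = 1
        a = choice_probability(resid, choices, preferred_sign=1)
        b = choice_probability(resid, -choices, preferred_sign=1)
        assert a.CP == pytest.approx(1 - b.CP, abs=1e-12)
        assert a.c_choice == pytest.approx(-b.c_choice, abs=1e-12)

    def test_class_underflow_raises_with_counts(self):
        resid = np.arange(8.0)
        choices = np.array([1, 1, 1, 1, 1, 1, -1, -1])
        with pytest.raises(ValueError, match="2 "):
            choice_probability(resid, choices, preferred_sign=1)


class TestSubspaceMap:
    def test_noiseless_identifiability(self, rng):
        s_true = np.array([0.1, 0.3, 0.2])
        H = rng.integers(0, 30, size=(40, 3)).astype(float)
        counts = H @ s_true
        smap = subspace_map(H, counts)
        assert np.allclose(smap.weights, s_true, atol=1e-6)
        assert np.allclose(stimulus_correct(counts, smap, H), 0, atol=1e-6)

    def test_constant_counts_predicted_exactly(self, rng):
        # constant-sum histograms: a flat map reproduces constant counts
        H = np.array([np.bincount(rng.integers(0, 3, size=30), minlength=3)
                      for _ in range(20)], dtype=float)
        counts = np.full(20, 60.0)
        smap = subspace_map(H, counts)
        assert np.allclose(smap.predict(H), counts, atol=1e-5)

    def test_hand_worked_normal_equations(self):
        # 3 disparities, 6 trials; solve (H'H) s = H'y independently
        H = np.array([[3., 1, 0], [1, 2, 1], [0, 1, 3],
                      [2, 2, 0], [1, 1, 2], [0, 3, 1]])
        y = np.array([5., 7, 9, 6, 8, 10])
        s_manual = np.linalg.inv(H.T @ H) @ (H.T @ y)
        smap = subspace_map(H, y)
        assert np.allclose(smap.weights, s_manual, atol=1e-5)

    def test_rank_deficient_flagged(self):
        H = np.array([[1., 1, 2], [2, 2, 4], [1, 1, 2], [3, 3, 6]])
        smap = subspace_map(H, np.array([1., 2, 1, 3]))
        assert smap.rank_deficient

    def test_additive_choice_gain_survives_correction(self, rng):
        # unit = stimulus drive + choice gain: residual class difference
        # recovers the injected gain
        s_true = np.array([0.2, 0.4, 0.3, 0.25])
        n = 400
        H = rng.multinomial(50, [0.25] * 4, size=n).astype(float)
        choices = rng.choice([-1, 1], size=n)
        gain = 3.0
        counts = H @ s_true + gain * choices + rng.normal(0, 1.0, n)
        smap = subspace_map(H, counts)
        resid = stimulus_correct(counts, smap, H)
        diff = resid[choices == 1].mean() - resid[choices == -1].mean()
        assert diff == pytest.approx(2 * gain, abs=0.5)


class TestTimecourse:
    def _toy(self, rng, onset_ms=0.0):
        from vischoice.config import SimConfig
        from vischoice.synth import generate_session, simulate_binned_counts
        cfg = SimConfig(n_block_cycles=2, trials_per_block=60,
                        n_units_per_side=2, seed=31, choice_gain=6.0,
                        choice_gain_spread=0.0, zero_signal_fraction=1.0,
                        drift_amplitude=0.0)
        sess = generate_session(cfg)
        binned = simulate_binned_counts(sess, units=[0], bin_ms=10.0,
                                        choice_onset_ms=onset_ms, rng=rng)
        return cfg, sess, binned[0]

    def test_degenerate_window_equals_whole_trial(self, rng):
        from vischoice.choice import unit_choice_stats
        from vischoice.synth import disparity_histogram
        cfg, sess, binned = self._toy(rng)
        choices = sess.trials["choice"].to_numpy()
        pref = int(sess.unit_meta.iloc[0]["pref_sign"])
        frames = sess.unit_frames(0)
        tc = timecourse_cc(binned, choices, frames, cfg.support, pref,
                           cfg.frame_rate, window_ms=2000.0, step_ms=2000.0,
                           latency_ms=0.0)
        assert len(tc.cc) == 1
        H = np.vstack([disparity_histogram(frames[t], cfg.support)
                       for t in range(sess.n_trials)])
        whole = unit_choice_stats(binned.sum(axis=1), choices, H, pref)
        assert tc.cc[0] == pytest.approx(whole.c_choice, abs=1e-12)

    def test_constant_gain_gives_flat_timecourse(self, rng):
        cfg, sess, binned = self._toy(rng)
        choices = sess.trials["choice"].to_numpy()
        pref = int(sess.unit_meta.iloc[0]["pref_sign"])
        tc = timecourse_cc(binned, choices, sess.unit_frames(0),
                           cfg.support, pref, cfg.frame_rate,
                           window_ms=300.0, step_ms=50.0)
        valid = tc.cc[~np.isnan(tc.cc)]
        early = valid[:len(valid) // 3].mean()
        late = valid[-len(valid) // 3:].mean()
        assert valid.mean() > 0.1
        assert abs(early - late) < 0.15

    def test_late_gain_onset_emerges_late(self, rng):
        cfg, sess, binned = self._toy(rng, onset_ms=1000.0)
        choices = sess.trials["choice"].to_numpy()
        pref = int(sess.unit_meta.iloc[0]["pref_sign"])
        tc = timecourse_cc(binned, choices, sess.unit_frames(0),
                           cfg.support, pref, cfg.frame_rate,
                           window_ms=300.0, step_ms=50.0)
        early = tc.cc[tc.time_ms < 800]
        late = tc.cc[tc.time_ms > 1200]
        assert np.nanmean(late) > np.nanmean(early) + 0.1
        assert abs(np.nanmean(early)) < 0.1
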