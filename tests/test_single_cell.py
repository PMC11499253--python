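"""Choice probability, ACHW, GLMs, photometry and the SVM decoder."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from linedyn import SimConfig, simulate_session
from linedyn.behavior import BoutTable
from linedyn.containers import PopulationRaster, zscore_rows
from linedyn.single_cell import (
    _binned_responses,
    autocorr_halfwidth,
    choice_probability,
    fit_behavior_glm,
    fit_coupled_glm,
    framewise_svm_decoder,
    photometry_normalize,
)
from linedyn.integrator import behavior_indicators

from conftest import make_bouts


def _pair_of_bout_sets(n_a=3, n_b=3, dur=20, gap=20):
    rows_a, rows_b = [], []
    t = 0
    for _ in range(n_a):
        rows_a.append(("female", "lordose", t, t + dur))
        t += dur + gap
    for _ in range(n_b):
        rows_b.append(("female", "dart", t, t + dur))
        t += dur + gap
    return make_bouts(rows_a), make_bouts(rows_b), t


class TestChoiceProbability:
    def test_identical_responses_give_half(self):
        ba, bb, T = _pair_of_bout_sets()
        data = np.tile(np.arange(20, dtype=float) % 7, (2, T // 20 + 1))
        raster = PopulationRaster(data[:, :T], 10.0)
        cp = choice_probability(raster, ba, bb, group_a="lordose",
                                group_b="dart", n_shuffles=20)
        assert np.allclose(cp.cp, 0.5)

    def test_fully_separated_responses_give_one(self):
        ba, bb, T = _pair_of_bout_sets()
        data = np.zeros((1, T))
        data[0, ba.frame_mask(T)] = 5.0
        raster = PopulationRaster(data, 10.0)
        cp = choice_probability(raster, ba, bb, group_a="lordose",
                                group_b="dart", n_shuffles=20)
        assert cp.cp[0] == pytest.approx(1.0)

    def test_matches_exhaustive_pair_counting(self, rng):
        """On small instances CP equals the Mann-Whitney U/(n*m) oracle."""
        ba, bb, T = _pair_of_bout_sets(n_a=2, n_b=2, dur=30)
        raster = PopulationRaster(rng.standard_normal((3, T)), 10.0)
        cp = choice_probability(raster, ba, bb, group_a="lordose",
                                group_b="dart", n_shuffles=10)
        ra = _binned_responses(raster, ba, "lordose", 1.0)
        rb = _binned_responses(raster, bb, "dart", 1.0)

        def brute(a, b):
            wins = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
            return wins / (len(a) * len(b))

        for i in range(3):
            assert cp.cp[i] == pytest.approx(brute(ra[i], rb[i]), abs=1e-12)

    def test_antisymmetry_under_behaviour_swap(self, rng):
        ba, bb, T = _pair_of_bout_sets()
        raster = PopulationRaster(rng.standard_normal((4, T)), 10.0)
        ab = choice_probability(raster, ba, bb, group_a="lordose",
                                group_b="dart", n_shuffles=5)
        ba_ = choice_probability(raster, bb, ba, group_a="dart",
                                 group_b="lordose", n_shuffles=5)
        assert np.allclose(ab.cp + ba_.cp, 1.0, atol=1e-12)

    def test_empty_behaviour_flagged(self, rng):
        ba, bb, T = _pair_of_bout_sets()
        empty = bb.select(group="lordose")  # no such bouts -> empty
        raster = PopulationRaster(rng.standard_normal((2, T)), 10.0)
        cp = choice_probability(raster, ba, empty, group_a="lordose",
                                group_b="lordose", n_shuffles=5)
        assert cp.flagged and np.all(np.isnan(cp.cp))

    def test_tuned_flag_requires_extremity_and_shuffle_deviation(self):
        ba, bb, T = _pair_of_bout_sets()
        data = np.zeros((1, T))
        data[0, ba.frame_mask(T)] = 5.0
        raster = PopulationRaster(data, 10.0)
        cp = choice_probability(raster, ba, bb, group_a="lordose",
                                group_b="dart", n_shuffles=200, seed=1)
        assert cp.tuned[0]


class TestACHW:
    def test_white_noise_has_subframe_achw(self, rng):
        out = autocorr_halfwidth(rng.standard_normal(6000), 10.0)
        assert out.achw_seconds < 0.2

    def test_ar1_closed_form(self):
        """AR(1) phi=0.995 at 10 Hz: ACHW ~ 0.1*ln(0.5)/ln(0.995) ~ 13.8 s
        (mean over 50 realizations)."""
        rng = np.random.default_rng(7)
        vals = []
        for _ in range(50):
            e = rng.standard_normal(6000)
            x = np.zeros(6000)
            for t in range(1, 6000):
                x[t] = 0.995 * x[t - 1] + e[t]
            vals.append(autocorr_halfwidth(x, 10.0).achw_seconds)
        expected = 0.1 * np.log(0.5) / np.log(0.995)
        assert np.mean(vals) == pytest.approx(expected, rel=0.15)

    @settings(max_examples=10, deadline=None)
    @given(a=st.floats(0.1, 10), b=st.floats(-5, 5))
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(3)
        x = np.cumsum(rng.standard_normal(2000)) * 0.1
        base = autocorr_halfwidth(x, 10.0).achw_seconds
        scaled = autocorr_halfwidth(a * x + b, 10.0).achw_seconds
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_constant_trace_flagged(self):
        out = autocorr_halfwidth(np.ones(500), 10.0)
        assert out.flagged and np.isnan(out.achw_seconds)

    def test_never_crossing_censored(self):
        out = autocorr_halfwidth(np.linspace(0, 1, 3000), 10.0,
                                 max_lag_seconds=20)
        assert out.censored and out.achw_seconds == pytest.approx(20.0)

    def test_slow_population_has_longer_achw_than_fast(
            self, receptive_session, unreceptive_session):
        """Persistence contrast: free-interaction-like slow sessions show
        longer mean single-cell ACHW than fast-dynamics sessions."""
        slow = np.mean([autocorr_halfwidth(t, 10.0).achw_seconds
                        for t in receptive_session.raster.data[:30]])
        fast = np.mean([autocorr_halfwidth(t, 10.0).achw_seconds
                        for t in unreceptive_session.raster.data[:30]])
        assert slow > fast


class TestBehaviorGLM:
    def test_noise_neuron_has_no_explained_variance(self, rng):
        sess_bouts = simulate_session(
            SimConfig(seed=2, n_neurons=3, duration_frames=3000)).male_bouts
        data = rng.standard_normal((3, 3000))
        raster = PopulationRaster(data, 10.0)
        g = fit_behavior_glm(raster, sess_bouts, folds=5)
        assert np.all(np.abs(g.cv_r2) < 0.05)

    def test_planted_filter_recovered(self, rng):
        """A neuron built as filter * mount indicator returns a filter with
        cosine similarity > 0.9 at SNR 5."""
        sess = simulate_session(SimConfig(seed=2, n_neurons=3,
                                          duration_frames=4000))
        u = behavior_indicators(sess.male_bouts, 4000)
        filt = np.exp(-np.arange(101) / 30.0)
        sig = np.convolve(u[1], filt)[:4000]
        noise_sd = sig.std() / np.sqrt(5.0)
        data = np.vstack([sig + rng.standard_normal(4000) * noise_sd
                          for _ in range(2)])
        raster = PopulationRaster(zscore_rows(data)[0], 10.0)
        g = fit_behavior_glm(raster, sess.male_bouts, folds=5)
        rec = g.filters[0, 1]
        cos = rec @ filt[:101] / np.linalg.norm(rec) / \
            np.linalg.norm(filt[:101])
        assert cos > 0.9

    def test_constant_regressor_dropped_with_record(self, rng):
        bouts = make_bouts([("male", "mount", 10, 50)])
        raster = PopulationRaster(rng.standard_normal((2, 400)), 10.0)
        g = fit_behavior_glm(raster, bouts, folds=3)
        assert "sniff" in g.dropped and "intromission" in g.dropped


class TestCoupledGLM:
    def test_independent_neurons_gain_nothing(self, rng):
        bouts = simulate_session(SimConfig(seed=3, n_neurons=3,
                                           duration_frames=3000)).male_bouts
        raster = PopulationRaster(rng.standard_normal((4, 3000)), 10.0)
        gb = fit_behavior_glm(raster, bouts, folds=5)
        gc = fit_coupled_glm(raster, bouts, folds=5)
        assert gc.cv_r2.mean() - gb.cv_r2.mean() < 0.05

    def test_duplicated_neurons_predict_each_other(self, rng):
        bouts = simulate_session(SimConfig(seed=3, n_neurons=3,
                                           duration_frames=2000)).male_bouts
        tr = np.cumsum(rng.standard_normal(2000)) * 0.1
        data = np.vstack([tr, tr + 1e-3 * rng.standard_normal(2000),
                          rng.standard_normal(2000)])
        raster = PopulationRaster(zscore_rows(data)[0], 10.0)
        gc = fit_coupled_glm(raster, bouts, folds=5)
        assert gc.cv_r2[0] > 0.95 and gc.cv_r2[1] > 0.95

    def test_shared_latent_coupling_beats_behaviour_only(self):
        """On generator rasters (shared latents) coupling raises cvR^2, the
        direction of the population-coupling result."""
        sess = simulate_session(SimConfig(seed=4, n_neurons=20,
                                          duration_frames=3000))
        gb = fit_behavior_glm(sess.raster, sess.male_bouts, folds=5)
        gc = fit_coupled_glm(sess.raster, sess.male_bouts, folds=5)
        assert gc.cv_r2.mean() > gb.cv_r2.mean()

    def test_self_coupling_excluded(self):
        sess = simulate_session(SimConfig(seed=4, n_neurons=5,
                                          duration_frames=1500))
        gc = fit_coupled_glm(sess.raster, sess.male_bouts, folds=3)
        assert np.allclose(np.diag(gc.coupling), 0.0)


class TestPhotometry:
    def test_equal_channels_give_zero(self, rng):
        f405 = 2.0 + 0.1 * rng.random(500)
        assert np.allclose(photometry_normalize(f405, f405), 0.0, atol=1e-9)

    def test_ten_percent_above_control_fit_gives_ten(self, rng):
        fit = 2.0 + 0.1 * rng.random(500)
        out = photometry_normalize(1.1 * fit, fit, control_fit=fit)
        assert np.allclose(out, 10.0, atol=1e-9)

    def test_proportional_channels_absorbed_by_fit(self, rng):
        # a constant gain difference is an artifact, not signal
        f405 = 2.0 + 0.1 * rng.random(500)
        assert np.allclose(photometry_normalize(1.1 * f405, f405), 0.0,
                           atol=1e-9)

    def test_joint_rescaling_invariance(self, rng):
        f405 = 2.0 + 0.2 * rng.random(500)
        f470 = f405 * (1 + 0.05 * rng.random(500))
        base = photometry_normalize(f470, f405)
        scaled = photometry_normalize(3.7 * f470, 3.7 * f405)
        assert np.allclose(base, scaled, atol=1e-9)

    def test_nonpositive_fit_rejected(self):
        with pytest.raises(ValueError):
            photometry_normalize(np.array([-1.0, -2.0, -1.5]),
                                 np.array([1.0, 2.0, 1.5]))


def _alternating_trials(rng, T=2000, n_neurons=20, sep=0.0):
    X = rng.standard_normal((n_neurons, T)) * 0.3
    rows = []
    cls = np.zeros(T, int)
    t, c = 0, 0
    while t < T - 40:
        cls[t:t + 30] = c
        rows.append(("female", "lordose" if c else "dart", t, t + 30))
        t += 40
        c = 1 - c
    X[0] += cls * sep
    bt = make_bouts(rows)
    return PopulationRaster(X, 10.0), bt


class TestDecoder:
    def test_separable_classes_decoded_with_shuffle_at_chance(self, rng):
        raster, bouts = _alternating_trials(rng, sep=2.0)
        out = framewise_svm_decoder(raster, bouts.select(group="lordose"),
                                    bouts.select(group="dart"),
                                    merge_gap_seconds=0.0, seed=0)
        assert out.f1_actual > 0.9
        assert 0.45 <= out.f1_shuffles.mean() <= 0.55

    def test_identical_distributions_match_shuffle(self, rng):
        raster, bouts = _alternating_trials(rng, sep=0.0)
        out = framewise_svm_decoder(raster, bouts.select(group="lordose"),
                                    bouts.select(group="dart"),
                                    merge_gap_seconds=0.0, seed=0)
        sd = out.f1_shuffles.std()
        assert abs(out.f1_actual - out.f1_shuffles.mean()) < 2 * max(sd, 0.02)

    def test_two_trial_toy_f1_hand_computed(self):
        """Tiny instance with a perfectly separating dimension: every held
        out frame is classified correctly -> F1 = 1."""
        data = np.zeros((2, 40))
        data[0, :20] = 1.0
        rows = [("female", "lordose", 0, 10), ("female", "lordose", 10, 20),
                ("female", "dart", 20, 30), ("female", "dart", 30, 40)]
        bt = make_bouts(rows)
        raster = PopulationRaster(data, 10.0)
        out = framewise_svm_decoder(raster, bt.select(group="lordose"),
                                    bt.select(group="dart"),
                                    merge_gap_seconds=0.0, folds=2,
                                    n_shuffles=5, seed=0)
        assert out.f1_actual == pytest.approx(1.0)

    def test_missing_class_flagged(self, rng):
        raster, bouts = _alternating_trials(rng)
        empty = bouts.select(group="sniff")
        out = framewise_svm_decoder(raster, bouts.select(group="lordose"),
                                    empty, seed=0)
        assert out.flagged
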