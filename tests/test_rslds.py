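"""rSLDS engine: fitting, time constants, scores, projections, flow fields."""

import numpy as np
import pytest

from linedyn import SimConfig, simulate_session
from linedyn.containers import PopulationRaster, LatentTrajectory
from linedyn.rslds import (
    FitConfig,
    RSLDSParams,
    attractor_line_distance,
    fit_excluding_windows,
    fit_rslds,
    flow_field_2d,
    forward_sim_accuracy,
    integration_dimension,
    line_attractor_score,
    pls_integration_dimension,
    project_into_model,
    select_model_order,
    time_constants,
)


def _planted_params(A, b=None, D=None, n_neurons=8, seed=0):
    D = A.shape[0] if D is None else D
    rng = np.random.default_rng(seed)
    C = rng.standard_normal((n_neurons, D))
    return RSLDSParams(
        A=A[None], b=np.zeros((1, D)) if b is None else b[None],
        Q=np.eye(D)[None] * 1e-4, R=np.zeros((1, D)), r=np.zeros(1),
        P=np.zeros((1, 1)), C=C, d=np.zeros(n_neurons),
        S=np.full(n_neurons, 0.01))


class TestTimeConstants:
    @pytest.mark.parametrize("k", [1, 10, 100])
    def test_log_inverse_closed_form(self, k):
        """tau(exp(-1/k)) = k frames exactly."""
        A = np.diag([np.exp(-1.0 / k), 0.2])
        tcs = time_constants(_planted_params(A), frame_rate=10.0)
        assert tcs.taus_frames[0][0] == pytest.approx(k, rel=1e-12)
        assert tcs.taus_seconds[0][0] == pytest.approx(k / 10.0, rel=1e-12)

    def test_zero_eigenvalue_gives_zero_tau(self):
        A = np.diag([0.0, 0.5])
        tcs = time_constants(_planted_params(A), frame_rate=10.0)
        assert min(tcs.taus_frames[0]) == 0.0

    def test_unit_eigenvalue_capped_and_flagged(self):
        A = np.diag([1.0, 0.5])
        tcs = time_constants(_planted_params(A), frame_rate=10.0)
        assert tcs.capped
        assert tcs.taus_frames[0][0] >= 1e5

    def test_complex_pair_shares_magnitude(self):
        rot = 0.9 * np.array([[np.cos(0.3), -np.sin(0.3)],
                              [np.sin(0.3), np.cos(0.3)]])
        tcs = time_constants(_planted_params(rot), frame_rate=10.0)
        assert tcs.taus_frames[0][0] == pytest.approx(tcs.taus_frames[0][1])


class TestLineAttractorScore:
    def test_hundred_vs_five_seconds(self):
        A = np.diag([np.exp(-0.1 / 100), np.exp(-0.1 / 5)])
        tcs = time_constants(_planted_params(A), frame_rate=10.0)
        assert line_attractor_score(tcs) == pytest.approx(np.log2(20), rel=1e-9)

    def test_equal_taus_score_zero(self):
        A = np.diag([0.9, 0.9])
        tcs = time_constants(_planted_params(A), frame_rate=10.0)
        assert line_attractor_score(tcs) == pytest.approx(0.0, abs=1e-12)

    def test_single_dimension_rejected(self):
        tcs = time_constants(_planted_params(np.array([[0.9]])), 10.0)
        with pytest.raises(ValueError):
            line_attractor_score(tcs)


class TestFitRslds:
    def test_noise_free_single_state_recovery(self, rng):
        """On clean single-state LDS data the eigenvalues are recovered to
        < 1% and emission variance explained is essentially perfect."""
        D, N, T = 2, 20, 2000
        A = np.diag([0.995, 0.9])
        x = np.zeros((D, T))
        drive = rng.standard_normal((D, T)) * np.array([[0.03], [0.3]])
        for t in range(1, T):
            x[:, t] = A @ x[:, t - 1] + drive[:, t]
        C = rng.standard_normal((N, D))
        y = C @ x
        y = (y - y.mean(1, keepdims=True)) / y.std(1, keepdims=True)
        raster = PopulationRaster(y, 10.0)
        params, lat, diag = fit_rslds(raster, K=1, D=2,
                                      config=FitConfig(n_iters=40))
        ev_true = np.sort(np.abs(np.linalg.eigvals(A)))
        ev_fit = np.sort(np.abs(np.linalg.eigvals(params.A[0])))
        assert np.allclose(ev_fit, ev_true, rtol=0.01)
        pred = params.C @ lat.x + params.d[:, None]
        r2 = 1 - ((y - pred)**2).sum() / (y**2).sum()
        assert r2 > 0.99

    def test_objective_improves_over_iterations(self, small_session):
        _, _, diag = fit_rslds(small_session.raster, K=1, D=3,
                               config=FitConfig(n_iters=15))
        trace = diag.elbo_trace
        assert trace[-1] > trace[0]
        # no catastrophic decreases along the trace
        drops = np.diff(trace) / np.abs(trace[0])
        assert drops.min() > -1e-3

    def test_fitted_spectrum_stable(self, small_session):
        params, _, diag = fit_rslds(small_session.raster, K=1, D=3,
                                    config=FitConfig(n_iters=15))
        for k in range(params.n_states):
            assert np.abs(np.linalg.eigvals(params.A[k])).max() <= 1 + 1e-6 \
                or diag.unstable

    def test_too_short_raster_rejected(self):
        raster = PopulationRaster(np.zeros((5, 3)), 10.0)
        with pytest.raises(ValueError):
            fit_rslds(raster, K=2, D=3)


class TestForwardSim:
    def test_truth_model_noise_free_perfect(self, rng):
        D, T = 2, 500
        A = np.diag([0.99, 0.9])
        x = np.zeros((D, T))
        x[:, 0] = [1.0, 1.0]
        for t in range(1, T):
            x[:, t] = A @ x[:, t - 1]
        params = _planted_params(A)
        lat = LatentTrajectory(x=x, frame_rate=10.0)
        out = forward_sim_accuracy(params, lat, delta_t=5)
        assert out["mse"].max() < 1e-18
        assert out["variance_explained"] == pytest.approx(1.0)

    def test_accuracy_bounded(self, small_session):
        params, lat, _ = fit_rslds(small_session.raster, K=1, D=3,
                                   config=FitConfig(n_iters=10))
        out = forward_sim_accuracy(params, lat, delta_t=10)
        assert np.all((out["accuracy"] >= 0) & (out["accuracy"] <= 1))

    def test_shuffled_surrogate_degrades(self, small_session, rng):
        params, lat, _ = fit_rslds(small_session.raster, K=1, D=3,
                                   config=FitConfig(n_iters=10))
        intact = forward_sim_accuracy(params, lat, delta_t=10)
        perm = rng.permutation(lat.n_frames)
        shuf = LatentTrajectory(x=lat.x[:, perm], z=lat.z[perm],
                                credences=lat.credences[perm],
                                frame_rate=10.0)
        degraded = forward_sim_accuracy(params, shuf, delta_t=10)
        assert degraded["variance_explained"] < \
            intact["variance_explained"] - 0.2

    def test_invalid_delta_rejected(self, small_session):
        params, lat, _ = fit_rslds(small_session.raster, K=1, D=2,
                                   config=FitConfig(n_iters=3))
        with pytest.raises(ValueError):
            forward_sim_accuracy(params, lat, delta_t=0)


class TestIntegrationDimension:
    def test_recovers_ground_truth_slow_latent(self, receptive_session):
        sess = receptive_session
        params, lat, _ = fit_rslds(sess.raster, K=1, D=3,
                                   config=FitConfig(n_iters=30))
        out = integration_dimension(params, lat)
        assert out["attractor_present"]
        r = np.corrcoef(out["series"], sess.latents.x[0])[0, 1]
        assert abs(r) > 0.9

    def test_unreceptive_flags_absence(self, unreceptive_session):
        params, lat, _ = fit_rslds(unreceptive_session.raster, K=1, D=2,
                                   config=FitConfig(n_iters=30))
        out = integration_dimension(params, lat, min_ratio=3.0)
        assert not out["attractor_present"]

    def test_persistence_across_bouts_and_ibis(self, receptive_session):
        """Integrator activity during copulation bouts roughly equals that
        during the IBIs (persistence rather than stimulus-locking)."""
        sess = receptive_session
        params, lat, _ = fit_rslds(sess.raster, K=1, D=3,
                                   config=FitConfig(n_iters=30))
        out = integration_dimension(params, lat)
        series = out["series"]
        # restrict to the copulation phase of the session
        cop_mask = sess.male_bouts.frame_mask(lat.n_frames, group="copulation")
        first = np.flatnonzero(cop_mask)[0]
        active = np.zeros_like(cop_mask)
        active[first:] = True
        bout_mean = series[cop_mask].mean()
        ibi_mean = series[active & ~cop_mask].mean()
        assert 0.8 <= bout_mean / ibi_mean <= 1.25


class TestProjectIntoModel:
    def test_training_raster_reproduces_training_latents(self, small_session):
        params, lat, _ = fit_rslds(small_session.raster, K=1, D=3,
                                   config=FitConfig(n_iters=15))
        lat2 = project_into_model(params, small_session.raster)
        for d in range(3):
            assert np.corrcoef(lat.x[d], lat2.x[d])[0, 1] > 0.99

    def test_neuron_mismatch_rejected(self, small_session):
        params, _, _ = fit_rslds(small_session.raster, K=1, D=2,
                                 config=FitConfig(n_iters=3))
        wrong = PopulationRaster(small_session.raster.data[:-1], 10.0)
        with pytest.raises(ValueError):
            project_into_model(params, wrong)

    def test_unreceptive_data_in_receptive_model_shows_no_ramp(self):
        """Cross-regime projection: unreceptive activity projected into a
        receptive-day model has no net slow-dimension ramp."""
        rec = simulate_session(SimConfig(seed=21, n_neurons=40,
                                         duration_frames=3000))
        unrec = simulate_session(SimConfig(seed=21, n_neurons=40,
                                           duration_frames=3000,
                                           regime="unreceptive",
                                           latent_dim=3))
        params, lat, _ = fit_rslds(rec.raster, K=1, D=3,
                                   config=FitConfig(n_iters=25))
        out = integration_dimension(params, lat)
        lat_x = project_into_model(params, unrec.raster)
        # slow-mode coordinate for both projections
        lam, V = np.linalg.eig(params.A[out["state"]])
        order = np.argsort(-np.abs(lam))
        w = np.real(np.linalg.inv(V[:, order])[0])
        ramp_rec = w @ lat.x[:, -300:].mean(1) - w @ lat.x[:, :300].mean(1)
        ramp_un = w @ lat_x.x[:, -300:].mean(1) - w @ lat_x.x[:, :300].mean(1)
        assert abs(ramp_un) < 0.2 * abs(ramp_rec)


class TestSelectModelOrder:
    def test_singleton_grid_returned(self, small_session):
        K, D = select_model_order(small_session.raster, K_grid=(1,),
                                  D_grid=(2,), folds=3,
                                  config=FitConfig(n_iters=6))
        assert (K, D) == (1, 2)

    def test_latent_dimension_recovered(self):
        """Cross-validation prefers the generative latent dimensionality."""
        sess = simulate_session(SimConfig(seed=30, n_neurons=40,
                                          duration_frames=2500))
        K, D = select_model_order(sess.raster, K_grid=(1,),
                                  D_grid=(1, 2, 3, 4), folds=3,
                                  config=FitConfig(n_iters=8))
        assert D == 3

    def test_empty_grid_rejected(self, small_session):
        with pytest.raises(ValueError):
            select_model_order(small_session.raster, K_grid=(), D_grid=(1,))


class TestFlowField:
    def test_point_attractor_slow_region_contains_fixed_point(self, rng):
        A = np.diag([0.9, 0.85])
        b = np.array([0.5, 0.3])
        params = _planted_params(A, b=b)
        x_star = np.linalg.solve(np.eye(2) - A, b)
        x = x_star[:, None] + rng.standard_normal((2, 400))
        ff = flow_field_2d(params, LatentTrajectory(x=x, frame_rate=10.0),
                           grid_n=30)
        p = ff.basis @ (x_star - ff.center)
        ix = np.argmin(np.abs(ff.grid_x - p[0]))
        iy = np.argmin(np.abs(ff.grid_y - p[1]))
        assert ff.slow_mask[iy, ix]

    def test_velocity_zero_at_fixed_point(self):
        A = np.diag([0.9, 0.85])
        b = np.array([0.5, 0.3])
        params = _planted_params(A, b=b)
        x_star = np.linalg.solve(np.eye(2) - A, b)
        v = (params.A[0] - np.eye(2)) @ x_star + params.b[0]
        assert np.abs(v).max() < 1e-9

    def test_line_attractor_slow_region_elongated(self, rng):
        """For a planted line attractor the slow region forms an elongated
        band along the slow axis."""
        A = np.diag([0.9995, 0.85])
        params = _planted_params(A)
        x = np.vstack([np.linspace(-3, 3, 600),
                       0.3 * rng.standard_normal(600)])
        ff = flow_field_2d(params, LatentTrajectory(x=x, frame_rate=10.0),
                           grid_n=40, slow_percentile=10)
        ys, xs = np.nonzero(ff.slow_mask)
        spread_x = ff.grid_x[xs].max() - ff.grid_x[xs].min()
        spread_y = ff.grid_y[ys].max() - ff.grid_y[ys].min()
        long_, short = max(spread_x, spread_y), min(spread_x, spread_y)
        assert long_ / max(short, 1e-12) > 5

    def test_one_dim_latents_rejected(self):
        params = _planted_params(np.array([[0.9]]))
        with pytest.raises(ValueError):
            flow_field_2d(params, LatentTrajectory(x=np.zeros((1, 50))))


class TestFitExcludingWindows:
    def test_empty_windows_equivalent_to_plain_fit(self, small_session):
        out = fit_excluding_windows(small_session.raster, [], K=1, D=3,
                                    config=FitConfig(n_iters=10))
        plain, _, _ = fit_rslds(small_session.raster, K=1, D=3,
                                config=FitConfig(n_iters=10))
        ev_a = np.sort(np.abs(np.linalg.eigvals(out["params"].A[0])))
        ev_b = np.sort(np.abs(np.linalg.eigvals(plain.A[0])))
        assert np.allclose(ev_a, ev_b, rtol=1e-6)

    def test_window_outside_session_rejected(self, small_session):
        with pytest.raises(ValueError):
            fit_excluding_windows(small_session.raster, [(2900, 3500)],
                                  K=1, D=2)

    def test_insufficient_complement_rejected(self, small_session):
        with pytest.raises(ValueError):
            fit_excluding_windows(small_session.raster, [(0, 2990)],
                                  K=1, D=2)


class TestPLS:
    def test_target_carrying_neuron_dominates_weights(self, rng):
        T = 600
        target = np.cumsum(rng.random(T) * 0.01)
        data = rng.standard_normal((10, T)) * 0.2
        data[3] = target
        raster = PopulationRaster(
            (data - data.mean(1, keepdims=True)) / data.std(1, keepdims=True),
            10.0)
        out = pls_integration_dimension(raster, target)
        assert abs(out["weights"][3]) > 0.9

    def test_white_noise_has_no_holdout_correlation(self, rng):
        raster = PopulationRaster(rng.standard_normal((20, 800)), 10.0)
        target = np.linspace(0, 1, 800)
        out = pls_integration_dimension(raster, target)
        assert abs(out["holdout_corr"]) < 0.35

    def test_zero_variance_target_rejected(self, small_session):
        with pytest.raises(ValueError):
            pls_integration_dimension(small_session.raster,
                                      np.ones(small_session.raster.n_frames))

    def test_agrees_with_rslds_integration_dimension(self, receptive_session):
        """Supervised (PLS) and unsupervised (rSLDS) routes find the same
        integration dimension."""
        sess = receptive_session
        params, lat, _ = fit_rslds(sess.raster, K=1, D=3,
                                   config=FitConfig(n_iters=30))
        unsup = integration_dimension(params, lat)["series"]
        # ramp target: normalized cumulative male-contact time
        contact = sess.male_bouts.frame_mask(sess.raster.n_frames)
        target = np.cumsum(contact).astype(float)
        target /= target.max()
        sup = pls_integration_dimension(sess.raster, target)["series"]
        assert abs(np.corrcoef(sup, unsup)[0, 1]) > 0.8


class TestAttractorLineDistance:
    def test_on_line_distance_zero(self):
        A = np.diag([0.999, 0.8])
        params = _planted_params(A)
        # points along the slow axis with fast coordinate at its fixed point
        x = np.vstack([np.linspace(0, 3, 100), np.zeros(100)])
        out = attractor_line_distance(params, LatentTrajectory(x=x,
                                                               frame_rate=10.0))
        assert np.allclose(out["distance_sd"], 0.0, atol=1e-9)

    def test_off_line_distance_scales_with_displacement(self):
        A = np.diag([0.999, 0.8])
        params = _planted_params(A)
        x = np.vstack([np.ones(10), np.full(10, 0.5)])
        out = attractor_line_distance(params, LatentTrajectory(x=x,
                                                               frame_rate=10.0))
        assert np.all(out["distance_sd"] > 0)
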