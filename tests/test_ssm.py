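"""State-space engine: oracle equivalence, prediction, validation, simulation."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon, box

from icetrack import ssm
from tests.conftest import joint_gaussian_oracle, make_rw_track


def _times_ys_Rs(df):
    t0 = df["timestamp"].iloc[0]
    times = (df["timestamp"] - t0).dt.total_seconds().to_numpy() / 3600.0
    ys = df[["x", "y"]].to_numpy(float)
    Rs = ssm.observation_covariances(df)
    return times, ys, Rs


class TestKalmanOracle:
    @pytest.mark.parametrize("model,params", [
        ("rw", {"sigma2_x": 2.0e5, "sigma2_y": 1.0e5}),
        ("crw", {"beta": 0.3, "sigma2": 4.0e5}),
    ])
    def test_smoother_matches_joint_gaussian_conditioning(self, model, params):
        """Smoothed means/covariances on <=10-fix tracks agree with brute-force
        conditioning of the full joint Gaussian to 1e-6 relative."""
        df = make_rw_track(n=10, seed=5)
        # irregular spacing and anisotropic, rotated observation ellipses
        df["timestamp"] = df["timestamp"] + pd.to_timedelta(
            np.linspace(0, 5, 10) ** 1.5, unit="h"
        )
        df["smaj_m"] = np.linspace(400, 900, 10)
        df["smin_m"] = np.linspace(200, 400, 10)
        df["eor_deg"] = np.linspace(0, 170, 10)
        times, ys, Rs = _times_ys_Rs(df)
        ll, store = ssm._kalman(model, params, times, ys, Rs, store=True)
        ms, Ps = ssm._rts_smooth(store)
        om, oc, oll = joint_gaussian_oracle(model, params, times, ys, Rs)
        scale = np.max(np.abs(om))
        assert np.max(np.abs(ms - om)) / scale < 1e-6
        assert np.max(np.abs(Ps - oc)) / np.max(np.abs(oc)) < 1e-6

    @pytest.mark.parametrize("model,params", [
        ("rw", {"sigma2_x": 2.0e5, "sigma2_y": 1.0e5}),
        ("crw", {"beta": 0.3, "sigma2": 4.0e5}),
    ])
    def test_loglik_matches_direct_mvn_density(self, model, params):
        df = make_rw_track(n=6, seed=7)
        times, ys, Rs = _times_ys_Rs(df)
        ll = ssm._kalman(model, params, times, ys, Rs)
        _, _, oll = joint_gaussian_oracle(model, params, times, ys, Rs)
        assert abs(ll - oll) / abs(oll) < 1e-8

    def test_ml_variance_matches_grid_search(self):
        """1-D RW with 3 equispaced observations and known obs variance: the
        ML process variance agrees with a brute-force likelihood grid."""
        from scipy.stats import multivariate_normal

        obs_sd = 100.0
        df = make_rw_track(n=3, sigma2=5.0e4, obs_sd=obs_sd, seed=3)
        df["y"] = df["x"]  # duplicate axis: independent, same ML per axis
        df["smaj_m"] = df["smin_m"] = obs_sd
        times, ys, Rs = _times_ys_Rs(df)

        def grid_ll_1d(s2):
            # direct joint density of the three x-observations
            m0, P0 = ssm._init_state("rw", ys[0])
            mean = np.full(3, ys[0, 0])
            C = np.empty((3, 3))
            for i in range(3):
                for j in range(3):
                    C[i, j] = P0[0, 0] + s2 * min(times[i], times[j])
            C += obs_sd**2 * np.eye(3)
            return multivariate_normal.logpdf(ys[:, 0], mean=mean, cov=C)

        grid = np.exp(np.linspace(np.log(1e2), np.log(1e7), 2001))
        s2_grid = grid[np.argmax([grid_ll_1d(s) for s in grid])]
        # refine around the grid optimum
        fine = np.linspace(s2_grid * 0.8, s2_grid * 1.25, 4001)
        s2_grid = fine[np.argmax([grid_ll_1d(s) for s in fine])]
        fit = ssm.fit_ssm(df, "rw")
        assert abs(fit.params["sigma2_x"] - s2_grid) / s2_grid < 1e-3

    def test_vanishing_obs_error_reproduces_observations(self):
        df = make_rw_track(n=40, obs_sd=0.0, seed=1)
        df["smaj_m"] = df["smin_m"] = 0.01
        fit = ssm.fit_ssm(df, "rw")
        xy = fit.positions(fit.smoothed_mean)
        assert np.max(np.abs(xy - df[["x", "y"]].to_numpy())) < 1.0

    def test_straight_track_pushes_velocity_autocorrelation_to_bound(self):
        n = 60
        t0 = pd.Timestamp("2021-09-01", tz="UTC")
        df = pd.DataFrame(
            {
                "id": "W1", "segment": "s0",
                "timestamp": t0 + pd.to_timedelta(np.arange(n), unit="h"),
                "x": 1000.0 * np.arange(n), "y": 500.0 * np.arange(n),
                "lc": "G", "smaj_m": 50.0, "smin_m": 50.0, "eor_deg": 0.0,
                "source": "gps",
            }
        )
        fit = ssm.fit_ssm(df, "crw")
        # beta at/near its lower bound = velocity autocorrelation at its
        # upper bound (exp(-beta dt) -> 1)
        assert np.exp(-fit.params["beta"] * 1.0) > 0.99


class TestPrediction:
    def test_grid_count_and_anchor(self):
        df = make_rw_track(n=2, dt_h=8.0, seed=0)
        fit = ssm.fit_ssm(df, "rw")
        pt = ssm.predict_regular(fit, step_hours=4.0)
        assert len(pt) == 3
        assert (pt["timestamp"].iloc[0] - df["timestamp"].iloc[0]).total_seconds() == 0

    def test_rw_midpoint_is_average_of_smoothed_endpoints(self):
        df = make_rw_track(n=2, dt_h=8.0, seed=2)
        fit = ssm.fit_ssm(df, "rw")
        pt = ssm.predict_regular(fit, step_hours=4.0)
        mid = pt[["x", "y"]].iloc[1].to_numpy()
        ends = (pt[["x", "y"]].iloc[0].to_numpy() + pt[["x", "y"]].iloc[2].to_numpy()) / 2
        np.testing.assert_allclose(mid, ends, rtol=1e-8)

    def test_interior_gap_se_exceeds_se_at_observations(self):
        df = make_rw_track(n=20, dt_h=4.0, seed=4)
        # carve a 40 h hole in the middle
        df = pd.concat([df.iloc[:8], df.iloc[18:]]).reset_index(drop=True)
        fit = ssm.fit_ssm(df, "rw")
        pt = ssm.predict_regular(fit, step_hours=4.0)
        obs_times = (df["timestamp"] - df["timestamp"][0]).dt.total_seconds() / 3600
        pt_times = (pt["timestamp"] - df["timestamp"][0]).dt.total_seconds() / 3600
        in_gap = (pt_times > 28) & (pt_times < 72 - 4)
        se_gap = pt.loc[in_gap.to_numpy(), "se_x"]
        edge = pt_times.sub(28).abs().idxmin()
        assert (se_gap >= pt.loc[edge, "se_x"] - 1e-9).all()

    def test_unconverged_fit_refused(self):
        df = make_rw_track(n=5, seed=0)
        fit = ssm.fit_ssm(df, "rw")
        fit.converged = False
        with pytest.raises(ValueError, match="unconverged"):
            ssm.predict_regular(fit)


class TestValidationSelection:
    def test_aicc_formula(self):
        assert np.isclose(ssm.aicc(-5.0, 2, 10), 14 + 2 * 2 * 3 / 7)

    def test_osar_calibrated_on_well_specified_rw(self):
        df = make_rw_track(n=500, seed=8)
        fit = ssm.fit_ssm(df, "rw")
        r = fit.osar[np.isfinite(fit.osar[:, 0])][1:].ravel()
        assert -0.15 < r.mean() < 0.15
        assert 0.8 < r.var() < 1.2

    def test_lowest_aicc_selected(self):
        df = make_rw_track(n=80, seed=9)
        fits = [ssm.fit_ssm(df, "rw"), ssm.fit_ssm(df, "crw")]
        chosen, diag = ssm.validate_and_select(fits, n_replicates=5, seed=0)
        by_aicc = min((f for f in fits if f.converged), key=lambda f: f.aicc)
        if "oversmooth_guard" not in diag:
            assert chosen.model == by_aicc.model
        assert diag["replicates"].shape == (5, 80, 2)

    def test_replicates_recentre_on_smoothed_track(self):
        df = make_rw_track(n=60, seed=10)
        fit = ssm.fit_ssm(df, "rw")
        reps = ssm.replicate_tracks(fit, 200, seed=1)
        centre = fit.positions(fit.smoothed_mean)
        err = np.abs(reps.mean(axis=0) - centre)
        spread = reps.std(axis=0).mean()
        assert np.max(err) < 5 * spread


@pytest.fixture(scope="module")
def parent():
    df = make_rw_track(n=60, seed=12)
    fit = ssm.fit_ssm(df, "rw")
    pt = ssm.predict_regular(fit, step_hours=4.0)
    return fit, pt


class TestSimulateAndFilter:

    def test_exactly_k_of_n_retained(self, parent):
        fit, pt = parent
        s = ssm.simulate_and_filter(fit, pt, n_sim=100, k_keep=20, seed=0)
        assert s.retained.sum() == 20
        assert s.tracks.shape[0] == 100
        assert s.tracks.shape[1] == len(pt)

    def test_parent_injected_ranks_first(self, parent):
        fit, pt = parent
        s = ssm.simulate_and_filter(fit, pt, n_sim=50, k_keep=10, seed=1)
        tracks = s.tracks.copy()
        tracks[7] = pt[["x", "y"]].to_numpy()
        from icetrack.ssm import _net_features

        pd_, pb = _net_features(pt[["x", "y"]].to_numpy())
        disp = np.array([_net_features(t)[0] for t in tracks])
        bear = np.array([_net_features(t)[1] for t in tracks])
        dbear = np.arctan2(np.sin(bear - pb), np.cos(bear - pb))
        scores = -np.sqrt(((disp - pd_) / (disp.std() or 1)) ** 2 + (dbear / (dbear.std() or 1)) ** 2)
        assert np.argmax(scores) == 7

    def test_identical_candidates_tie_break_by_index(self, parent):
        fit, pt = parent
        s = ssm.simulate_and_filter(fit, pt, n_sim=30, k_keep=5, seed=2)
        s.scores[:] = -1.0
        order = np.argsort(-s.scores, kind="stable")
        assert list(order[:5]) == [0, 1, 2, 3, 4]

    def test_k_keep_larger_than_n_sim_rejected(self, parent):
        fit, pt = parent
        with pytest.raises(ValueError):
            ssm.simulate_and_filter(fit, pt, n_sim=10, k_keep=20)

    def test_step_variance_matches_fitted_process(self, parent):
        fit, pt = parent
        s = ssm.simulate_and_filter(fit, pt, n_sim=1000, k_keep=20, seed=3)
        dx = np.diff(s.tracks[:, :, 0], axis=1)
        emp = dx.var()
        want = fit.params["sigma2_x"] * 4.0  # 4-h steps
        assert abs(emp - want) / want < 0.10

    def test_barrier_keeps_tracks_off_land(self, parent):
        fit, pt = parent
        land_box = (5000.0, -50_000.0, 80_000.0, 50_000.0)

        def on_land(x, y):
            return land_box[0] <= x <= land_box[2] and land_box[1] <= y <= land_box[3]

        s = ssm.simulate_and_filter(fit, pt, n_sim=50, k_keep=10, land=on_land, seed=4)
        for tr in s.tracks:
            assert not any(on_land(x, y) for x, y in tr)


class TestReroute:
    land = box(0, 0, 100_000, 100_000)

    def _track(self, pts):
        return pd.DataFrame(
            {
                "x": [p[0] for p in pts],
                "y": [p[1] for p in pts],
                "lon": 0.0,
                "lat": 80.0,
            }
        )

    def test_inland_point_moved_to_eroded_coast(self):
        t = ssm.reroute(self._track([(50_000, 50_000)]), self.land, buffer_m=10_000)
        assert bool(t["rerouted"][0])
        x, y = t.loc[0, ["x", "y"]]
        eroded = self.land.buffer(-10_000)
        from shapely.geometry import Point

        assert eroded.boundary.distance(Point(x, y)) < 1.0

    def test_open_sea_point_unchanged(self):
        t = ssm.reroute(self._track([(-50_000, 50_000)]), self.land, buffer_m=10_000)
        assert not t["rerouted"][0]
        assert t.loc[0, "x"] == -50_000

    def test_fjord_point_within_buffer_band_left_in_place(self):
        # a 10-km-wide fjord arm: erosion by 10 km removes the whole arm
        fjord_land = Polygon(
            [(0, 0), (100_000, 0), (100_000, 45_000), (30_000, 45_000),
             (30_000, 55_000), (100_000, 55_000), (100_000, 100_000), (0, 100_000)]
        )
        pt = (35_000, 50_000)  # 5 km into the fjord arm
        assert fjord_land.buffer(-10_000).disjoint
        t = ssm.reroute(self._track([pt]), fjord_land, buffer_m=10_000)
        assert not t["rerouted"][0]
        assert t.loc[0, "x"] == pt[0] and t.loc[0, "y"] == pt[1]

    def test_invalid_geometry_rejected(self):
        bowtie = Polygon([(0, 0), (10, 10), (10, 0), (0, 10)])
        with pytest.raises(ValueError, match="invalid"):
            ssm.reroute(self._track([(5, 5)]), bowtie)
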