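"""Spline basis, design construction, Monte-Carlo RSF fits and stepwise."""

import subprocess

import numpy as np
import pandas as pd
import pytest

from icetrack import rsf
from icetrack.seascape import generate_rsf_testset


class TestNaturalSpline:
    def test_three_interior_knots_give_four_columns(self):
        x = np.linspace(0, 3500, 100)
        assert rsf.natural_spline_basis(x).shape == (100, 4)

    def test_linear_beyond_boundary_knots(self):
        x = np.concatenate([np.linspace(0, 3500, 50), [3600, 3700, 3800, -50, -100, -150]])
        B = rsf.natural_spline_basis(x, boundary=(0, 3500))
        for cols in (B[-6:-3], B[-3:]):  # beyond each boundary
            second_diff = cols[0] - 2 * cols[1] + cols[2]
            assert np.max(np.abs(second_diff)) < 1e-6

    def test_span_matches_truncated_power_textbook_construction(self):
        """Independent oracle: the classical truncated-power natural-spline
        basis spans the same 5-dim function space (with intercept)."""
        rng = np.random.default_rng(0)
        x = np.sort(rng.uniform(0, 3500, 80))
        knots = np.array([220.0, 500.0, 2500.0])
        lo, hi = 0.0, 3500.0
        xi = np.concatenate([[lo], knots, [hi]])
        K = len(xi)

        def d(k, t):
            return (np.maximum(t - xi[k], 0) ** 3 - np.maximum(t - xi[K - 1], 0) ** 3) / (
                xi[K - 1] - xi[k]
            )

        oracle = np.column_stack([x] + [d(k, x) - d(K - 2, x) for k in range(K - 2)])
        ours = rsf.natural_spline_basis(x, boundary=(lo, hi))
        A = np.c_[np.ones(len(x)), ours]
        for j in range(oracle.shape[1]):
            beta, *_ = np.linalg.lstsq(A, oracle[:, j], rcond=None)
            assert np.max(np.abs(oracle[:, j] - A @ beta)) < 1e-8 * max(
                1.0, np.max(np.abs(oracle[:, j]))
            )
        B = np.c_[np.ones(len(x)), oracle]
        for j in range(ours.shape[1]):
            beta, *_ = np.linalg.lstsq(B, ours[:, j], rcond=None)
            assert np.max(np.abs(ours[:, j] - B @ beta)) < 1e-8

    def test_span_matches_r_ns(self, tmp_path):
        """Cross-check against R's splines::ns on the same knots."""
        rng = np.random.default_rng(1)
        x = np.sort(rng.uniform(0, 3500, 40))
        np.savetxt(tmp_path / "x.txt", x)
        r_code = (
            f'x <- scan("{tmp_path / "x.txt"}"); '
            "b <- splines::ns(x, knots=c(220,500,2500), Boundary.knots=c(0,3500)); "
            f'write.csv(unclass(b), "{tmp_path / "b.csv"}", row.names=FALSE)'
        )
        proc = subprocess.run(["Rscript", "-e", r_code], capture_output=True, text=True)
        assert proc.returncode == 0, proc.stderr
        Rb = pd.read_csv(tmp_path / "b.csv").to_numpy()
        ours = rsf.natural_spline_basis(x, boundary=(0, 3500))
        A = np.c_[np.ones(len(x)), ours]
        for j in range(Rb.shape[1]):
            beta, *_ = np.linalg.lstsq(A, Rb[:, j], rcond=None)
            assert np.max(np.abs(Rb[:, j] - A @ beta)) < 1e-8

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            rsf.natural_spline_basis(np.full(10, 5.0))
        with pytest.raises(ValueError, match="increasing"):
            rsf.natural_spline_basis(np.arange(10.0), knots=[3, 2, 1])


class TestBuildDesign:
    @pytest.fixture(scope="class")
    def design(self, seascape):
        rng = np.random.default_rng(2)
        sea_rc = np.argwhere(~seascape.land)

        def pts(n, r):
            rc = sea_rc[r.integers(len(sea_rc), size=n)]
            return pd.DataFrame(
                {
                    "x": seascape.x0 + (rc[:, 1] + 0.5) * seascape.cell,
                    "y": seascape.y0 + (rc[:, 0] + 0.5) * seascape.cell,
                }
            )

        used = pts(120, rng)
        used["segment"] = np.arange(120) % 3
        sims = {
            s: [pts(40, rng)[["x", "y"]].to_numpy() for _ in range(20)] for s in range(3)
        }
        return rsf.build_design(used, sims, seascape)

    def test_standardized_columns_centred_and_scaled(self, design):
        d, _ = design
        for col in ("sst", "ice", "ice_sq", "dpth_1"):
            assert abs(d[col].mean()) < 1e-9
            assert abs(d[col].std(ddof=0) - 1.0) < 1e-9

    def test_ice_sq_is_standardized_square_of_standardized_ice(self, design):
        d, _ = design
        sq = d["ice"] ** 2
        sq = (sq - sq.mean()) / sq.std(ddof=0)
        np.testing.assert_allclose(d["ice_sq"], sq, atol=1e-9)

    def test_in_ice_follows_sign_of_edge_distance(self, design, seascape):
        d, _ = design
        signed = seascape.sample("dist_ice_edge", d["x"].to_numpy(), d["y"].to_numpy())
        ok = np.isfinite(signed)
        np.testing.assert_array_equal(d["in_ice"].to_numpy()[ok], (signed[ok] < 0).astype(float))

    def test_out_of_extent_location_errors_with_offenders(self, seascape):
        used = pd.DataFrame({"x": [seascape.x0 - 1e6], "y": [seascape.y0], "segment": [0]})
        with pytest.raises(ValueError, match="outside raster extent"):
            rsf.build_design(used, {}, seascape)


class TestRandomInterceptLogistic:
    def test_zero_variance_reduces_to_plain_logistic_vs_glm_oracle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        n = 800
        X = np.c_[np.ones(n), rng.normal(0, 1, (n, 2))]
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-(X @ [0.3, 1.0, -0.5])))).astype(float)
        beta, s2, ok = rsf.fit_ri_logistic(X, y, np.zeros(n, int), random_effect=False)
        oracle = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        assert np.max(np.abs(beta - oracle.params)) < 1e-6

    def test_recovers_random_intercept_variance(self):
        rng = np.random.default_rng(4)
        G, m = 60, 40
        v = rng.normal(0, 1.0, G)
        X = np.c_[np.ones(G * m), rng.normal(0, 1, G * m)]
        groups = np.repeat(np.arange(G), m)
        eta = X @ [0.0, 1.0] + v[groups]
        y = (rng.uniform(size=G * m) < 1 / (1 + np.exp(-eta))).astype(float)
        beta, s2, ok = rsf.fit_ri_logistic(X, y, groups)
        assert abs(beta[1] - 1.0) < 0.15
        assert 0.4 < s2 < 2.0


def _mc_design_from_testset(seascape, beta, n_segments, n_per_seg, seed, covs=("sst",)):
    used, avail, truth = generate_rsf_testset(
        seascape, dict.fromkeys(covs, 0.0) | beta, n_used=n_segments * n_per_seg,
        seed=seed, n_segments=n_segments,
    )
    rows = [used.assign(use=1, sim=-1)]
    for k in range(20):
        av = avail(n_segments * n_per_seg, seed_=10_000 + 97 * seed + k)
        av["segment"] = np.arange(len(av)) % n_segments
        rows.append(av.assign(use=0, sim=k))
    return pd.concat(rows, ignore_index=True)


class TestMonteCarloRSF:
    def test_wrong_simulation_count_rejected(self, seascape):
        d = _mc_design_from_testset(seascape, {"sst": 0.0}, 4, 10, seed=0)
        d = d[d["sim"] < 15]  # only 15 sims left
        with pytest.raises(ValueError, match="expected 20"):
            rsf.fit_mc_rsf(d, ["sst"], seed=0)

    def test_identical_datasets_degenerate_aggregation_warns(self, seascape):
        d = _mc_design_from_testset(seascape, {"sst": 0.5}, 4, 10, seed=1)
        one = d[(d["sim"] <= 0)].copy()
        dup = [one]
        for k in range(1, 20):  # 20 identical availability sets
            nxt = one[one["sim"] == 0].copy()
            nxt["sim"] = k
            dup.append(nxt)
        d2 = pd.concat(dup, ignore_index=True).drop_duplicates(ignore_index=True)
        d2 = pd.concat(
            [one[one["sim"] == -1]]
            + [one[one["sim"] == 0].assign(sim=k) for k in range(20)],
            ignore_index=True,
        )
        with pytest.warns(UserWarning, match="degenerate"):
            res = rsf.fit_mc_rsf(d2, ["sst"], seed=2)
        assert np.isnan(res.table.set_index("covariate").loc["sst", "p"])

    def test_aggregation_invariant_to_dataset_and_row_order(self, seascape):
        d = _mc_design_from_testset(seascape, {"sst": 0.6}, 6, 12, seed=3)
        r1 = rsf.fit_mc_rsf(d, ["sst"], seed=5)
        # aggregation is symmetric in the 20 fits: permuting the per-fit
        # matrix leaves mean/SD identical
        perm = r1.per_fit.sample(frac=1.0, random_state=1)
        np.testing.assert_allclose(perm.mean(), r1.per_fit.mean(), rtol=0, atol=1e-12)
        np.testing.assert_allclose(perm.std(ddof=1), r1.per_fit.std(ddof=1), rtol=0, atol=1e-12)
        # row permutation within datasets only perturbs fits at solver tolerance
        shuffled = d.sample(frac=1.0, random_state=0).reset_index(drop=True)
        r2 = rsf.fit_mc_rsf(shuffled, ["sst"], seed=5)
        np.testing.assert_allclose(
            r1.table["coef"].to_numpy(), r2.table["coef"].to_numpy(), atol=1e-3
        )

    def test_pipeline_deterministic_given_seed(self, seascape):
        d = _mc_design_from_testset(seascape, {"sst": 0.6}, 6, 12, seed=3)
        r1 = rsf.fit_mc_rsf(d, ["sst"], seed=5)
        r2 = rsf.fit_mc_rsf(d.copy(), ["sst"], seed=5)
        np.testing.assert_array_equal(r1.per_fit.to_numpy(), r2.per_fit.to_numpy())

    def test_balanced_null_gives_near_zero_coefficients(self, seascape):
        d = _mc_design_from_testset(seascape, {"sst": 0.0}, 30, 20, seed=6)
        res = rsf.fit_mc_rsf(d, ["sst"], seed=7)
        tab = res.table.set_index("covariate")
        assert abs(tab.loc["sst", "coef"]) < 0.1
        assert abs(tab.loc["_intercept", "coef"]) < 0.1


class TestBackwardStepwise:
    def test_all_significant_returns_full_model(self, seascape):
        d = _mc_design_from_testset(seascape, {"sst": 1.0, "ssh": 0.8}, 40, 20, seed=8,
                                    covs=("sst", "ssh"))
        res = rsf.backward_stepwise(d, ["sst", "ssh"], seed=9)
        assert res.covariates == ["sst", "ssh"]
        assert res.dropped == []

    def test_noise_covariate_dropped_first(self, seascape):
        drops = []
        for seed in range(8):
            d = _mc_design_from_testset(
                seascape, {"sst": 1.2, "ssh": 0.0}, 40, 20, seed=20 + seed,
                covs=("sst", "ssh"),
            )
            res = rsf.backward_stepwise(d, ["sst", "ssh"], seed=seed)
            drops.append([x["term"] for x in res.dropped])
        first_drops = [d[0] for d in drops if d]
        assert first_drops.count("ssh") >= 0.9 * len(first_drops)
        assert all("sst" not in d for d in drops)

    def test_tie_drops_later_declared_covariate(self, monkeypatch, seascape):
        d = _mc_design_from_testset(seascape, {"sst": 0.0, "ssh": 0.0}, 6, 10, seed=30,
                                    covs=("sst", "ssh"))
        calls = {}

        real = rsf.fit_mc_rsf

        def fake(design, covariates=None, **kw):
            res = real(design, covariates, **kw)
            res.table["p"] = np.where(
                res.table["covariate"] == "_intercept", 0.0, 0.5
            )  # perfect tie above alpha
            calls.setdefault("first", [x for x in covariates or []])
            return res

        monkeypatch.setattr(rsf, "fit_mc_rsf", fake)
        res = rsf.backward_stepwise(d, ["sst", "ssh"], seed=31)
        assert res.dropped[0]["term"] == "ssh"  # later in declaration order
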