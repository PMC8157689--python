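"""VIF, dbMEM, RDA/varpart, LFMM and Mantel against closed forms/oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from popadapt import SimConfig
from popadapt.envassoc import (
    dbmem,
    forward_select,
    hellinger_transform,
    ibd_ibe_distances,
    lfmm,
    mantel,
    rda_fit,
    varpart,
    varpart_from_adj_r2,
    vif_prune,
)
from popadapt.io import SampleMetadata
from popadapt.simulate import simulate_coordinates, simulate_environment, simulate_genotypes


class TestVifPrune:
    def test_orthogonal_variables_all_kept(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((40, 4))
        Q, _ = np.linalg.qr(X)
        env = pd.DataFrame(Q, columns=list("abcd"))
        assert vif_prune(env) == list("abcd")

    def test_two_variable_closed_form(self):
        # corr 0.9 -> VIF = 1/(1-0.81) = 5.263 < 10 -> both kept
        rng = np.random.default_rng(1)
        n = 2000
        a = rng.standard_normal(n)
        b = 0.9 * a + np.sqrt(1 - 0.81) * rng.standard_normal(n)
        env = pd.DataFrame({"a": a, "b": b})
        from popadapt.envassoc import _vif

        vifs = _vif(env.to_numpy())
        r2 = np.corrcoef(a, b)[0, 1] ** 2
        assert vifs[0] == pytest.approx(1 / (1 - r2), rel=1e-9)
        assert vif_prune(env) == ["a", "b"]

    def test_exact_linear_combination_drops_exactly_one(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal(30)
        b = rng.standard_normal(30)
        env = pd.DataFrame({"a": a, "b": b, "c": a + b})
        kept = vif_prune(env)
        assert len(kept) == 2
        # the later-listed member of the collinear set goes first
        assert kept == ["a", "b"]


class TestDbmem:
    def _coords(self, lons, lats):
        return pd.DataFrame({"lon": lons, "lat": lats},
                            index=[f"S{i}" for i in range(len(lons))])

    def test_eigenvectors_orthogonal_and_fewer_than_sites(self):
        cfg = SimConfig(seed=4)
        coords = simulate_coordinates(cfg)
        mems = dbmem(coords)
        M = mems.to_numpy()
        gram = M.T @ M
        assert np.allclose(gram - np.diag(np.diag(gram)), 0.0, atol=1e-8)
        assert mems.shape[1] < len(coords)

    def test_transect_first_mem_is_broad_scale_trend(self):
        """On a regular transect the leading MEM is the broad-scale
        sinusoid-like wave tracking position (|r| with the coordinate high);
        later MEMs oscillate faster (more sign changes)."""
        coords = self._coords(np.linspace(100, 104, 9), np.full(9, 25.0))
        mems = dbmem(coords)
        v = mems["dbMEM1"].to_numpy()
        r = np.corrcoef(v, np.arange(9))[0, 1]
        assert abs(r) > 0.85
        crossings = [int(np.sum(np.diff(np.sign(mems.iloc[:, k])) != 0))
                     for k in range(3)]
        assert crossings[0] <= crossings[2]

    def test_identical_sites_rejected(self):
        coords = self._coords([110.0] * 4, [25.0] * 4)
        with pytest.raises(ValueError):
            dbmem(coords)


class TestHellinger:
    def test_row_examples_and_normalization(self):
        out = hellinger_transform(np.array([[1.0, 1.0]]))
        np.testing.assert_allclose(out, [[np.sqrt(0.5), np.sqrt(0.5)]])
        rng = np.random.default_rng(5)
        X = rng.integers(0, 3, (6, 10)).astype(float) + 0.1
        H = hellinger_transform(X)
        np.testing.assert_allclose((H**2).sum(axis=1), 1.0, atol=1e-12)
        row = X[2]
        np.testing.assert_allclose(H[2], np.sqrt(row / row.sum()))

    def test_zero_row_rejected(self):
        with pytest.raises(ValueError):
            hellinger_transform(np.zeros((2, 3)))


class TestRda:
    def test_exact_linear_response_gives_r2_one(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((15, 2))
        B = rng.standard_normal((2, 5))
        res = rda_fit(X @ B, X, n_perm=49, seed=0)
        assert res.r2 == pytest.approx(1.0, abs=1e-10)
        assert res.adj_r2 == pytest.approx(1.0, abs=1e-10)
        assert res.p_value <= 0.05

    def test_small_system_matches_hat_matrix_oracle(self):
        rng = np.random.default_rng(7)
        Y = rng.standard_normal((6, 3))
        X = rng.standard_normal((6, 2))
        res = rda_fit(Y, X, n_perm=0)
        Yc = Y - Y.mean(axis=0)
        Xc = np.column_stack([np.ones(6), X - X.mean(axis=0)])
        H = Xc @ np.linalg.pinv(Xc)
        Yhat = H @ Yc
        r2 = np.sum(Yhat**2) / np.sum(Yc**2)
        assert res.r2 == pytest.approx(r2, abs=1e-12)
        assert res.adj_r2 == pytest.approx(1 - (1 - r2) * 5 / 3, abs=1e-12)
        np.testing.assert_allclose(
            np.sort(res.eigenvalues)[::-1],
            np.sort(np.linalg.svd(Yhat, compute_uv=False)[:2] ** 2 / 5)[::-1],
            atol=1e-12,
        )

    def test_null_p_uniform(self):
        ps = []
        for s in range(100):
            rng = np.random.default_rng(s)
            ps.append(
                rda_fit(rng.standard_normal((20, 10)),
                        rng.standard_normal((20, 3)), n_perm=99, seed=s).p_value
            )
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_too_many_predictors_rejected(self):
        rng = np.random.default_rng(8)
        with pytest.raises(ValueError):
            rda_fit(rng.standard_normal((5, 3)), rng.standard_normal((5, 5)))


class TestForwardSelect:
    def test_predictive_variable_selected_first(self):
        rng = np.random.default_rng(9)
        n = 40
        x_true = rng.standard_normal(n)
        Y = np.outer(x_true, rng.standard_normal(8)) + 0.3 * rng.standard_normal((n, 8))
        X = pd.DataFrame(
            {"noise1": rng.standard_normal(n), "signal": x_true,
             "noise2": rng.standard_normal(n)}
        )
        sel = forward_select(Y, X, n_perm=99, seed=0)
        assert sel[0] == "signal"

    def test_pure_noise_selects_nothing_mostly(self):
        empties = 0
        for s in range(20):
            rng = np.random.default_rng(s)
            Y = rng.standard_normal((25, 10))
            X = pd.DataFrame(rng.standard_normal((25, 5)), columns=list("abcde"))
            empties += len(forward_select(Y, X, n_perm=99, seed=s)) <= 1
        assert empties >= 18

    def test_alpha_one_without_cap_admits_everything(self):
        rng = np.random.default_rng(10)
        Y = rng.standard_normal((20, 6))
        X = pd.DataFrame(rng.standard_normal((20, 4)), columns=list("abcd"))
        sel = forward_select(Y, X, n_perm=9, alpha=1.0, seed=1,
                             use_adj_r2_cap=False)
        assert sorted(sel) == list("abcd")


class TestVarpart:
    def test_fraction_identity_sums_to_one(self):
        rng = np.random.default_rng(11)
        Y = rng.standard_normal((30, 12))
        Xe = rng.standard_normal((30, 3))
        Xg = 0.5 * Xe[:, :2] + rng.standard_normal((30, 2))
        res = varpart(Y, Xe, Xg, n_perm=49, seed=0)
        assert sum(res.fractions().values()) == pytest.approx(1.0, abs=1e-9)

    def test_identical_predictors_have_no_pure_fractions(self):
        rng = np.random.default_rng(12)
        Y = rng.standard_normal((25, 8))
        X = rng.standard_normal((25, 3))
        res = varpart(Y, X, X, n_perm=0)
        assert res.a == pytest.approx(0.0, abs=1e-10)
        assert res.c == pytest.approx(0.0, abs=1e-10)
        assert res.b == pytest.approx(res.adj_env, abs=1e-10)


class TestLfmm:
    def test_k_zero_equals_direct_regression_oracle(self):
        rng = np.random.default_rng(13)
        n, L = 30, 40
        G = rng.binomial(2, 0.4, (n, L)).astype(float)
        x = rng.standard_normal(n)
        env = pd.DataFrame({"e": x})
        res = lfmm(G, env, K=0, n_repetitions=1, seed=0)
        # oracle: per-locus OLS t-statistics
        Gc = G - G.mean(axis=0)
        xc = x - x.mean()
        design = np.column_stack([np.ones(n), xc])
        coef, *_ = np.linalg.lstsq(design, Gc, rcond=None)
        resid = Gc - design @ coef
        s2 = (resid**2).sum(axis=0) / (n - 2)
        se = np.sqrt(s2 * np.linalg.inv(design.T @ design)[1, 1])
        z_oracle = coef[1] / se
        np.testing.assert_allclose(res.z["e"].to_numpy(), z_oracle, atol=1e-8)

    def test_constant_variable_rejected(self):
        rng = np.random.default_rng(14)
        G = rng.binomial(2, 0.5, (10, 5)).astype(float)
        with pytest.raises(ValueError):
            lfmm(G, pd.DataFrame({"e": np.ones(10)}), K=2)

    def test_null_calibration_and_fpr(self):
        """Confounded null (structured env independent of drift): calibrated
        p-values give a false-positive rate near nominal at p<0.005."""
        fprs = []
        for s in range(5):
            cfg = SimConfig(n_pops=10, n_ind_per_pop=[10] * 10, n_loci=1000,
                            fst_target=0.15, seed=300 + s)
            G, t = simulate_genotypes(cfg)
            rng = np.random.default_rng(1000 + s)
            env = pd.DataFrame({"e": np.repeat(rng.standard_normal(10), 10)})
            res = lfmm(G, env, K=4, n_repetitions=5, seed=s)
            fprs.append(float((res.p["e"] < 0.005).mean()))
        assert np.mean(fprs) <= 0.015  # within 3x nominal


class TestMantel:
    def test_affine_relationship_gives_unit_r(self):
        rng = np.random.default_rng(15)
        pts = rng.standard_normal((6, 2))
        from scipy.spatial.distance import pdist, squareform

        A = squareform(pdist(pts))
        B = 2.0 * A + 3.0
        np.fill_diagonal(B, 0.0)
        res = mantel(A, B, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0, abs=1e-9)

    def test_four_by_four_matches_exhaustive_enumeration(self):
        A = np.array([[0, 1, 2, 3], [1, 0, 4, 5], [2, 4, 0, 6], [3, 5, 6, 0]], float)
        B = A[np.ix_([1, 0, 3, 2], [1, 0, 3, 2])] + 0.1
        np.fill_diagonal(B, 0.0)
        iu = np.tril_indices(4, -1)
        obs = np.corrcoef(A[iu], B[iu])[0, 1]
        count = sum(
            np.corrcoef(A[np.ix_(p, p)][iu], B[iu])[0, 1] >= obs - 1e-12
            for p in itertools.permutations(range(4))
        )
        exact_p = count / 24.0
        res = mantel(A, B, n_perm=999, seed=3)
        assert res.r == pytest.approx(obs, abs=1e-12)
        assert res.p == pytest.approx(exact_p, abs=0.06)

    def test_invariant_to_joint_relabeling(self):
        rng = np.random.default_rng(16)
        from scipy.spatial.distance import pdist, squareform

        A = squareform(pdist(rng.standard_normal((7, 2))))
        B = squareform(pdist(rng.standard_normal((7, 3))))
        perm = rng.permutation(7)
        r1 = mantel(A, B, n_perm=0 or 9, seed=0).r
        r2 = mantel(A[np.ix_(perm, perm)], B[np.ix_(perm, perm)], n_perm=9, seed=0).r
        assert r1 == pytest.approx(r2, abs=1e-12)


class TestIbdIbeDistances:
    def _meta(self, lons, lats):
        pops = [f"P{i}" for i in range(len(lons))]
        return SampleMetadata(pd.DataFrame(
            {"population": pops, "group": ["G"] * len(pops),
             "lon": lons, "lat": lats, "altitude": [1000.0] * len(pops)},
            index=[f"{p}_1" for p in pops],
        ))

    def test_one_degree_meridian_is_111km(self):
        meta = self._meta([110.0, 110.0], [24.0, 25.0])
        env = pd.DataFrame({"e1": [0.0, 1.0], "e2": [1.0, 0.0]},
                           index=["P0", "P1"])
        with pytest.warns(UserWarning):  # PC cap at n_sites - 1
            geo, _ = ibd_ibe_distances(meta, env)
        assert geo.iloc[0, 1] == pytest.approx(111.2, abs=0.3)

    def test_identical_environments_give_zero_distance(self):
        # all sites share one environment: every pairwise distance is 0
        meta = self._meta([110.0, 111.0, 112.0], [24.0, 25.0, 24.5])
        env = pd.DataFrame(np.tile([1.0, 2.0, 3.0, 4.0], (3, 1)),
                           index=["P0", "P1", "P2"],
                           columns=list("abcd"))
        with pytest.warns(UserWarning):
            _, envd = ibd_ibe_distances(meta, env)
        assert np.allclose(envd.to_numpy(), 0.0, atol=1e-9)

    def test_three_site_pca_hand_check(self):
        meta = self._meta([110.0, 111.0, 112.0], [24.0, 25.0, 24.5])
        env = pd.DataFrame({"a": [0.0, 1.0, 2.0], "b": [2.0, 1.0, 0.0]},
                           index=["P0", "P1", "P2"])
        _, envd = ibd_ibe_distances(meta, env, n_env_pcs=2)
        # standardized variables are perfectly anticorrelated: one PC carries
        # everything; distances proportional to |a_i - a_j| standardized
        z = (env["a"] - 1.0) / env["a"].std(ddof=0)
        expected = abs(z.iloc[0] - z.iloc[1]) * np.sqrt(2)
        assert envd.iloc[0, 1] == pytest.approx(expected, abs=1e-9)
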