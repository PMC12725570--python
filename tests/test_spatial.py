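"""Spatial statistics and the random-forest attribution model."""

import numpy as np
import pandas as pd
import pytest

from fcnflow.errors import NoPredictorsError, TooFewSitesError
from fcnflow.spatial import (
    SpatialRandomForest,
    SpatialWeights,
    compute_vifs,
    default_thresholds,
    mem_spatial_predictors,
    morans_i,
    prune_predictors,
    spearman_screen,
)


@pytest.fixture
def grid_weights():
    rng = np.random.default_rng(20)
    coords = rng.uniform(0, 10, size=(20, 2))
    thr = default_thresholds(coords)[1]
    return coords, SpatialWeights.from_coords(coords, thr)


class TestMoransI:
    def test_hand_computed_five_site_instance(self):
        coords = np.array([[0, 0], [1, 0], [2, 0], [0, 1], [1, 1]], dtype=float)
        x = np.array([1.0, 2.0, 4.0, 2.0, 3.0])
        w = SpatialWeights.from_coords(coords, threshold=1.5)
        got = morans_i(x, w, n_perm=0)
        # independent oracle: explicit double sum over the weight matrix
        z = x - x.mean()
        W = w.weights
        num = sum(
            W[i, j] * z[i] * z[j] for i in range(5) for j in range(5)
        )
        expected = (5 / W.sum()) * num / (z @ z)
        assert got.I == pytest.approx(expected, abs=1e-12)
        assert got.expected_I == pytest.approx(-0.25)

    def test_permutation_null_mean_matches_closed_form(self, grid_weights):
        _, w = grid_weights
        rng = np.random.default_rng(21)
        vals = np.array([morans_i(rng.normal(size=20), w, n_perm=0).I for _ in range(3000)])
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - (-1 / 19)) < 4 * se + 1e-4

    def test_gradient_on_line_is_positive_and_significant(self):
        coords = np.column_stack([np.arange(25, dtype=float), np.zeros(25)])
        w = SpatialWeights.from_coords(coords, threshold=1.5)
        res = morans_i(np.arange(25, dtype=float), w, n_perm=999, seed=4)
        assert res.I > 0
        assert res.p_value <= 0.05

    def test_zero_variance_rejected(self, grid_weights):
        _, w = grid_weights
        with pytest.raises(ValueError):
            morans_i(np.ones(20), w, n_perm=99)


class TestMEM:
    def test_eigenvectors_orthogonal(self, grid_weights):
        _, w = grid_weights
        mems = mem_spatial_predictors(w)
        m = mems.to_numpy()
        gram = m.T @ m
        assert np.allclose(gram - np.diag(np.diag(gram)), 0.0, atol=1e-8)

    def test_first_mem_has_maximal_moran(self, grid_weights):
        _, w = grid_weights
        mems = mem_spatial_predictors(w)
        scores = [
            morans_i(mems.iloc[:, k].to_numpy(), w, n_perm=0).I
            for k in range(mems.shape[1])
        ]
        assert scores[0] == pytest.approx(max(scores), abs=1e-8)

    def test_eigenvalues_match_dense_eigensolver(self):
        rng = np.random.default_rng(22)
        coords = rng.uniform(0, 5, size=(10, 2))
        w = SpatialWeights.from_coords(coords, threshold=3.0)
        mems = mem_spatial_predictors(w)
        a = 0.5 * (w.raw + w.raw.T)
        h = np.eye(10) - np.ones((10, 10)) / 10
        all_vals = np.sort(np.linalg.eigvalsh(h @ a @ h))[::-1]
        got = mems.attrs["eigenvalues"]
        assert got == pytest.approx(all_vals[: len(got)], abs=1e-9)


class TestPruning:
    def test_orthogonal_predictors_kept_with_unit_vif(self):
        rng = np.random.default_rng(23)
        X = pd.DataFrame(rng.normal(size=(200, 2)), columns=["a", "b"])
        X["b"] -= X["a"] * (X["a"] @ X["b"]) / (X["a"] @ X["a"])
        kept, log = prune_predictors(X, rng.normal(size=200))
        assert kept == ["a", "b"]
        assert compute_vifs(X[kept]).max() < 1.2

    def test_duplicated_column_keeps_exactly_one(self):
        rng = np.random.default_rng(24)
        a = rng.normal(size=100)
        X = pd.DataFrame({"a": a, "a_copy": a, "c": rng.normal(size=100)})
        y = a + rng.normal(scale=0.1, size=100)
        kept, log = prune_predictors(X, y)
        assert sum(c in kept for c in ("a", "a_copy")) == 1
        assert "c" in kept

    def test_zero_variance_dropped_first(self):
        rng = np.random.default_rng(25)
        X = pd.DataFrame({"zv": np.ones(50), "x": rng.normal(size=50)})
        kept, log = prune_predictors(X, rng.normal(size=50))
        assert kept == ["x"]
        assert log.iloc[0]["reason"] == "ZV"

    def test_keeps_more_response_relevant_member(self):
        rng = np.random.default_rng(26)
        sig = rng.normal(size=300)
        proxy = sig + rng.normal(scale=0.3, size=300)  # r ≈ 0.96
        y = sig + rng.normal(scale=0.5, size=300)
        X = pd.DataFrame({"signal": sig, "proxy": proxy})
        kept, _ = prune_predictors(X, y)
        assert kept == ["signal"]

    def test_vif_matches_regression_definition(self):
        from statsmodels.stats.outliers_influence import variance_inflation_factor
        from statsmodels.tools import add_constant

        rng = np.random.default_rng(27)
        X = pd.DataFrame(rng.normal(size=(80, 4)), columns=list("abcd"))
        X["d"] = X["a"] * 0.8 + X["b"] * 0.3 + rng.normal(scale=0.5, size=80)
        ours = compute_vifs(X)
        design = add_constant(X).to_numpy()
        theirs = [variance_inflation_factor(design, k + 1) for k in range(4)]
        assert ours.to_numpy() == pytest.approx(theirs, rel=1e-6)

    def test_output_satisfies_both_thresholds_on_random_instances(self):
        rng = np.random.default_rng(28)
        for trial in range(30):
            n, p = 60, 10
            base = rng.normal(size=(n, 4))
            mix = rng.normal(size=(4, p))
            X = pd.DataFrame(base @ mix + rng.normal(scale=0.6, size=(n, p)),
                             columns=[f"v{j}" for j in range(p)])
            y = base[:, 0] + rng.normal(size=n)
            kept, _ = prune_predictors(X, y)
            if len(kept) > 1:
                corr = X[kept].corr().abs().to_numpy()
                np.fill_diagonal(corr, 0.0)
                assert corr.max() <= 0.75 + 1e-9
                assert compute_vifs(X[kept]).max() <= 5.0 + 1e-9

    def test_all_zero_variance_raises(self):
        X = pd.DataFrame({"a": np.ones(20), "b": np.zeros(20)})
        with pytest.raises(NoPredictorsError):
            prune_predictors(X, np.arange(20.0))


def _simulated_sites(n, seed, spatial_effect=0.0, signal=True):
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0, 100, size=(n, 2))
    X = pd.DataFrame(rng.normal(size=(n, 4)), columns=["p1", "p2", "p3", "noise"])
    y = rng.normal(scale=0.5, size=n)
    if signal:
        y = y + 2.0 * X["p1"].to_numpy() + 1.0 * X["p2"].to_numpy()
    if spatial_effect:
        y = y + spatial_effect * np.sin(coords[:, 0] / 15.0)
    return X, y, coords


class TestSpatialRandomForest:
    def test_same_seed_identical_results(self):
        X, y, coords = _simulated_sites(60, seed=30)
        r1 = SpatialRandomForest(y, X, coords).fit(n_runs=3, seed=9, n_perm_moran=99)
        r2 = SpatialRandomForest(y, X, coords).fit(n_runs=3, seed=9, n_perm_moran=99)
        assert np.array_equal(r1.oob_r2, r2.oob_r2)
        pd.testing.assert_frame_equal(r1.importances, r2.importances)

    def test_unstructured_response_rarely_adds_spatial_predictors(self):
        """Without planted spatial structure the residual diagnostics should
        stay quiet in the large majority of replicates (each of the three
        thresholds can fire spuriously at the 5% level)."""
        clean = 0
        for k in range(10):
            X, y, coords = _simulated_sites(80, seed=310 + k, spatial_effect=0.0)
            res = SpatialRandomForest(y, X, coords).fit(n_runs=1, seed=1, n_perm_moran=199)
            clean += res.spatial_predictors_used == []
        assert clean >= 7

    def test_planted_gradient_triggers_mem_and_clears_residuals(self):
        X, y, coords = _simulated_sites(120, seed=32, spatial_effect=3.0, signal=False)
        res = SpatialRandomForest(y, X, coords).fit(n_runs=2, seed=2, n_perm_moran=199)
        assert len(res.spatial_predictors_used) >= 1
        assert all(m.p_value > 0.05 for m in res.residual_moran)

    def test_too_few_sites_rejected(self):
        X, y, coords = _simulated_sites(10, seed=33)
        with pytest.raises(TooFewSitesError):
            SpatialRandomForest(y, X, coords)

    def test_importance_identifies_planted_signal(self):
        X, y, coords = _simulated_sites(150, seed=34)
        res = SpatialRandomForest(y, X, coords).fit(n_runs=5, seed=3, n_perm_moran=99)
        assert res.importance_rank("p1") == 1
        assert res.median_importance()["p1"] > res.median_importance()["noise"]

    def test_summary_mentions_key_quantities(self):
        X, y, coords = _simulated_sites(60, seed=35)
        res = SpatialRandomForest(y, X, coords).fit(n_runs=2, seed=4, n_perm_moran=99)
        text = res.summary()
        assert "OOB R2" in text and "Moran" in text


class TestPartialDependence:
    def test_null_predictor_near_flat(self):
        X, y, coords = _simulated_sites(150, seed=36)
        res = SpatialRandomForest(y, X, coords).fit(n_runs=3, seed=5, n_perm_moran=99)
        curve = res.partial_dependence("noise", grid_size=15)
        spread = curve["prediction"].max() - curve["prediction"].min()
        assert spread < 0.05 * (y.max() - y.min())

    def test_monotone_planted_effect_recovered(self):
        from scipy.stats import spearmanr

        X, y, coords = _simulated_sites(150, seed=37)
        res = SpatialRandomForest(y, X, coords).fit(n_runs=3, seed=6, n_perm_moran=99)
        curve = res.partial_dependence("p1", grid_size=20)
        rho = spearmanr(curve["p1"], curve["prediction"]).statistic
        assert rho >= 0.9

    def test_unknown_predictor_rejected(self):
        X, y, coords = _simulated_sites(60, seed=38)
        res = SpatialRandomForest(y, X, coords).fit(n_runs=2, seed=7, n_perm_moran=99)
        with pytest.raises(KeyError):
            res.partial_dependence("not_there")


def test_spearman_screen_shape():
    rng = np.random.default_rng(39)
    X = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
    out = spearman_screen(X, X["a"] + rng.normal(size=50))
    assert list(out.index) == list("abc")
    assert out.loc["a", "spearman_r"] > 0.5
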