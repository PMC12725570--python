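"""Temporal beta-diversity: decomposition, permutation tests, species tables."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fcnflow.errors import ShapeMismatchError, TooFewSitesError
from fcnflow.tbi import (
    CommunityPair,
    dominance_test,
    occupancy_change,
    species_paired_tests,
    tbi_components,
    tbi_permutation_test,
)


def pair_from(t1, t2):
    t1, t2 = np.atleast_2d(t1), np.atleast_2d(t2)
    return CommunityPair(
        sites=[f"s{i}" for i in range(t1.shape[0])],
        species=[f"x{j}" for j in range(t1.shape[1])],
        t1=t1,
        t2=t2,
    )


class TestComponents:
    def test_identical_nonempty_row_zero_dissimilarity(self):
        res = tbi_components(pair_from([[1, 1, 0]], [[1, 1, 0]]))
        assert res["D"].iloc[0] == 0.0

    def test_formula_forced_counts(self):
        res = tbi_components(pair_from([[1, 1, 1, 0]], [[1, 0, 0, 1]]))
        row = res.iloc[0]
        assert (row["a"], row["b"], row["c"]) == (1, 2, 1)
        assert row["D"] == pytest.approx(0.6)
        assert row["B"] == pytest.approx(0.4)
        assert row["C"] == pytest.approx(0.2)

    def test_disjoint_nonempty_rows_total_turnover(self):
        res = tbi_components(pair_from([[1, 1, 0, 0]], [[0, 0, 1, 1]]))
        assert res["D"].iloc[0] == 1.0

    def test_empty_both_periods_undefined(self):
        res = tbi_components(pair_from([[0, 0]], [[0, 0]]))
        assert np.isnan(res["D"].iloc[0])

    def test_shape_mismatch_raises(self):
        with pytest.raises(ShapeMismatchError):
            CommunityPair(sites=["s"], species=["x", "y"],
                          t1=np.zeros((1, 2)), t2=np.zeros((2, 2)))

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.integers(0, 2**20 - 1), st.integers(0, 2**20 - 1))
    def test_decomposition_identities(self, bits1, bits2):
        """D = B + C exactly; 0 ≤ B, C ≤ D ≤ 1; marginals recover richness."""
        r1 = [(bits1 >> k) & 1 for k in range(20)]
        r2 = [(bits2 >> k) & 1 for k in range(20)]
        row = tbi_components(pair_from([r1], [r2])).iloc[0]
        assert row["a"] + row["b"] == sum(r1)
        assert row["a"] + row["c"] == sum(r2)
        if row["denom"] > 0:
            assert row["D"] == row["B"] + row["C"]
            assert 0.0 <= row["B"] <= row["D"] <= 1.0
            assert 0.0 <= row["C"] <= row["D"]

    def test_presence_conservation_across_sites(self):
        rng = np.random.default_rng(11)
        t1 = (rng.random((40, 15)) < 0.4).astype(int)
        t2 = (rng.random((40, 15)) < 0.4).astype(int)
        res = tbi_components(pair_from(t1, t2))
        assert (res["a"] + res["b"]).sum() == t1.sum()
        assert (res["a"] + res["c"]).sum() == t2.sum()


class TestPermutationTest:
    def test_unchanged_site_has_p_one(self):
        t = np.array([[1, 1, 0], [1, 0, 1], [0, 1, 1], [1, 1, 1]])
        res = tbi_permutation_test(pair_from(t, t), n_perm=199, seed=0)
        assert (res["p_value"] == 1.0).all()

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(12)
        t1 = (rng.random((12, 8)) < 0.5).astype(int)
        t2 = (rng.random((12, 8)) < 0.5).astype(int)
        a = tbi_permutation_test(pair_from(t1, t2), n_perm=299, seed=7)
        b = tbi_permutation_test(pair_from(t1, t2), n_perm=299, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_matches_exhaustive_enumeration_oracle(self):
        """Monte-Carlo p converges to the exact tail over the full permutation
        group on a tiny instance (3 sites × 2 species → 6^4 group elements)."""
        t1 = np.array([[1, 1], [1, 0], [0, 0]])
        t2 = np.array([[0, 1], [1, 1], [1, 0]])
        pair = pair_from(t1, t2)
        obs = tbi_components(pair)["D"].to_numpy()

        def site_d(m1, m2, s):
            a = int(np.sum(m1[s] & m2[s]))
            b = int(np.sum(m1[s] & ~m2[s]))
            c = int(np.sum(~m1[s] & m2[s]))
            denom = 2 * a + b + c
            return np.nan if denom == 0 else (b + c) / denom

        perms = list(itertools.permutations(range(3)))
        exact_ge = np.zeros(3)
        total = 0
        for pa in perms:
            for pb in perms:
                m1 = np.stack([t1[list(pa), 0], t1[list(pb), 1]], axis=1).astype(bool)
                for pc in perms:
                    for pd_ in perms:
                        m2 = np.stack([t2[list(pc), 0], t2[list(pd_), 1]], axis=1).astype(bool)
                        total += 1
                        for s in range(3):
                            d = site_d(m1, m2, s)
                            if not np.isnan(d) and d >= obs[s] - 1e-12:
                                exact_ge[s] += 1
        exact_tail = exact_ge / total

        res = tbi_permutation_test(pair, n_perm=20000, seed=3, batch_size=2000)
        mc_tail = (res["p_value"].to_numpy() * (1 + 20000) - 1) / 20000
        assert mc_tail == pytest.approx(exact_tail, abs=0.02)

    def test_pooled_scheme_runs_and_is_seeded(self):
        rng = np.random.default_rng(13)
        t1 = (rng.random((10, 6)) < 0.5).astype(int)
        t2 = (rng.random((10, 6)) < 0.5).astype(int)
        a = tbi_permutation_test(pair_from(t1, t2), n_perm=99, seed=1,
                                 scheme="columns_pooled_periods")
        b = tbi_permutation_test(pair_from(t1, t2), n_perm=99, seed=1,
                                 scheme="columns_pooled_periods")
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            tbi_permutation_test(pair_from([[1]], [[1]]), scheme="bogus")


class TestDominance:
    def test_pure_loss_direction(self):
        t1 = np.ones((6, 4), dtype=int)
        t2 = t1.copy()
        t2[:, :2] = 0  # every site loses two species, gains none
        res = tbi_permutation_test(pair_from(t1, t2), n_perm=99, seed=0)
        dom = dominance_test(res, n_perm=999, seed=0)
        assert dom["direction"] == "loss"
        assert dom["mean_C"] == 0.0

    def test_symmetric_change_is_none(self):
        # every site loses one species and gains one: B == C per site
        t1 = np.tile([1, 1, 0, 0], (8, 1))
        t2 = np.tile([1, 0, 1, 0], (8, 1))
        res = tbi_permutation_test(pair_from(t1, t2), n_perm=99, seed=0)
        dom = dominance_test(res, n_perm=999, seed=0)
        assert dom["direction"] == "none"
        assert dom["mean_B"] == pytest.approx(dom["mean_C"])

    def test_injected_loss_bias_recovered(self):
        """With loss probability well above gain probability the test should
        call 'loss' in nearly every replicate."""
        rng = np.random.default_rng(14)
        hits = 0
        n_rep = 40
        for _ in range(n_rep):
            t1 = (rng.random((30, 12)) < 0.6).astype(int)
            lose = rng.random(t1.shape) < 0.35
            gain = rng.random(t1.shape) < 0.03
            t2 = np.where(t1 == 1, 1 - lose, gain).astype(int)
            res = tbi_components(pair_from(t1, t2))
            res["p_value"] = np.nan
            dom = dominance_test(res, n_perm=499, seed=int(rng.integers(2**31 - 1)))
            hits += dom["direction"] == "loss"
        assert hits >= 0.95 * n_rep

    def test_too_few_sites(self):
        res = tbi_components(pair_from([[1, 0]], [[0, 1]]))
        with pytest.raises(TooFewSitesError):
            dominance_test(res)


class TestSpeciesTests:
    def test_unchanged_species_p_one(self):
        rng = np.random.default_rng(15)
        t1 = (rng.random((10, 3)) < 0.5).astype(int)
        res = species_paired_tests(pair_from(t1, t1.copy()), n_perm=199, seed=0)
        assert (res["p_raw"] == 1.0).all()

    def test_uniform_loss_reaches_minimum_attainable_p(self):
        """A species lost at every one of 12 occupied sites: the sign-flip
        tail equals the exhaustive two-sided minimum 2/2^12, so the add-one
        Monte-Carlo p must be near it."""
        n = 12
        t1 = np.ones((n, 1), dtype=int)
        t2 = np.zeros((n, 1), dtype=int)
        res = species_paired_tests(pair_from(t1, t2), n_perm=9999, seed=2)
        exact = 2.0 / 2**n  # both all-minus and all-plus flips tie |t| = inf
        p = res["p_raw"].iloc[0]
        assert p <= 0.001
        se = np.sqrt(exact * (1 - exact) / 9999)
        assert abs(p - exact) < 1e-4 + 4 * se

    def test_matches_exhaustive_sign_flip_oracle(self):
        rng = np.random.default_rng(16)
        n = 10
        t1 = (rng.random((n, 1)) < 0.7).astype(int)
        t2 = t1.copy()
        flip = rng.random((n, 1)) < 0.4
        t2[flip] = 1 - t2[flip]
        diff = (t2 - t1).ravel().astype(float)

        def tstat(d):
            sd = d.std(ddof=1)
            if sd == 0:
                return np.inf * np.sign(d.mean()) if d.mean() != 0 else 0.0
            return d.mean() / (sd / np.sqrt(len(d)))

        t_obs = abs(tstat(diff))
        count = 0
        for signs in itertools.product((-1.0, 1.0), repeat=n):
            if abs(tstat(diff * np.array(signs))) >= t_obs - 1e-12:
                count += 1
        exact = count / 2**n

        res = species_paired_tests(pair_from(t1, t2), n_perm=20000, seed=5)
        p = res["p_raw"].iloc[0]
        se = np.sqrt(exact * (1 - exact) / 20000)
        assert abs(p - exact) < 1e-3 + 4 * se

    def test_holm_adjustment_arithmetic(self):
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([0.01, 0.02, 0.04], method="holm")[1]
        assert adj == pytest.approx([0.03, 0.04, 0.04])

    def test_single_site_rejected(self):
        with pytest.raises(TooFewSitesError):
            species_paired_tests(pair_from([[1]], [[0]]))


class TestOccupancyChange:
    @pytest.mark.parametrize(
        "n_hist, n_curr, pct",
        [(55, 16, -70.9), (756, 109, -85.6), (315, 63, -80.0), (128, 24, -81.3)],
    )
    def test_reported_species_declines(self, n_hist, n_curr, pct):
        t1 = np.zeros((n_hist, 1), dtype=int)
        t1[:n_hist] = 1
        t2 = np.zeros((n_hist, 1), dtype=int)
        t2[:n_curr] = 1
        res = occupancy_change(pair_from(t1, t2))
        row = res.iloc[0]
        assert (row["n_hist"], row["n_curr"], row["delta"]) == (n_hist, n_curr, n_curr - n_hist)
        assert row["pct_change"] == pct

    def test_extirpation_is_minus_100(self):
        t1 = np.ones((5, 1), dtype=int)
        res = occupancy_change(pair_from(t1, np.zeros_like(t1)))
        assert res["pct_change"].iloc[0] == -100.0

    def test_range_types_attached(self):
        res = occupancy_change(pair_from([[1, 0]], [[1, 1]]),
                               range_types={"x0": "anadromous"})
        assert res.loc["x0", "range_type"] == "anadromous"
        assert res.loc["x1", "range_type"] is None
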