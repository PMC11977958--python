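"""Gower dissimilarity, ANOSIM, and NMDS behavior."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra import numpy as hnp

from shellfingerprint.ordination import (DissimilarityMatrix, anosim,
                                         gower_dissimilarity, nmds)


class TestGower:
    def test_identical_rows_have_zero_dissimilarity(self, rng):
        X = rng.normal(size=(6, 4))
        X[3] = X[0]
        d = gower_dissimilarity(X)
        assert d.matrix[0, 3] == pytest.approx(0.0)

    def test_opposite_extremes_reach_one(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [0.5, 0.5]])
        d = gower_dissimilarity(X)
        assert d.matrix[0, 1] == pytest.approx(1.0)

    def test_values_in_unit_interval_and_symmetric(self, rng):
        d = gower_dissimilarity(rng.normal(size=(10, 5)))
        assert (d.matrix >= 0).all() and (d.matrix <= 1 + 1e-12).all()
        np.testing.assert_allclose(d.matrix, d.matrix.T)

    def test_matches_bruteforce_double_loop(self, rng):
        X = rng.normal(size=(15, 6))
        d = gower_dissimilarity(X)
        rngs = X.max(axis=0) - X.min(axis=0)
        for i in range(15):
            for j in range(15):
                expect = np.mean(np.abs(X[i] - X[j]) / rngs)
                assert d.matrix[i, j] == pytest.approx(expect, abs=1e-12)

    def test_zero_range_column_reported(self, rng):
        X = rng.normal(size=(8, 3))
        X[:, 1] = 2.0
        with pytest.raises(ValueError, match="zero-range"):
            gower_dissimilarity(X)


class TestAnosim:
    def test_complete_separation_gives_r_one(self):
        # all between-group dissimilarities exceed all within-group ones
        n = 8
        m = np.zeros((n, n))
        groups = np.array(["a"] * 4 + ["b"] * 4)
        rng = np.random.default_rng(0)
        for i in range(n):
            for j in range(i + 1, n):
                base = 0.9 if groups[i] != groups[j] else 0.1
                m[i, j] = m[j, i] = base + 0.01 * rng.random()
        res = anosim(DissimilarityMatrix(m, [str(i) for i in range(n)]),
                     groups, n_perm=99, seed=1)
        assert res.R == pytest.approx(1.0)

    def test_null_mean_r_near_zero(self):
        rs = []
        for s in range(300):
            rng = np.random.default_rng(s)
            X = rng.normal(size=(14, 3))
            g = np.array(["a"] * 7 + ["b"] * 7)
            d = gower_dissimilarity(X)
            rs.append(anosim(d, g, n_perm=1, seed=s).R)
        assert abs(np.mean(rs)) < 0.02

    def test_rank_invariance_under_monotone_transform(self, rng):
        X = rng.normal(size=(12, 4))
        g = np.array(["a"] * 6 + ["b"] * 6)
        d = gower_dissimilarity(X)
        d_sq = DissimilarityMatrix(d.matrix ** 2, d.sample_ids)
        r1 = anosim(d, g, n_perm=9, seed=0).R
        r2 = anosim(d_sq, g, n_perm=9, seed=0).R
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_matches_skbio_statistic(self, rng):
        skbio_dist = pytest.importorskip("skbio.stats.distance")
        X = rng.normal(size=(16, 4))
        g = ["a"] * 8 + ["b"] * 8
        X = np.asarray(X)
        X[np.array(g) == "b"] += 0.4
        d = gower_dissimilarity(X)
        ours = anosim(d, np.array(g), n_perm=9, seed=0)
        theirs = skbio_dist.anosim(skbio_dist.DistanceMatrix(d.matrix), g,
                                   permutations=9)
        assert ours.R == pytest.approx(theirs["test statistic"], abs=1e-12)

    def test_seeded_permutation_p_reproducible(self, rng):
        X = rng.normal(size=(12, 3))
        g = np.array(["a"] * 6 + ["b"] * 6)
        d = gower_dissimilarity(X)
        p1 = anosim(d, g, n_perm=199, seed=5).p_value
        p2 = anosim(d, g, n_perm=199, seed=5).p_value
        assert p1 == p2

    def test_tied_matrix_rejected(self):
        m = np.ones((6, 6)) * 0.5
        np.fill_diagonal(m, 0.0)
        with pytest.raises(ValueError, match="tied"):
            anosim(DissimilarityMatrix(m, list("abcdef")),
                   np.array(["a"] * 3 + ["b"] * 3), n_perm=9, seed=0)


class TestNmds:
    def test_exact_two_dimensional_configuration_recovered(self, rng):
        truth = rng.normal(size=(20, 2))
        from scipy.spatial.distance import pdist, squareform
        d = DissimilarityMatrix(squareform(pdist(truth)),
                                [str(i) for i in range(20)])
        res = nmds(d, k=2, n_starts=8, seed=3)
        assert res.stress < 0.01
        assert res.converged

    def test_stress_trajectories_non_increasing(self, rng):
        d = gower_dissimilarity(rng.normal(size=(15, 4)))
        res = nmds(d, k=2, n_starts=6, seed=1, max_iter=100)
        for traj in res.stress_history:
            assert (np.diff(traj) <= 1e-12).all()

    def test_more_starts_never_worse(self, rng):
        d = gower_dissimilarity(rng.normal(size=(15, 4)))
        few = nmds(d, k=2, n_starts=4, seed=7)
        many = nmds(d, k=2, n_starts=8, seed=7)
        assert many.stress <= few.stress + 1e-12

    def test_configuration_shape_and_centering(self, rng):
        d = gower_dissimilarity(rng.normal(size=(12, 3)))
        res = nmds(d, k=2, n_starts=4, seed=2)
        assert res.configuration.shape == (12, 2)
        np.testing.assert_allclose(res.configuration.mean(axis=0), 0, atol=1e-9)
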