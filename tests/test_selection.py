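"""Jackknife validation, exhaustive subset search, stratified bootstrap."""

import numpy as np
import pandas as pd
import pytest

import shellfingerprint as sf
from shellfingerprint.selection import (bootstrap_accuracy, enumerate_subsets,
                                        exhaustive_subset_search,
                                        jackknife_accuracy)


def _separable(rng, gap=20.0, n=30, p=3):
    y = np.repeat(["a", "b", "c"], n // 3)
    X = rng.normal(size=(n, p))
    X[y == "b", 0] += gap
    X[y == "c", 1] += gap
    return pd.DataFrame(X, columns=[f"E{i}" for i in range(p)]), y


class TestEnumerate:
    @pytest.mark.parametrize("p,count", [(9, 511), (1, 1), (3, 7)])
    def test_subset_counts(self, p, count):
        subs = enumerate_subsets([f"E{i}" for i in range(p)])
        assert len(subs) == count
        assert len(set(subs)) == count

    def test_ordering_by_size_then_panel(self):
        subs = enumerate_subsets(["a", "b", "c"])
        assert subs == [("a",), ("b",), ("c",), ("a", "b"), ("a", "c"),
                        ("b", "c"), ("a", "b", "c")]

    def test_large_panel_rejected(self):
        with pytest.raises(ValueError, match="heuristic"):
            enumerate_subsets([f"E{i}" for i in range(17)])


class TestJackknife:
    def test_widely_separated_clusters_are_perfect(self, rng):
        X, y = _separable(rng)
        rep = jackknife_accuracy(X, y)
        assert rep.overall_accuracy == 1.0
        assert (rep.per_group_accuracy == 1.0).all()

    def test_confusion_row_sums_equal_group_sizes(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        y = np.array(["g1"] * 18 + ["g2"] * 13 + ["g3"] * 9)
        rep = jackknife_accuracy(X, y)
        assert rep.confusion.sum(axis=1).to_dict() == {"g1": 18, "g2": 13, "g3": 9}

    def test_matches_explicit_refit_loop(self, rng):
        # oracle: refit from scratch per fold with the public fit/predict
        X, y = _separable(rng, gap=1.0, n=21)
        rep = jackknife_accuracy(X, y)
        hits = 0
        Xa = X.to_numpy()
        for i in range(len(y)):
            mask = np.ones(len(y), bool)
            mask[i] = False
            m = sf.fit_lda(Xa[mask], y[mask])
            lab, _ = predicted = sf.predict_lda(m, Xa[[i]])
            hits += lab[0] == y[i]
        assert rep.overall_accuracy == pytest.approx(hits / len(y))

    def test_tiny_groups_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(5, 2)), columns=list("ab"))
        y = np.array(["a", "a", "a", "b", "b"])
        with pytest.raises(ValueError, match="n >= 3"):
            jackknife_accuracy(X, y)


class TestSubsetSearch:
    def test_winner_at_least_as_good_as_full_panel(self, subset_search, preprocessed):
        _, sig_z, _, _ = preprocessed
        full = jackknife_accuracy(sig_z, "region")
        assert subset_search.winner_report.overall_accuracy >= full.overall_accuracy

    def test_ranking_covers_all_subsets(self, subset_search):
        assert len(subset_search.ranking) + len(subset_search.skipped or []) == 511

    def test_informative_elements_recovered(self):
        # 6 elements, only E0/E1 carry signal: the winning subset should
        # contain both in nearly every replicate
        hit = 0
        reps = 25
        for r in range(reps):
            rng = np.random.default_rng(100 + r)
            y = np.repeat(["a", "b", "c"], 15)
            X = pd.DataFrame(rng.normal(size=(45, 6)),
                             columns=[f"E{i}" for i in range(6)])
            X.loc[y == "b", "E0"] += 2.5
            X.loc[y == "c", "E1"] += 2.5
            res = exhaustive_subset_search(X, y)
            hit += {"E0", "E1"} <= set(res.winner)
        assert hit >= int(0.9 * reps)

    def test_row_order_permutation_invariance(self, rng):
        X, y = _separable(rng, gap=1.2, n=24)
        res1 = exhaustive_subset_search(X, y)
        perm = rng.permutation(len(y))
        res2 = exhaustive_subset_search(X.iloc[perm].reset_index(drop=True), y[perm])
        assert res1.winner == res2.winner
        assert res1.winner_report.overall_accuracy == pytest.approx(
            res2.winner_report.overall_accuracy)


class TestBootstrap:
    def test_perfectly_separable_gives_unit_accuracy_zero_width(self, rng):
        X, y = _separable(rng)
        rep = bootstrap_accuracy(X, y, reps=100, seed=4)
        assert rep.bootstrap_mean == 1.0
        assert rep.ci_high - rep.ci_low == 0.0

    def test_fixed_seed_bit_reproducible(self, rng):
        X, y = _separable(rng, gap=1.0)
        a = bootstrap_accuracy(X, y, reps=200, seed=9)
        b = bootstrap_accuracy(X, y, reps=200, seed=9)
        assert a.bootstrap_mean == b.bootstrap_mean
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
        pd.testing.assert_frame_equal(a.confusion, b.confusion)

    def test_infeasible_stratification_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(6, 2)), columns=list("ab"))
        y = np.array(["a", "a", "a", "a", "b", "b"])
        with pytest.raises(ValueError, match="infeasible|too small"):
            bootstrap_accuracy(X, y, reps=10, seed=0)

    def test_agrees_with_jackknife_on_fixture(self, preprocessed, subset_search):
        # cross-scheme consistency: two validation schemes on the same data
        # should land within a few percentage points of each other
        _, sig_z, _, _ = preprocessed
        jk = subset_search.winner_report.overall_accuracy
        boot = bootstrap_accuracy(sig_z, "region", subset=subset_search.winner,
                                  reps=1000, seed=21)
        assert abs(boot.bootstrap_mean - jk) < 0.05
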