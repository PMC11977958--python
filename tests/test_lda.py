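"""Discriminant analysis against brute-force and library oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from shellfingerprint.lda import (LDAModel, canonical_scores, confidence_ellipse,
                                  fit_lda, point_in_ellipse, predict_lda)


def _toy_three_groups(rng, n=30, p=4, sep=1.5):
    y = np.repeat(["a", "b", "c"], n // 3 + 1)[:n]
    X = rng.normal(size=(n, p))
    X[y == "b", 0] += sep
    X[y == "c", 1] += sep
    return X, y


class TestFit:
    def test_two_groups_1d_boundary_at_zero(self, rng):
        X = np.concatenate([rng.normal(-1, 0.3, 50), rng.normal(1, 0.3, 50)])[:, None]
        y = np.array(["lo"] * 50 + ["hi"] * 50)
        m = fit_lda(X, y, priors="uniform")
        # exactly at the midpoint of the two class means the posterior is 1/2
        mid = m.class_means.mean()
        _, post = predict_lda(m, [[mid]])
        np.testing.assert_allclose(post[0], [0.5, 0.5], atol=1e-12)
        lab, _ = predict_lda(m, [[mid - 0.2], [mid + 0.2]])
        assert list(lab) == ["lo", "hi"]

    def test_three_groups_two_axes_proportions_sum_to_one(self, rng):
        X, y = _toy_three_groups(rng)
        m = fit_lda(X, y)
        assert m.n_axes == 2
        assert m.proportion_of_trace.sum() == pytest.approx(1.0)
        assert (m.proportion_of_trace >= 0).all()
        assert m.eigenvalues[0] >= m.eigenvalues[1]

    def test_singular_pooled_covariance_reported(self, rng):
        X = rng.normal(size=(12, 3))
        X[:, 2] = X[:, 1]  # collinear
        y = np.array(["a"] * 6 + ["b"] * 6)
        with pytest.raises(Exception, match="[Ss]ingular|element-subset|reduce"):
            fit_lda(X, y)

    def test_g2_axis_matches_closed_form(self, rng):
        X = rng.normal(size=(40, 3))
        y = np.array(["a"] * 20 + ["b"] * 20)
        X[y == "b"] += [1.0, 0.5, -0.3]
        m = fit_lda(X, y)
        direction = np.linalg.solve(m.pooled_cov, m.class_means[0] - m.class_means[1])
        cos = abs(direction @ m.axes[:, 0]) / (
            np.linalg.norm(direction) * np.linalg.norm(m.axes[:, 0]))
        assert cos == pytest.approx(1.0, abs=1e-10)

    def test_json_round_trip(self, region_model, tmp_path):
        path = tmp_path / "model.json"
        region_model.to_json(path)
        back = LDAModel.from_json(path)
        np.testing.assert_allclose(back.axes, region_model.axes)
        np.testing.assert_allclose(back.pooled_cov, region_model.pooled_cov)
        assert back.classes == region_model.classes
        assert back.transform_params.center.equals(
            region_model.transform_params.center)


class TestPredict:
    def test_class_mean_classified_to_its_class(self, rng):
        X, y = _toy_three_groups(rng)
        m = fit_lda(X, y, priors="uniform")
        lab, post = predict_lda(m, m.class_means)
        assert list(lab) == m.classes
        assert (post.argmax(axis=1) == np.arange(3)).all()

    def test_matches_bruteforce_gaussian_scores(self, rng):
        # independent oracle: evaluate the shared-covariance Gaussian
        # discriminant directly per class and take the argmax
        X, y = _toy_three_groups(rng, n=20)
        m = fit_lda(X, y)
        lab, post = predict_lda(m, X)
        Sinv = np.linalg.inv(m.pooled_cov)
        expected = []
        for x in X:
            scores = []
            for k, c in enumerate(m.classes):
                d = x - m.class_means[k]
                scores.append(-0.5 * d @ Sinv @ d + np.log(m.priors[k]))
            expected.append(m.classes[int(np.argmax(scores))])
            w = np.exp(scores - np.max(scores))
            np.testing.assert_allclose(post[len(expected) - 1], w / w.sum(),
                                       atol=1e-10)
        assert list(lab) == expected

    def test_matches_sklearn_predictions(self, rng):
        sklearn = pytest.importorskip("sklearn.discriminant_analysis")
        X, y = _toy_three_groups(rng, n=24)
        m = fit_lda(X, y)
        lab, post = predict_lda(m, X)
        sk = sklearn.LinearDiscriminantAnalysis().fit(X, y)
        assert (lab == sk.predict(X)).all()
        cols = [list(sk.classes_).index(c) for c in m.classes]
        np.testing.assert_allclose(post, sk.predict_proba(X)[:, cols], atol=1e-8)

    def test_posterior_rows_sum_to_one(self, rng):
        X, y = _toy_three_groups(rng)
        m = fit_lda(X, y)
        _, post = predict_lda(m, rng.normal(size=(50, 4)))
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-12)

    @given(st.floats(min_value=0.1, max_value=50.0))
    def test_affine_equivariance_under_column_rescale(self, scale):
        rng = np.random.default_rng(3)
        X, y = _toy_three_groups(rng)
        m0 = fit_lda(X, y)
        X2 = X.copy()
        X2[:, 1] *= scale
        m1 = fit_lda(X2, y)
        lab0, _ = predict_lda(m0, X)
        lab1, _ = predict_lda(m1, X2)
        assert (lab0 == lab1).all()
        np.testing.assert_allclose(m0.proportion_of_trace, m1.proportion_of_trace,
                                   atol=1e-8)


class TestCanonicalScores:
    def test_duplicate_sample_gets_identical_scores(self, rng):
        X, y = _toy_three_groups(rng)
        m = fit_lda(X, y)
        sc = canonical_scores(m, np.vstack([X[5], X[5]]))
        np.testing.assert_allclose(sc.scores[0], sc.scores[1])
        np.testing.assert_allclose(sc.scores[0], m.training_scores[5])

    def test_first_axis_beats_random_directions(self, rng):
        X, y = _toy_three_groups(rng, n=60)
        m = fit_lda(X, y)

        def ratio(direction):
            proj = X @ direction
            grand = proj.mean()
            sb = sw = 0.0
            for c in np.unique(y):
                block = proj[y == c]
                sb += len(block) * (block.mean() - grand) ** 2
                sw += ((block - block.mean()) ** 2).sum()
            return sb / sw

        best = ratio(m.axes[:, 0])
        for _ in range(1000):
            d = rng.normal(size=4)
            assert ratio(d / np.linalg.norm(d)) <= best + 1e-12

    def test_score_separation_matches_mahalanobis_ordering(self, rng):
        X, y = _toy_three_groups(rng, n=90, sep=2.0)
        m = fit_lda(X, y)
        Sinv = np.linalg.inv(m.pooled_cov)

        def full_space(i, j):
            d = m.class_means[i] - m.class_means[j]
            return d @ Sinv @ d

        centers = canonical_scores(m, m.class_means).scores

        def score_space(i, j):
            return ((centers[i] - centers[j]) ** 2).sum()

        pairs = [(0, 1), (0, 2), (1, 2)]
        full = np.array([full_space(*p) for p in pairs])
        red = np.array([score_space(*p) for p in pairs])
        assert (np.argsort(full) == np.argsort(red)).all()


class TestEllipse:
    def test_centroid_inside_own_ellipse(self, rng):
        pts = rng.normal(size=(30, 2))
        spec = confidence_ellipse(pts)
        assert point_in_ellipse(spec, pts.mean(axis=0))

    def test_far_point_outside(self, rng):
        pts = rng.normal(size=(30, 2))
        spec = confidence_ellipse(pts)
        semi_major = np.sqrt(np.linalg.eigvalsh(spec.shape)[-1] * spec.quantile)
        far = spec.center + np.array([10 * semi_major, 0])
        assert not point_in_ellipse(spec, far)

    def test_boundary_membership_inclusive(self):
        spec = confidence_ellipse(np.array([[0, 0], [1, 0], [0, 1], [1, 1.0]]))
        evals, evecs = np.linalg.eigh(spec.shape)
        boundary = spec.center + np.sqrt(evals[0] * spec.quantile) * evecs[:, 0]
        assert point_in_ellipse(spec, boundary)

    def test_degenerate_covariance_rejected(self):
        line = np.column_stack([np.arange(5.0), np.arange(5.0)])
        with pytest.raises(ValueError, match="degenerate|non-PD"):
            confidence_ellipse(line)
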