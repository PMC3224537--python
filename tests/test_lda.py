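"""Fisher discriminant vs closed-form and dense-eigensolve oracles."""

import numpy as np
import pytest
from scipy.stats import norm

from mammocad.datatypes import FeatureMatrix
from mammocad.lda import fisher_ratio, lda_fit, lda_predict


def _features(X, y):
    return FeatureMatrix(coeffs=X, labels=np.asarray(y))


def _two_gaussians(rng, mu0, mu1, n, cov=None):
    d = len(mu0)
    cov = np.eye(d) if cov is None else cov
    X0 = rng.multivariate_normal(mu0, cov, size=n).T
    X1 = rng.multivariate_normal(mu1, cov, size=n).T
    X = np.hstack([X0, X1])
    y = np.array(["neg"] * n + ["pos"] * n)
    return _features(X, y)


class TestFit:
    def test_axis_aligned_means_force_beta(self, rng):
        feats = _two_gaussians(rng, [0.0, 0.0], [1.0, 0.0], 2000)
        model = lda_fit(feats, positive_class="pos")
        np.testing.assert_allclose(np.abs(model.beta), [1.0, 0.0], atol=0.06)

    def test_matches_dense_eigen_oracle(self, rng):
        X = rng.standard_normal((3, 60))
        X[:, 30:] += np.array([[1.0], [0.5], [-0.3]])
        y = ["a"] * 30 + ["b"] * 30
        model = lda_fit(_features(X, y))
        Winv_B = np.linalg.inv(model.within_scatter) @ model.between_scatter
        vals, vecs = np.linalg.eig(Winv_B)
        top = np.real(vecs[:, np.argmax(np.real(vals))])
        top /= np.linalg.norm(top)
        assert abs(abs(model.beta @ top) - 1.0) < 1e-8

    def test_two_class_closed_form_identity(self, rng):
        """beta is parallel to pooledSigma^-1 (mu1 - mu2)."""
        cov = np.array([[2.0, 0.6, 0.1], [0.6, 1.0, 0.2], [0.1, 0.2, 0.5]])
        feats = _two_gaussians(rng, [0, 0, 0], [1, 0.5, -0.2], 500, cov)
        model = lda_fit(feats, positive_class="pos")
        y = feats.labels
        F = feats.coeffs
        pooled = np.zeros((3, 3))
        delta = None
        means = {}
        for cls in ("neg", "pos"):
            Fc = F[:, y == cls]
            means[cls] = Fc.mean(axis=1)
            R = Fc - means[cls][:, None]
            pooled += R @ R.T
        direction = np.linalg.solve(pooled, means["pos"] - means["neg"])
        direction /= np.linalg.norm(direction)
        assert abs(abs(model.beta @ direction) - 1.0) < 1e-8

    def test_scatter_matrices_psd_and_symmetric(self, rng):
        feats = _two_gaussians(rng, [0, 0], [2, 1], 100)
        model = lda_fit(feats)
        for M in (model.between_scatter, model.within_scatter):
            np.testing.assert_allclose(M, M.T, atol=1e-10)
            assert np.linalg.eigvalsh(M)[0] > -1e-8

    def test_requires_exactly_two_classes(self, rng):
        X = rng.standard_normal((2, 9))
        with pytest.raises(ValueError, match="2 classes"):
            lda_fit(_features(X, ["a", "b", "c"] * 3))

    def test_singular_within_scatter_regularized_not_crashed(self):
        # feature 2 duplicates feature 1 exactly -> singular W
        X = np.array([[0.0, 1, 2, 3, 10, 11, 12, 13]])
        X = np.vstack([X, X])
        y = ["a"] * 4 + ["b"] * 4
        model = lda_fit(_features(X, y))
        assert np.isfinite(model.beta).all()


class TestPredict:
    def test_class_mean_classified_positive(self, rng):
        feats = _two_gaussians(rng, [0, 0], [3, 0], 200)
        model = lda_fit(feats, positive_class="pos")
        mean_pos = model.class_means["pos"][:, None]
        pred = lda_predict(model, _features(mean_pos, ["?"]))
        assert pred[0] == "pos"

    def test_exact_midpoint_goes_negative(self, rng):
        feats = _two_gaussians(rng, [0.0], [2.0], 50)
        model = lda_fit(feats, positive_class="pos")
        # construct the feature value whose score is exactly the threshold
        x_mid = model.threshold / model.beta[0]
        pred = lda_predict(model, _features(np.array([[x_mid]]), ["?"]))
        assert pred[0] == "neg"

    def test_accuracy_near_analytic_bayes_rate(self):
        """Two spherical Gaussians at d' = 4: CV-free holdout accuracy
        within 2 points of Phi(d'/2)."""
        rng = np.random.default_rng(17)
        d_prime = 4.0
        train = _two_gaussians(rng, [0, 0], [d_prime, 0], 2500)
        test = _two_gaussians(rng, [0, 0], [d_prime, 0], 2500)
        model = lda_fit(train, positive_class="pos")
        pred = lda_predict(model, test)
        acc = np.mean(pred == test.labels)
        bayes = norm.cdf(d_prime / 2)
        assert abs(acc - bayes) < 0.02

    def test_dimension_mismatch_rejected(self, rng):
        feats = _two_gaussians(rng, [0, 0], [1, 1], 20)
        model = lda_fit(feats)
        with pytest.raises(ValueError, match="dimension"):
            lda_predict(model, _features(rng.standard_normal((3, 4)),
                                         ["x"] * 4))

    def test_predictions_invariant_under_affine_feature_map(self, rng):
        """Scaling + rotating the feature space consistently leaves the
        predicted labels unchanged."""
        feats = _two_gaussians(rng, [0, 0, 0], [1.5, 0.7, -0.4], 300)
        test = _two_gaussians(rng, [0, 0, 0], [1.5, 0.7, -0.4], 100)
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0],
                      [0, 0, 1.0]])
        M = R @ np.diag([3.0, 0.5, 1.7])
        pred_raw = lda_predict(lda_fit(feats, positive_class="pos"), test)
        feats_t = _features(M @ feats.coeffs, feats.labels)
        test_t = _features(M @ test.coeffs, test.labels)
        pred_t = lda_predict(lda_fit(feats_t, positive_class="pos"), test_t)
        np.testing.assert_array_equal(pred_raw, pred_t)

    def test_agrees_with_reference_lda_direction(self, rng):
        """Independent cross-check against scikit-learn's LDA solver."""
        sklearn = pytest.importorskip("sklearn.discriminant_analysis")
        feats = _two_gaussians(rng, [0, 0, 0, 0], [1, 0.5, -0.5, 0.2], 400)
        model = lda_fit(feats, positive_class="pos")
        ref = sklearn.LinearDiscriminantAnalysis(solver="eigen")
        ref.fit(feats.coeffs.T, feats.labels)
        ref_dir = ref.coef_.ravel() / np.linalg.norm(ref.coef_)
        assert abs(abs(model.beta @ ref_dir) - 1.0) < 1e-6


class TestFisherRatio:
    def test_beta_beats_random_directions(self, rng):
        feats = _two_gaussians(rng, [0, 0, 0], [1, 1, 0], 300)
        model = lda_fit(feats)
        best = fisher_ratio(model.beta, model)
        for _ in range(100):
            d = rng.standard_normal(3)
            assert fisher_ratio(d, model) <= best + 1e-10

    def test_scale_invariance(self, rng):
        feats = _two_gaussians(rng, [0, 0], [1, 2], 50)
        model = lda_fit(feats)
        d = rng.standard_normal(2)
        assert fisher_ratio(2 * d, model) == pytest.approx(
            fisher_ratio(d, model), rel=1e-12)

    def test_identical_class_means_give_zero(self, rng):
        X = rng.standard_normal((2, 100))
        y = ["a", "b"] * 50
        model = lda_fit(_features(X, y))
        # class means nearly equal; B ~ 0 so the ratio is tiny everywhere
        assert fisher_ratio(np.array([1.0, 1.0]), model) < 0.05

    def test_zero_direction_rejected(self, rng):
        feats = _two_gaussians(rng, [0, 0], [1, 1], 20)
        model = lda_fit(feats)
        with pytest.raises(ValueError, match="nonzero"):
            fisher_ratio(np.zeros(2), model)
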