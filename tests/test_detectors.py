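"""Unit tests for the three normative detectors and the SVM baseline."""

import numpy as np
import pytest
from scipy import stats as sps

import tractnorm as tn
from tractnorm import detectors as D
from tractnorm.exceptions import (
    DegenerateFeatureError,
    DimensionError,
    ParameterError,
)


@pytest.mark.parametrize("n,widths", [
    (100, [100, 50, 25, 50, 100]),
    (4, [4, 2, 1, 2, 4]),
    (101, [101, 51, 26, 51, 101]),
    (60, [60, 30, 15, 30, 60]),
])
def test_layer_widths(n, widths):
    assert tn.build_layer_widths(n) == widths


def test_layer_widths_too_few_features():
    with pytest.raises(ParameterError):
        tn.build_layer_widths(3)


class TestAutoencoder:
    def test_learns_constant_data(self, rng):
        X = np.tile(rng.uniform(0.2, 0.8, 12), (20, 1))
        model = tn.fit_autoencoder(X, tn.AutoencoderSpec(seed=0))
        h = model.history["train_loss"]
        assert h[-1] < h[0]

    def test_deterministic_given_seed(self, rng):
        X = rng.uniform(0, 1, (25, 10))
        m1 = tn.fit_autoencoder(X, tn.AutoencoderSpec(seed=9))
        m2 = tn.fit_autoencoder(X, tn.AutoencoderSpec(seed=9))
        assert m1.history["train_loss"][-1] == m2.history["train_loss"][-1]
        for a, b in zip(m1.weights, m2.weights):
            np.testing.assert_array_equal(a, b)

    def test_generalizes_to_training_pattern_not_orthogonal_one(self, rng):
        """Trained on rank-1 data, held-out rank-1 rows reconstruct better
        than rows built from an orthogonal pattern."""
        u = np.abs(rng.normal(size=16))
        u /= np.linalg.norm(u)
        v = rng.normal(size=16)
        v -= (v @ u) * u
        v = np.abs(v) / np.linalg.norm(v)  # different, non-negative pattern
        train = np.outer(rng.uniform(0.5, 1.0, 40), u)
        same = np.outer(rng.uniform(0.5, 1.0, 10), u)
        other = np.outer(rng.uniform(0.5, 1.0, 10), v)
        model = tn.fit_autoencoder(train, tn.AutoencoderSpec(epochs=100, seed=3))
        assert tn.score_mae(model, same).mean() < tn.score_mae(model, other).mean()

    def test_score_mae_hand_example_and_oracle(self, rng):
        X = rng.uniform(0, 1, (15, 8))
        model = tn.fit_autoencoder(X, tn.AutoencoderSpec(seed=1))
        scores = tn.score_mae(model, X)
        # elementwise-loop oracle
        recon = model.reconstruct(X)
        expected = np.array([
            np.mean([abs(X[j, i] - recon[j, i]) for i in range(8)])
            for j in range(15)
        ])
        np.testing.assert_allclose(scores, expected)
        assert np.all(scores >= 0)

    def test_mae_of_perfect_reconstruction_is_zero(self):
        assert np.mean(np.abs(np.array([0.2, 0.4]) - np.array([0.2, 0.4]))) == 0
        # and the two-feature hand case: x=(0.2,0.4), xhat=(0.1,0.7) -> 0.2
        assert np.mean(np.abs(np.array([0.2, 0.4]) - np.array([0.1, 0.7]))) \
            == pytest.approx(0.2)

    def test_reconstruction_error_sign_and_consistency(self, rng):
        X = rng.uniform(0, 1, (12, 6))
        model = tn.fit_autoencoder(X, tn.AutoencoderSpec(seed=2))
        err = tn.reconstruction_errors(model, X)
        np.testing.assert_allclose(np.abs(err).mean(axis=1),
                                   tn.score_mae(model, X))
        recon = model.reconstruct(X)
        assert np.all((err > 0) == (recon < X))

    def test_dimension_mismatch(self, rng):
        model = tn.fit_autoencoder(rng.uniform(0, 1, (10, 6)),
                                   tn.AutoencoderSpec(seed=0))
        with pytest.raises(DimensionError):
            tn.score_mae(model, rng.uniform(0, 1, (3, 5)))


class TestZScore:
    def test_subject_at_training_mean_scores_zero(self, rng):
        X = rng.normal(5, 2, (50, 4))
        stats = tn.NormativeStats.fit(X)
        score = tn.score_zscore(stats, stats.mean[None, :])
        assert score[0] == pytest.approx(0.0, abs=1e-12)

    def test_two_sigma_single_feature(self, rng):
        X = rng.normal(0, 1, (100, 1))
        stats = tn.NormativeStats.fit(X)
        x = stats.mean + 2 * stats.std
        assert tn.score_zscore(stats, x[None, :])[0] == pytest.approx(2.0)

    def test_absolute_mode_matches_loop_oracle(self, rng):
        train = rng.normal(size=(20, 3))
        stats = tn.NormativeStats.fit(train)
        X = rng.normal(size=(5, 3))
        expected = np.array([
            np.mean([abs((X[j, i] - stats.mean[i]) / stats.std[i])
                     for i in range(3)]) for j in range(5)
        ])
        np.testing.assert_allclose(tn.score_zscore(stats, X), expected)
        signed = np.array([
            np.mean([(X[j, i] - stats.mean[i]) / stats.std[i]
                     for i in range(3)]) for j in range(5)
        ])
        np.testing.assert_allclose(
            tn.score_zscore(stats, X, mode="signed"), signed)

    def test_degenerate_feature_rejected(self):
        X = np.column_stack([np.arange(10.0), np.full(10, 2.0)])
        with pytest.raises(DegenerateFeatureError):
            tn.NormativeStats.fit(X)

    def test_monotone_in_injected_deviation(self, rng):
        train = rng.normal(size=(40, 6))
        stats = tn.NormativeStats.fit(train)
        x = train.mean(axis=0)
        prev = -np.inf
        for amp in [0.5, 1, 2, 4, 8]:
            xa = x.copy()
            xa[2] += amp * stats.std[2]
            s = tn.score_zscore(stats, xa[None, :])[0]
            assert s >= prev
            prev = s


class TestMahalanobis:
    def test_one_dimensional_reduces_to_abs_z(self, rng):
        X = rng.normal(3, 2, (200, 1))
        model = tn.fit_pca_mahalanobis(X, variance_threshold=1.0)
        x = rng.normal(3, 2, (20, 1))
        M = tn.score_mahalanobis(model, x)
        sd = model.cov[0, 0] ** 0.5
        z = np.abs(model.pca.transform(x).ravel() - model.mean[0]) / sd
        np.testing.assert_allclose(M, z, rtol=1e-10)

    def test_identity_covariance_gives_euclidean_distance(self, rng):
        # isotropic data: component covariance ~ diag; check with whitened toy
        X = rng.normal(0, 1, (5000, 3))
        model = tn.fit_pca_mahalanobis(X, variance_threshold=1.0)
        x = rng.normal(0, 1, (10, 3))
        s = model.pca.transform(x) - model.mean
        expected = np.sqrt(np.einsum("ij,jk,ik->i", s, model.cov_inv, s))
        np.testing.assert_allclose(tn.score_mahalanobis(model, x), expected)
        # with near-identity covariance the distance is near-Euclidean
        euclid = np.linalg.norm(s, axis=1)
        np.testing.assert_allclose(tn.score_mahalanobis(model, x), euclid,
                                   rtol=0.1)

    def test_matches_bruteforce_quadratic_form(self, rng):
        """Agreement with an explicit solve on 6x6 instances to 1e-8."""
        for trial in range(5):
            X = rng.normal(size=(40, 6))
            model = tn.fit_pca_mahalanobis(X, variance_threshold=0.999999)
            x = rng.normal(size=(8, 6))
            got = tn.score_mahalanobis(model, x)
            s = model.pca.transform(x)
            brute = np.array([
                np.sqrt((si - model.mean) @ np.linalg.solve(
                    model.cov, si - model.mean)) for si in s
            ])
            np.testing.assert_allclose(got, brute, atol=1e-8)

    def test_squared_distance_is_chi2_on_fresh_normals(self, rng):
        A = rng.normal(size=(8, 8))
        cov = A @ A.T / 8 + np.eye(8)
        train = rng.multivariate_normal(np.zeros(8), cov, size=500)
        model = tn.fit_pca_mahalanobis(train, 0.85)
        fresh = rng.multivariate_normal(np.zeros(8), cov, size=2000)
        M2 = tn.score_mahalanobis(model, fresh) ** 2
        p = sps.kstest(M2, sps.chi2(model.n_components).cdf).pvalue
        assert p > 0.01

    def test_monotone_in_injected_deviation(self, rng):
        X = rng.normal(size=(60, 5))
        model = tn.fit_pca_mahalanobis(X, 0.85)
        x = X.mean(axis=0)
        direction = model.pca.components_[0]
        prev = -np.inf
        for amp in [0, 1, 2, 5, 10]:
            s = tn.score_mahalanobis(model, (x + amp * direction)[None, :])[0]
            assert s >= prev
            prev = s

    def test_permutation_equivariance_and_column_invariance(self, rng):
        X = rng.normal(size=(50, 6))
        x = rng.normal(size=(7, 6))
        model = tn.fit_pca_mahalanobis(X, 0.85)
        base = tn.score_mahalanobis(model, x)
        perm = rng.permutation(7)
        np.testing.assert_allclose(tn.score_mahalanobis(model, x[perm]),
                                   base[perm])
        cols = rng.permutation(6)
        model_c = tn.fit_pca_mahalanobis(X[:, cols], 0.85)
        np.testing.assert_allclose(
            tn.score_mahalanobis(model_c, x[:, cols]), base, rtol=1e-8)


class TestSvmBaseline:
    def test_separable_blobs_reach_perfect_auc(self, rng):
        X = np.vstack([rng.normal(0, 0.3, (20, 2)),
                       rng.normal(5, 0.3, (20, 2))])
        y = np.array([0] * 20 + [1] * 20)
        res = tn.fit_svm_baseline(X, y, seed=0, n_repeats=2)
        assert res.mean_auc == pytest.approx(1.0)
        assert res.n_param_combinations == 32  # 4x7 rbf + 4 linear

    def test_shuffled_labels_near_chance(self, rng):
        X = rng.normal(size=(60, 4))
        y = rng.permutation([0] * 30 + [1] * 30)
        res = tn.fit_svm_baseline(X, y, seed=1, n_repeats=2)
        assert abs(res.mean_auc - 0.5) < 3 * max(res.sd_auc, 0.05)
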