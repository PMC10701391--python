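import numpy as np
import pytest

from seegdecode import csp_features, csp_fit, csp_lda_cell
from seegdecode.preprocess import EpochSet


def _two_class_epochs(rng, cov_move, cov_rest, n_per_class=30, n_samples=512):
    k = cov_move.shape[0]
    chol_m = np.linalg.cholesky(cov_move)
    chol_r = np.linalg.cholesky(cov_rest)
    data = np.concatenate([
        np.einsum("cd,tds->tcs", chol_m,
                  rng.standard_normal((n_per_class, k, n_samples))),
        np.einsum("cd,tds->tcs", chol_r,
                  rng.standard_normal((n_per_class, k, n_samples))),
    ])
    labels = np.array(["move"] * n_per_class + ["rest"] * n_per_class)
    return EpochSet(data, labels, "beta", 256.0)


class TestCSPFit:
    def test_axis_aligned_covariances_give_axis_filters(self, rng):
        eps = _two_class_epochs(rng, np.diag([4.0, 1.0]), np.diag([1.0, 4.0]),
                                n_per_class=50, n_samples=2048)
        model = csp_fit(eps, n_filters=2)
        # first filter favors move variance: eigenvalue ~ 4/(4+1)
        assert model.eigenvalues[0] == pytest.approx(0.8, abs=0.02)
        assert model.eigenvalues[1] == pytest.approx(0.2, abs=0.02)
        for row in model.filters:
            axis = np.argmax(np.abs(row))
            assert np.abs(row[1 - axis]) < 0.15 * np.abs(row[axis])

    def test_identical_class_covariances_are_nondiscriminative(self, rng):
        eps = _two_class_epochs(rng, np.eye(3), np.eye(3), n_per_class=40,
                                n_samples=2048)
        model = csp_fit(eps, n_filters=3)
        np.testing.assert_allclose(model.eigenvalues, 0.5, atol=0.03)

    def test_filters_jointly_diagonalize_class_means(self, rng):
        a = rng.standard_normal((3, 3))
        cov_move = a @ a.T + np.eye(3)
        eps = _two_class_epochs(rng, cov_move, np.eye(3), n_per_class=40,
                                n_samples=1024)
        model = csp_fit(eps, n_filters=3)
        from seegdecode.csp import _class_covariances
        c_move, c_rest = _class_covariances(eps)
        for c in (c_move, c_rest):
            d = model.filters @ c @ model.filters.T
            off = d - np.diag(np.diag(d))
            assert np.abs(off).max() < 1e-8

    def test_trial_permutation_leaves_filters_unchanged(self, rng):
        eps = _two_class_epochs(rng, np.diag([3.0, 1.0]), np.diag([1.0, 3.0]))
        model = csp_fit(eps, n_filters=2)
        perm = rng.permutation(eps.n_trials)
        eps_p = EpochSet(eps.data[perm], eps.labels[perm], "beta", 256.0)
        model_p = csp_fit(eps_p, n_filters=2)
        for w, wp in zip(model.filters, model_p.filters):
            # filters defined up to sign
            assert min(np.abs(w - wp).max(), np.abs(w + wp).max()) < 1e-10

    def test_single_class_rejected(self, rng):
        eps = _two_class_epochs(rng, np.eye(2), np.eye(2), n_per_class=5)
        eps.labels[:] = "move"
        with pytest.raises(ValueError):
            csp_fit(eps, 2)

    def test_too_many_filters_rejected(self, rng):
        eps = _two_class_epochs(rng, np.eye(2), np.eye(2), n_per_class=5)
        with pytest.raises(ValueError):
            csp_fit(eps, 3)


class TestCSPFeatures:
    def test_unit_filter_recovers_channel_power(self, rng):
        eps = _two_class_epochs(rng, np.eye(2), np.eye(2), n_per_class=10,
                                n_samples=4096)
        from seegdecode.csp import CSPModel
        model = CSPModel(filters=np.array([[1.0, 0.0]]),
                         eigenvalues=np.array([0.5]))
        feats = csp_features(model, eps)
        np.testing.assert_allclose(feats[:, 0], 1.0, atol=0.15)

    def test_zero_trial_gives_zero_features(self):
        from seegdecode.csp import CSPModel
        eps = EpochSet(np.zeros((2, 2, 64)), np.array(["move", "rest"]),
                       "beta", 256.0)
        model = CSPModel(filters=np.eye(2), eigenvalues=np.array([0.5, 0.5]))
        np.testing.assert_array_equal(csp_features(model, eps), 0.0)

    def test_features_scale_quadratically_with_amplitude(self, rng):
        eps = _two_class_epochs(rng, np.eye(2), np.eye(2), n_per_class=3)
        from seegdecode.csp import CSPModel
        model = CSPModel(filters=rng.standard_normal((2, 2)),
                         eigenvalues=np.array([0.5, 0.5]))
        f1 = csp_features(model, eps)
        eps2 = EpochSet(2.0 * eps.data, eps.labels, "beta", 256.0)
        np.testing.assert_allclose(csp_features(model, eps2), 4.0 * f1,
                                   rtol=1e-12)

    def test_log_option(self, rng):
        eps = _two_class_epochs(rng, np.eye(2), np.eye(2), n_per_class=3)
        from seegdecode.csp import CSPModel
        model = CSPModel(filters=np.eye(2), eigenvalues=np.array([0.5, 0.5]))
        np.testing.assert_allclose(csp_features(model, eps, log=True),
                                   np.log(csp_features(model, eps)))


class TestCSPLDACell:
    def test_separable_classes_decoded(self, rng):
        eps = _two_class_epochs(rng, np.diag([5.0, 1.0, 1.0]),
                                np.diag([1.0, 1.0, 5.0]), n_per_class=30)
        aucs = csp_lda_cell(eps, n_filters=2, n_folds=5, seed=0)
        assert aucs.mean() >= 0.9

    def test_null_classes_near_chance(self, rng):
        means = []
        for seed in range(5):
            eps = _two_class_epochs(rng, np.eye(3), np.eye(3), n_per_class=30)
            means.append(csp_lda_cell(eps, n_filters=2, n_folds=5,
                                      seed=seed).mean())
        assert abs(np.mean(means) - 0.5) < 0.1

    def test_deterministic_under_seed(self, rng):
        eps = _two_class_epochs(rng, np.diag([2.0, 1.0]), np.diag([1.0, 2.0]))
        a1 = csp_lda_cell(eps, n_filters=2, n_folds=5, seed=4)
        a2 = csp_lda_cell(eps, n_filters=2, n_folds=5, seed=4)
        np.testing.assert_array_equal(a1, a2)
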