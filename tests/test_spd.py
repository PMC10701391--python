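import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.covariance import LedoitWolf

from seegdecode import (CovarianceSet, jeffreys_distance, kl_divergence,
                        lw_shrinkage_covariance, mdm_fit, mdm_score,
                        mean_arithmetic, mean_harmonic, mean_kl_sym)
from seegdecode.spd import check_spd, mdm_predict
from conftest import random_spd


class TestLedoitWolf:
    def test_matches_reference_closed_form(self):
        x = np.random.default_rng(0).standard_normal((4, 50))
        ref = LedoitWolf().fit(x.T).covariance_
        np.testing.assert_allclose(lw_shrinkage_covariance(x), ref, atol=1e-10)

    def test_consistency_limit_identity(self, rng):
        # large n from identity covariance: output ~ I, shrinkage small
        x = rng.standard_normal((4, 20000))
        out = lw_shrinkage_covariance(x)
        np.testing.assert_allclose(out, np.eye(4), atol=0.05)

    def test_rank_deficient_input_is_regularized_to_spd(self, rng):
        k = 10
        x = rng.standard_normal((k, k // 2))  # S has rank < k
        out = lw_shrinkage_covariance(x)
        assert np.linalg.eigvalsh(out).min() > 0

    def test_errors(self, rng):
        with pytest.raises(ValueError):
            lw_shrinkage_covariance(rng.standard_normal((3, 1)))
        with pytest.raises(ValueError, match="degenerate"):
            lw_shrinkage_covariance(np.ones((3, 10)))


class TestKL:
    def test_self_divergence_is_zero(self, rng):
        a = random_spd(rng, 4)
        assert kl_divergence(a, a) == pytest.approx(0.0, abs=1e-10)

    def test_closed_form_identity_vs_diag(self):
        a, b = np.eye(2), np.diag([4.0, 1.0])
        assert kl_divergence(a, b) == pytest.approx(
            0.5 * (1.25 - 2 + np.log(4)), abs=1e-12)
        assert kl_divergence(b, a) == pytest.approx(
            0.5 * (5 - 2 - np.log(4)), abs=1e-12)

    def test_congruence_invariance(self, rng):
        for _ in range(20):
            a, b = random_spd(rng, 3), random_spd(rng, 3)
            w = rng.standard_normal((3, 3)) + 0.1 * np.eye(3)
            assert kl_divergence(w @ a @ w.T, w @ b @ w.T) == pytest.approx(
                kl_divergence(a, b), rel=1e-8)

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError):
            kl_divergence(random_spd(rng, 2), random_spd(rng, 3))

    def test_non_spd_rejected(self):
        with pytest.raises(ValueError):
            kl_divergence(np.array([[1.0, 2.0], [2.0, 1.0]]), np.eye(2))


class TestJeffreys:
    def test_closed_form(self):
        a, b = np.eye(2), np.diag([4.0, 1.0])
        expected = 0.5 * (0.5 * (1.25 - 2 + np.log(4)) + 0.5 * (3 - np.log(4)))
        assert jeffreys_distance(a, b) == pytest.approx(expected, abs=1e-12)
        assert jeffreys_distance(a, b) == pytest.approx(0.5625, abs=1e-4)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=2, max_value=6), st.integers(min_value=0, max_value=10 ** 6))
    def test_symmetry_and_nonnegativity(self, k, seed):
        r = np.random.default_rng(seed)
        a, b = random_spd(r, k), random_spd(r, k)
        d_ab, d_ba = jeffreys_distance(a, b), jeffreys_distance(b, a)
        assert d_ab == pytest.approx(d_ba, rel=1e-10)
        assert d_ab >= 0
        assert jeffreys_distance(a, a) == pytest.approx(0.0, abs=1e-10)


class TestMeans:
    def test_singleton_mean_is_identity_operation(self, rng):
        a = random_spd(rng, 3)
        for fn in (mean_arithmetic, mean_harmonic, mean_kl_sym):
            np.testing.assert_allclose(fn([a]), a, atol=1e-10)

    def test_commuting_closed_forms(self):
        mats = [np.diag([1.0, 1.0]), np.diag([3.0, 3.0])]
        np.testing.assert_allclose(mean_arithmetic(mats), np.diag([2.0, 2.0]),
                                   atol=1e-12)
        np.testing.assert_allclose(mean_harmonic(mats), np.diag([1.5, 1.5]),
                                   atol=1e-12)
        np.testing.assert_allclose(mean_kl_sym(mats),
                                   np.diag([np.sqrt(3.0)] * 2), atol=1e-10)

    def test_mean_of_identical_copies_is_the_copy(self, rng):
        c = random_spd(rng, 4)
        np.testing.assert_allclose(mean_kl_sym([c] * 5), c, atol=1e-10)

    def test_loewner_ordering_harmonic_below_sym_below_arithmetic(self, rng):
        for _ in range(10):
            mats = [random_spd(rng, 3) for _ in range(4)]
            a = mean_arithmetic(mats)
            h = mean_harmonic(mats)
            m = mean_kl_sym(mats)
            assert np.linalg.eigvalsh(a - m).min() > -1e-8
            assert np.linalg.eigvalsh(m - h).min() > -1e-8

    def test_congruence_equivariance(self, rng):
        mats = [random_spd(rng, 3) for _ in range(5)]
        w = rng.standard_normal((3, 3)) + 0.2 * np.eye(3)
        transformed = [w @ c @ w.T for c in mats]
        for fn in (mean_arithmetic, mean_harmonic, mean_kl_sym):
            np.testing.assert_allclose(fn(transformed), w @ fn(mats) @ w.T,
                                       rtol=1e-8, atol=1e-8)

    def test_empty_and_mismatched_inputs(self, rng):
        with pytest.raises(ValueError):
            mean_arithmetic([])
        with pytest.raises(ValueError):
            mean_kl_sym([random_spd(rng, 2), random_spd(rng, 3)])


class TestMDM:
    def _toy_covs(self):
        move = [np.diag([4.0, 1.0])] * 3
        rest = [np.diag([1.0, 4.0])] * 3
        return CovarianceSet(matrices=move + rest,
                             labels=np.array(["move"] * 3 + ["rest"] * 3))

    def test_identical_class_matrices_give_that_mean(self):
        model = mdm_fit(self._toy_covs(), "kl_sym")
        np.testing.assert_allclose(model.class_means["move"],
                                   np.diag([4.0, 1.0]), atol=1e-10)

    def test_divergence_matched_centroids(self, rng):
        mats = [random_spd(rng, 3) for _ in range(4)]
        covs = CovarianceSet(matrices=mats + mats[:2],
                             labels=np.array(["move"] * 4 + ["rest"] * 2))
        np.testing.assert_allclose(
            mdm_fit(covs, "kl_left").class_means["move"], mean_arithmetic(mats),
            atol=1e-12)
        np.testing.assert_allclose(
            mdm_fit(covs, "kl_right").class_means["move"], mean_harmonic(mats),
            atol=1e-12)

    def test_sample_at_move_mean_scores_positive(self):
        model = mdm_fit(self._toy_covs(), "kl_sym")
        assert mdm_score(model, np.diag([4.0, 1.0])) > 0
        assert mdm_predict(model, np.diag([4.0, 1.0])) == "move"

    def test_equidistant_sample_ties_to_rest(self):
        model = mdm_fit(self._toy_covs(), "kl_sym")
        c = np.eye(2)  # symmetric between diag(4,1) and diag(1,4)
        assert mdm_score(model, c) == pytest.approx(0.0, abs=1e-12)
        assert mdm_predict(model, c) == "rest"

    def test_skewed_sample_classified_by_explicit_distances(self):
        model = mdm_fit(self._toy_covs(), "kl_sym")
        c = np.diag([3.0, 1.0])
        d_move = jeffreys_distance(c, np.diag([4.0, 1.0]))
        d_rest = jeffreys_distance(c, np.diag([1.0, 4.0]))
        assert d_move < d_rest
        assert mdm_predict(model, c) == "move"

    def test_trial_order_invariance(self, rng):
        mats = [random_spd(rng, 3) for _ in range(8)]
        labels = np.array(["move", "rest"] * 4)
        model = mdm_fit(CovarianceSet(mats, labels), "kl_sym")
        perm = rng.permutation(8)
        model_p = mdm_fit(CovarianceSet([mats[i] for i in perm], labels[perm]),
                          "kl_sym")
        for cls in ("move", "rest"):
            np.testing.assert_allclose(model.class_means[cls],
                                       model_p.class_means[cls], atol=1e-10)

    def test_single_class_rejected(self, rng):
        covs = CovarianceSet([random_spd(rng, 2)] * 3, np.array(["move"] * 3))
        with pytest.raises(ValueError):
            mdm_fit(covs)

    def test_all_outputs_pass_spd_checks(self, rng):
        mats = [random_spd(rng, 4) for _ in range(6)]
        labels = np.array(["move"] * 3 + ["rest"] * 3)
        for div in ("kl_left", "kl_right", "kl_sym"):
            model = mdm_fit(CovarianceSet(mats, labels), div)
            for mean in model.class_means.values():
                check_spd(mean)
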