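"""Latent-FC features, feature selection, SVR, bias adjustment, protocols."""

import numpy as np
import pytest

from latentcortex.agepred import (
    bias_adjust,
    chance_mae,
    cross_center_predict,
    crossval_predict,
    fit_rsvm,
    global_network_strength,
    latent_fc,
    prediction_metrics,
    select_features,
)


class TestLatentFC:
    def test_independent_series_near_zero_offdiagonals(self):
        rng = np.random.default_rng(0)
        Z = rng.standard_normal((6, 10_000))
        fc = latent_fc(Z, "covariance")
        assert np.abs(fc.vector).max() < 0.05
        assert np.allclose(fc.matrix, fc.matrix.T)

    def test_duplicated_series_covariance_equals_variance(self):
        rng = np.random.default_rng(1)
        z = rng.standard_normal(500)
        Z = np.stack([z, z, rng.standard_normal(500)])
        fc = latent_fc(Z, "covariance")
        assert fc.matrix[0, 1] == pytest.approx(fc.matrix[0, 0])

    def test_specified_covariance_recovered(self):
        """Sample covariance of long correlated series matches the generating
        matrix to 2% in Frobenius norm."""
        rng = np.random.default_rng(0)
        cov = np.array([[1.0, 0.5, 0.2], [0.5, 2.0, -0.3], [0.2, -0.3, 1.5]])
        L = np.linalg.cholesky(cov)
        Z = L @ rng.standard_normal((3, 50_000))
        fc = latent_fc(Z, "covariance")
        assert np.linalg.norm(fc.matrix - cov) / np.linalg.norm(cov) < 0.02

    def test_vector_is_upper_triangle(self):
        Z = np.random.default_rng(2).standard_normal((256, 10))
        fc = latent_fc(Z)
        assert fc.vector.shape == (32_640,)  # 256*255/2

    def test_correlation_mode_constant_series(self):
        Z = np.vstack([np.ones(10), np.random.default_rng(0).standard_normal(10)])
        with pytest.warns(UserWarning, match="constant"):
            fc = latent_fc(Z, "correlation")
        assert np.isnan(fc.matrix[0, 1])


class TestSelectFeatures:
    def test_age_itself_always_selected(self):
        rng = np.random.default_rng(0)
        ages = rng.uniform(25, 45, 50)
        F = np.column_stack([ages, rng.standard_normal((50, 10))])
        mask, r, p = select_features(F, ages)
        assert mask[0]
        assert r[0] == pytest.approx(1.0)

    def test_null_features_familywise_rate(self):
        """Under a global null, BH selects anything in at most ~alpha of
        replicates (Simes equality; Monte-Carlo slack on 1000 replicates)."""
        rng = np.random.default_rng(0)
        n, m, reps = 100, 500, 1000
        hits = 0
        ages = rng.uniform(25, 45, n)
        for _ in range(reps):
            F = rng.standard_normal((n, m))
            mask, _, _ = select_features(F, ages, alpha=0.05)
            hits += mask.any()
        assert hits / reps <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_uncorrected_variant(self):
        rng = np.random.default_rng(1)
        ages = rng.uniform(25, 45, 60)
        F = np.column_stack([ages + rng.standard_normal(60),
                             rng.standard_normal((60, 5))])
        mask, _, _ = select_features(F, ages, method="uncorrected", alpha=0.01)
        assert mask[0]

    def test_zero_variance_feature_excluded(self):
        rng = np.random.default_rng(2)
        ages = rng.uniform(25, 45, 30)
        F = np.column_stack([np.ones(30), ages])
        with pytest.warns(UserWarning, match="zero-variance"):
            mask, r, _ = select_features(F, ages)
        assert not mask[0] and np.isnan(r[0])


class TestRSVM:
    def test_realizable_function_learned(self):
        rng = np.random.default_rng(0)
        f = rng.uniform(0, 10, 60)
        ages = 2 * f + 1
        model = fit_rsvm(f[:40, None], ages[:40])
        pred = model.predict(f[40:, None])
        assert np.abs(pred - ages[40:]).max() < 0.1 + 1e-3

    def test_constant_ages_predicted(self):
        rng = np.random.default_rng(1)
        F = rng.standard_normal((20, 3))
        model = fit_rsvm(F, np.full(20, 40.0))
        np.testing.assert_allclose(model.predict(F), 40.0, atol=0.2)

    def test_empty_feature_set_rejected(self):
        with pytest.raises(ValueError, match="empty feature set"):
            fit_rsvm(np.zeros((10, 0)), np.arange(10.0))


class TestBiasAdjust:
    def test_unbiased_predictions_near_identity(self):
        rng = np.random.default_rng(0)
        ages = rng.uniform(25, 45, 100)
        adj = bias_adjust(ages, ages)
        assert adj.a == pytest.approx(1.0) and adj.b == pytest.approx(0.0)

    def test_exact_affine_inversion(self):
        ages_val = np.array([30.0, 35.0, 40.0, 44.0])
        pred_val = 0.5 * ages_val + 20
        adj = bias_adjust(pred_val, ages_val)
        ages_test = np.array([28.0, 42.0])
        np.testing.assert_allclose(adj(0.5 * ages_test + 20), ages_test,
                                   atol=1e-10)

    def test_constant_shift(self):
        ages = np.array([30.0, 35.0, 40.0])
        adj = bias_adjust(ages - 2, ages)
        np.testing.assert_allclose(adj(np.array([38.0])), 40.0, atol=1e-10)

    def test_never_degrades_exact_affine_bias(self):
        """Algebraic identity: on the validation set itself, adjusting an
        exactly affine bias yields zero error."""
        rng = np.random.default_rng(0)
        ages = rng.uniform(25, 45, 50)
        pred = -0.7 * ages + 55
        adj = bias_adjust(pred, ages)
        assert np.abs(adj(pred) - ages).max() < 1e-9
        assert np.mean(np.abs(adj(pred) - ages)) <= np.mean(np.abs(pred - ages))

    def test_constant_predictions_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            bias_adjust(np.ones(5), np.arange(5.0))


class TestMetrics:
    def test_perfect_prediction(self):
        m = prediction_metrics(np.array([1.0, 2.0]), np.array([1.0, 2.0]))
        assert m["rmse"] == 0 and m["mae"] == 0
        assert m["r2"] == pytest.approx(1.0)
        assert m["correlation"] == pytest.approx(1.0)

    def test_worked_example(self):
        with pytest.warns(UserWarning):
            m = prediction_metrics(np.array([1.0, 2.0, 3.0]),
                                   np.array([2.0, 2.0, 2.0]))
        assert m["rmse"] == pytest.approx(0.8165, abs=1e-4)
        assert m["mae"] == pytest.approx(0.6667, abs=1e-4)
        assert np.isnan(m["correlation"])

    def test_shift_invariant_correlation(self):
        y = np.array([1.0, 2.0, 3.0])
        m = prediction_metrics(y, y + 1)
        assert m["mae"] == pytest.approx(1.0)
        assert m["correlation"] == pytest.approx(1.0)


class TestProtocols:
    def _network_cohort(self, n=120, T=200, effect=True, seed=0):
        from latentcortex.agepred import fc_feature_matrix
        from latentcortex.synthetic import _ar1_series, default_truth, make_mesh

        mesh = make_mesh(1)
        truth = default_truth(mesh, K=4, seed=0,
                              effect_scale=0.04 if effect else 0.0)
        rng = np.random.default_rng(seed)
        ages = rng.uniform(*truth.age_range, n)
        fcs = [latent_fc(_ar1_series(rng, truth.covariance_at(a), T),
                         age_weeks=float(a)) for a in ages]
        return fc_feature_matrix(fcs)

    def test_split_sizes_match_protocol(self):
        """At the published cohort size (409 usable scans) the tenfold split
        reproduces train/val/test of about 314/55/40."""
        rng = np.random.default_rng(0)
        ages = rng.uniform(25, 45, 409)
        F = np.column_stack([ages + 0.1 * rng.standard_normal(409),
                             rng.standard_normal((409, 5))])
        rep = crossval_predict(F, ages, repeats=1, seed=0)
        train, val, test = rep.split_sizes
        assert abs(train - 314) <= 2
        assert abs(val - 55) <= 2
        assert abs(test - 40) <= 2

    def test_noiseless_linear_feature_gives_zero_mae(self):
        rng = np.random.default_rng(0)
        ages = rng.uniform(25, 45, 60)
        F = np.column_stack([(ages - 35) / 2, rng.standard_normal((60, 3))])
        rep = crossval_predict(F, ages, repeats=1, seed=0)
        assert rep.mae.max() < 0.2

    def test_effect_size_monotonicity(self):
        """Median MAE decreases as the generative age effect grows."""
        maes = []
        from latentcortex.agepred import fc_feature_matrix
        from latentcortex.synthetic import _ar1_series, default_truth, make_mesh

        mesh = make_mesh(1)
        for scale in (0.0, 0.02, 0.04):
            truth = default_truth(mesh, K=4, seed=0, effect_scale=scale)
            rng = np.random.default_rng(1)
            ages = rng.uniform(*truth.age_range, 120)
            fcs = [latent_fc(_ar1_series(rng, truth.covariance_at(a), 200),
                             age_weeks=float(a)) for a in ages]
            F, ag = fc_feature_matrix(fcs)
            try:
                rep = crossval_predict(F, ag, repeats=1, seed=0,
                                       selection="uncorrected", alpha=0.01)
                maes.append(np.median(rep.mae))
            except ValueError:
                maes.append(chance_mae(ag))
        assert maes[2] < maes[1] < maes[0]

    def test_global_network_strength(self):
        v = np.array([0.3, 0.5, -0.2])
        assert global_network_strength(v, [True, True, False]) == pytest.approx(0.8)
        assert global_network_strength(2 * v, [True, True, False]) == \
            pytest.approx(1.6)
        with pytest.raises(ValueError, match="no positively"):
            global_network_strength(v, [False, False, False])

    def test_cross_center_transfer(self):
        """Training on one acquisition profile and testing on another still
        beats the mean-age predictor when the truth is shared."""
        F_tr, a_tr = self._network_cohort(n=150, T=300, seed=0)
        F_te, a_te = self._network_cohort(n=60, T=80, seed=5)
        rep = cross_center_predict(F_tr, a_tr, F_te, a_te, repeats=5, seed=0)
        assert rep.mae.mean() < chance_mae(a_te)
        assert rep.n_repeats == 5

    def test_cross_center_default_repeats(self):
        import inspect

        sig = inspect.signature(cross_center_predict)
        assert sig.parameters["repeats"].default == 100
        assert inspect.signature(crossval_predict).parameters["repeats"].default == 100
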