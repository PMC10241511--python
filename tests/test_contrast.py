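"""Component-variance age effects, group splits, dual regression, difference maps."""

import numpy as np
import pytest

from latentcortex.contrast import (
    ic_variance,
    latent_difference_map,
    split_age_groups,
    variance_age_correlation,
)
from latentcortex.vae import LatentTimeseries


def _lt(mu):
    mu = np.asarray(mu, dtype=float)
    return LatentTimeseries(mu=mu, sigma=np.ones_like(mu))


class TestICVariance:
    def test_standardized_series_unit_variance(self):
        rng = np.random.default_rng(0)
        z = rng.standard_normal((4, 500))
        z = (z - z.mean(1, keepdims=True)) / z.std(1, ddof=1, keepdims=True)
        v = ic_variance(_lt(z), np.eye(4))
        np.testing.assert_allclose(v, 1.0, atol=1e-10)

    def test_constant_series_zero(self):
        v = ic_variance(_lt(np.ones((2, 10))), np.eye(2))
        np.testing.assert_allclose(v, 0.0)

    def test_linear_transform_algebra(self):
        """W = diag(1, 2) doubles the second series: variances (1, 4)."""
        rng = np.random.default_rng(1)
        z = rng.standard_normal((2, 2000))
        z = (z - z.mean(1, keepdims=True)) / z.std(1, ddof=1, keepdims=True)
        W = np.array([[1.0, 0.0], [0.0, 2.0]])
        v = ic_variance(_lt(z), W)
        assert v[0] == pytest.approx(1.0, abs=1e-8)
        assert v[1] == pytest.approx(4.0, abs=1e-8)

    def test_too_few_frames(self):
        with pytest.raises(ValueError):
            ic_variance(_lt(np.ones((2, 2))), np.eye(2))


class TestVarianceAgeCorrelation:
    def test_null_false_discovery_proportion(self):
        """Age-independent variances: mean FDP over replicates stays at the
        nominal FDR level (Monte-Carlo slack on 1000 replicates)."""
        rng = np.random.default_rng(0)
        n, k, reps = 40, 30, 1000
        fdp = 0.0
        for _ in range(reps):
            ages = rng.uniform(25, 45, n)
            variances = rng.chisquare(20, size=(n, k)) / 20
            _, _, sig = variance_age_correlation(variances, ages)
            fdp += sig.any()
        fdp /= reps
        assert fdp <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_injected_component_detected_with_positive_r(self):
        rng = np.random.default_rng(1)
        n, k, T = 80, 30, 150
        ages = rng.uniform(24.3, 44.9, n)
        variances = np.empty((n, k))
        for i, a in enumerate(ages):
            series = rng.standard_normal((k, T))
            series[4] *= np.sqrt(1.0 + 0.05 * (a - 34.6))
            variances[i] = series.var(axis=1, ddof=1)
        r, p, sig = variance_age_correlation(variances, ages)
        assert sig[4] and r[4] > 0

    def test_constant_ages_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            variance_age_correlation(np.ones((10, 3)) +
                                     np.random.default_rng(0).random((10, 3)),
                                     np.full(10, 40.0))

    def test_zero_variance_component_excluded(self):
        rng = np.random.default_rng(2)
        V = rng.random((20, 3))
        V[:, 1] = 0.7
        with pytest.warns(UserWarning, match="zero-variance"):
            r, _, sig = variance_age_correlation(V, rng.uniform(30, 44, 20))
        assert np.isnan(r[1]) and not sig[1]


class TestSplit:
    def test_threshold_example(self):
        s = split_age_groups(np.array([38.0, 40.0, 44.0]))
        assert s.young.tolist() == [0]
        assert s.median.tolist() == [1]
        assert s.old.tolist() == [2]
        assert (s.threshold_low, s.threshold_high) == (39.0, 43.0)

    def test_all_median_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            s = split_age_groups(np.full(5, 41.0))
        assert s.young.size == 0 and s.old.size == 0 and s.median.size == 5

    def test_boundaries_inclusive(self):
        s = split_age_groups(np.array([39.0, 43.0]))
        assert s.young.tolist() == [0] and s.old.tolist() == [1]

    def test_bad_thresholds(self):
        with pytest.raises(ValueError):
            split_age_groups(np.array([40.0]), low=43, high=39)


class TestGroupNetworkMap:
    def _group_latents(self, n_subjects=8, k=12, T=400, seed=0):
        rng = np.random.default_rng(seed)
        mix = rng.standard_normal((k, 4))
        return [_lt(mix @ rng.laplace(size=(4, T))
                    + 0.05 * rng.standard_normal((k, T)))
                for _ in range(n_subjects)]

    def test_full_cohort_map_matches_component_map(self):
        """Dual regression over the whole cohort reproduces the component's
        own cortical map (r >= 0.9)."""
        from latentcortex.contrast import group_network_map
        from latentcortex.networks import basis_to_cortex, temporal_ica, concat_latents

        latents = self._group_latents()
        Z, _ = concat_latents(latents)
        nb = temporal_ica(Z, n_components=4, seed=0)
        rng = np.random.default_rng(1)
        D = rng.standard_normal((200, 12))
        dec = lambda M: D @ M
        gmap = group_network_map(latents, nb, 0, dec, None, seed=3)
        cmap = basis_to_cortex(nb.mixing[:, 0], dec, None, seed=3)
        assert np.corrcoef(gmap.values, cmap.values)[0, 1] >= 0.9

    def test_single_subject_group_defined(self):
        from latentcortex.contrast import group_network_map
        from latentcortex.networks import temporal_ica, concat_latents

        latents = self._group_latents(n_subjects=3, seed=2)
        Z, _ = concat_latents(latents)
        nb = temporal_ica(Z, n_components=4, seed=0)
        D = np.random.default_rng(0).standard_normal((50, 12))
        gmap = group_network_map(latents[:1], nb, 1, lambda M: D @ M, None)
        assert np.all(np.isfinite(gmap.values))

    def test_amplified_network_strengthens_group_map(self):
        """Doubling one source's amplitude in a subgroup increases that
        component's group-map magnitude relative to the baseline group."""
        from latentcortex.contrast import group_network_map
        from latentcortex.networks import temporal_ica, concat_latents

        rng = np.random.default_rng(3)
        k = 12
        mix = rng.standard_normal((k, 4))
        base = [_lt(mix @ rng.laplace(size=(4, 400))) for _ in range(6)]
        S = [rng.laplace(size=(4, 400)) for _ in range(6)]
        loud = [_lt(mix @ (s * np.array([2.0, 1, 1, 1])[:, None])) for s in S]
        Z, _ = concat_latents(base + loud)
        nb = temporal_ica(Z, n_components=4, seed=0)
        # find the component whose basis matches mix[:, 0]
        comp = int(np.argmax(np.abs(
            (mix[:, 0] / np.linalg.norm(mix[:, 0])) @
            (nb.mixing / np.linalg.norm(nb.mixing, axis=0)))))
        D = rng.standard_normal((100, k))
        dec = lambda M: D @ M
        m_base = group_network_map(base, nb, comp, dec, None, seed=4)
        m_loud = group_network_map(loud, nb, comp, dec, None, seed=4)
        assert np.linalg.norm(m_loud.values) > np.linalg.norm(m_base.values)

    def test_empty_group_rejected(self):
        from latentcortex.contrast import dual_regression_basis

        with pytest.raises(ValueError, match="empty"):
            dual_regression_basis([], None, 0)


class TestDifferenceMap:
    def test_linear_decoder_proportionality(self):
        rng = np.random.default_rng(0)
        D = rng.standard_normal((120, 8))
        a, b = rng.standard_normal((2, 8))
        m = latent_difference_map(a, b, lambda Z: D @ Z, None,
                                  n_scales=2000, seed=3)
        r = np.corrcoef(m.values, D @ (a - b))[0, 1]
        assert r >= 0.999

    def test_antisymmetry_exact_for_fixed_seed(self):
        rng = np.random.default_rng(1)
        D = rng.standard_normal((60, 6))
        dec = lambda Z: np.tanh(D @ Z)  # nonlinear decoder
        a, b = rng.standard_normal((2, 6))
        m_ab = latent_difference_map(a, b, dec, None, n_scales=500, seed=5)
        m_ba = latent_difference_map(b, a, dec, None, n_scales=500, seed=5)
        np.testing.assert_allclose(m_ab.values, -m_ba.values, atol=1e-12)

    def test_identical_groups_zero_map(self):
        rng = np.random.default_rng(2)
        D = rng.standard_normal((60, 6))
        a = rng.standard_normal(6)
        m = latent_difference_map(a, a, lambda Z: np.tanh(D @ Z), None,
                                  n_scales=500, seed=5)
        assert np.abs(m.values).max() == 0.0

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            latent_difference_map(np.zeros(4), np.zeros(5), lambda Z: Z, None)
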