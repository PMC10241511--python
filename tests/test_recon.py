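"""Reconstruction degree, Fisher aggregation, smoothing, partial r, ICC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from latentcortex.io import CorticalTimeseries
from latentcortex.recon import (
    adjusted_correlation,
    fisher_mean,
    intersession_consistency,
    reconstruction_degree,
    smoothing_profile,
    surface_smooth,
)


class TestReconstructionDegree:
    def test_perfect_and_inverted(self):
        X = np.random.default_rng(0).standard_normal((50, 4))
        np.testing.assert_allclose(reconstruction_degree(X, X), np.ones(4),
                                   atol=1e-12)
        np.testing.assert_allclose(reconstruction_degree(X, -X), -np.ones(4),
                                   atol=1e-12)

    def test_worked_example(self):
        x = np.array([[1.0], [2.0], [3.0], [4.0]])
        x_rec = np.array([[1.0], [2.0], [3.0], [5.0]])
        r = reconstruction_degree(x, x_rec)[0]
        assert r == pytest.approx(0.9827, abs=1e-4)

    def test_constant_frame_missing_with_warning(self):
        X = np.random.default_rng(0).standard_normal((10, 2))
        X_rec = X.copy()
        X_rec[:, 1] = 3.0
        with pytest.warns(UserWarning, match="constant"):
            r = reconstruction_degree(X, X_rec)
        assert np.isnan(r[1]) and not np.isnan(r[0])

    def test_mask_restricts_vertices(self):
        X = np.zeros((6, 1))
        X[:3, 0] = [1, 2, 3]
        X_rec = np.zeros((6, 1))
        X_rec[:3, 0] = [1, 2, 3]
        X_rec[3:, 0] = [9, 9, 9]  # disagreement outside the mask is ignored
        mask = np.array([1, 1, 1, 0, 0, 0], bool)
        assert reconstruction_degree(X, X_rec, mask)[0] == pytest.approx(1.0)


class TestFisherMean:
    def test_examples(self):
        assert fisher_mean([0.0, 0.0, 0.0]) == 0.0
        assert fisher_mean([0.5, 0.5]) == pytest.approx(0.5)
        assert fisher_mean([0.2, 0.8]) == pytest.approx(0.5722, abs=1e-4)

    def test_missing_skipped_and_all_missing_errors(self):
        assert fisher_mean([0.3, np.nan]) == pytest.approx(0.3)
        with pytest.raises(ValueError):
            fisher_mean([np.nan, np.nan])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-0.999, 0.999), min_size=1, max_size=20))
    def test_bounded_by_inputs(self, rs):
        m = fisher_mean(rs)
        assert min(rs) - 1e-12 <= m <= max(rs) + 1e-12

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(-0.9, 0.89), min_size=2, max_size=10),
           st.floats(0.001, 0.1))
    def test_monotone_under_elementwise_increase(self, rs, bump):
        assert fisher_mean([r + bump for r in rs]) > fisher_mean(rs)


class TestSurfaceSmooth:
    def test_fwhm_zero_is_identity(self, mesh3):
        ts = CorticalTimeseries(
            values=np.random.default_rng(0).standard_normal(
                (mesh3.n_vertices, 3)), mesh_id=mesh3.mesh_id)
        out = surface_smooth(ts, mesh3, 0.0)
        assert np.array_equal(out.values, ts.values)

    def test_constant_field_unchanged(self, mesh3):
        ts = CorticalTimeseries(values=np.full((mesh3.n_vertices, 1), 2.5),
                                mesh_id=mesh3.mesh_id)
        out = surface_smooth(ts, mesh3, 7.0)
        np.testing.assert_allclose(out.values, 2.5, atol=1e-12)

    def test_negative_fwhm_rejected(self, mesh3):
        ts = CorticalTimeseries(values=np.zeros((mesh3.n_vertices, 1)),
                                mesh_id=mesh3.mesh_id)
        with pytest.raises(ValueError):
            surface_smooth(ts, mesh3, -1.0)

    def test_impulse_half_maximum_radius(self, mesh4):
        """A unit impulse smoothed at FWHM f has half-maximum response at
        geodesic radius f/2 (within discretization error)."""
        from scipy.sparse.csgraph import dijkstra

        from latentcortex._smooth import edge_graph

        fwhm = 6.0
        vidx = 123
        imp = np.zeros((mesh4.n_vertices, 1))
        imp[vidx] = 1.0
        ts = CorticalTimeseries(values=imp, mesh_id=mesh4.mesh_id)
        out = surface_smooth(ts, mesh4, fwhm).values[:, 0]
        idx = mesh4.hemi_indices("L")
        g = edge_graph(mesh4.vertices[idx], mesh4.hemi_triangles("L"))
        d = dijkstra(g, indices=[vidx], directed=False)[0]
        half_radius = d[out[idx] >= out[vidx] / 2].max()
        assert abs(half_radius - fwhm / 2) / (fwhm / 2) < 0.20

    def test_no_mixing_across_hemispheres(self, mesh3):
        n = mesh3.n_vertices // 2
        imp = np.zeros((mesh3.n_vertices, 1))
        imp[5] = 1.0  # left hemisphere
        ts = CorticalTimeseries(values=imp, mesh_id=mesh3.mesh_id)
        out = surface_smooth(ts, mesh3, 10.0).values[:, 0]
        assert np.all(out[n:] == 0)


class TestSmoothingProfile:
    def test_identity_reconstruction_peaks_at_boundary(self, mesh3):
        X = np.random.default_rng(0).standard_normal((mesh3.n_vertices, 5))
        curve, eff, boundary = smoothing_profile(X, X, mesh3)
        assert eff == 1.0 and boundary

    def test_explicit_smoothing_recovered(self, mesh3):
        """A reconstruction built by smoothing at 5 mm is diagnosed with an
        effective FWHM of exactly 5 mm."""
        rng = np.random.default_rng(1)
        X = rng.standard_normal((mesh3.n_vertices, 6))
        ts = CorticalTimeseries(values=X, mesh_id=mesh3.mesh_id)
        X_rec = surface_smooth(ts, mesh3, 5.0).values
        curve, eff, boundary = smoothing_profile(X, X_rec, mesh3)
        assert eff == 5.0 and not boundary

    def test_more_smoothed_model_peaks_later(self, mesh4):
        """Profiles of 3 mm- and 7 mm-smoothed reconstructions peak in
        order, without requiring the curves to cross.  Uses the finer mesh:
        kernels below ~5 mm are under the subdivision-3 edge length."""
        rng = np.random.default_rng(2)
        X = rng.standard_normal((mesh4.n_vertices, 4))
        ts = CorticalTimeseries(values=X, mesh_id=mesh4.mesh_id)
        _, eff3, _ = smoothing_profile(
            X, surface_smooth(ts, mesh4, 3.0).values, mesh4)
        _, eff7, _ = smoothing_profile(
            X, surface_smooth(ts, mesh4, 7.0).values, mesh4)
        assert eff3 == 3.0 and eff7 == 7.0 and eff7 > eff3

    def test_default_grid_is_1_to_10(self, mesh3):
        X = np.random.default_rng(0).standard_normal((mesh3.n_vertices, 2))
        curve, _, _ = smoothing_profile(X, X, mesh3)
        assert len(curve) == 10


class TestAdjustedCorrelation:
    def test_no_covariates_reduces_to_pearson(self):
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal((2, 100))
        r, p = adjusted_correlation(x, y)
        assert r == pytest.approx(np.corrcoef(x, y)[0, 1])

    def test_perfect_confound_removed(self):
        rng = np.random.default_rng(1)
        c = rng.standard_normal(200)
        x = 2 * c + rng.standard_normal(200)
        r, p = adjusted_correlation(x, c, covariates=c)
        assert abs(r) < 1e-10

    def test_shared_confound_only(self):
        """x and y share only a covariate-driven component: plain r is large
        but the partial r falls inside the null band."""
        rng = np.random.default_rng(0)
        n = 500
        c = rng.standard_normal(n)
        x = c + 0.5 * rng.standard_normal(n)
        y = c + 0.5 * rng.standard_normal(n)
        plain, _ = adjusted_correlation(x, y)
        partial, p = adjusted_correlation(x, y, covariates=c)
        assert plain > 0.6
        assert abs(partial) < 2.5 / np.sqrt(n)
        assert p > 0.01

    def test_rank_deficient_covariates_rejected(self):
        x = np.arange(10.0)
        cov = np.ones((10, 2))
        with pytest.raises(ValueError, match="rank"):
            adjusted_correlation(x, x, covariates=cov)


class TestIntersessionConsistency:
    def test_identical_sessions(self):
        rng = np.random.default_rng(0)
        s = rng.standard_normal(30)
        ages = rng.uniform(30, 45, 30)
        r, p, icc = intersession_consistency(s, s, ages, ages + 3)
        assert r == pytest.approx(1.0)
        assert icc == pytest.approx(1.0)

    def test_independent_scores_in_null_band(self):
        rng = np.random.default_rng(1)
        n = 1000
        s1, s2 = rng.standard_normal((2, n))
        ages = rng.uniform(28, 44, n)
        r, p, icc = intersession_consistency(s1, s2, ages,
                                             ages + rng.uniform(2, 10, n))
        band = 3 / np.sqrt(n)
        assert abs(r) < band and abs(icc) < band

    def test_variance_components_recovered(self):
        """Subject effect carrying half the variance: ICC(2,1) ~ 0.5."""
        rng = np.random.default_rng(0)
        n = 1000
        subject = rng.standard_normal(n) * np.sqrt(0.5)
        s1 = subject + rng.standard_normal(n) * np.sqrt(0.5)
        s2 = subject + rng.standard_normal(n) * np.sqrt(0.5)
        a1 = rng.uniform(30, 44, n)
        a2 = a1 + rng.uniform(2, 12, n)
        _, _, icc = intersession_consistency(s1, s2, a1, a2)
        assert icc == pytest.approx(0.5, abs=0.07)

    def test_unpaired_rejected(self):
        with pytest.raises(ValueError):
            intersession_consistency([1, 2, 3], [1, 2], [30, 31, 32], [33, 34])
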