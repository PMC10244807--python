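"""Pair-correlation estimators against closed-form and direct-sum oracles."""

import numpy as np
import pytest
from scipy.optimize import curve_fit
from scipy.signal import correlate2d
from shapely.geometry import Polygon

from nanofa.correlation import (_bin_points, _mask_raster,
                                average_correlations, fit_c_tail_exponential,
                                fit_g_two_exponential, pair_autocorrelation,
                                pair_crosscorrelation)

SQ1000 = Polygon([(0, 0), (1000, 0), (1000, 1000), (0, 1000)])


def brute_force_g(pts, poly, r_max, bin_width, grid):
    """Direct-space oracle: same discretization, direct summation instead
    of FFT for both the pair histogram and the mask autocorrelation."""
    M, origin = _mask_raster(poly, grid, poly.bounds)
    H = _bin_points(pts, origin, grid, M.shape) * M.astype(bool)
    SH = correlate2d(H, H, mode="full")
    SA = correlate2d(M, M, mode="full")
    cy, cx = M.shape[0] - 1, M.shape[1] - 1
    SH[cy, cx] -= H.sum()
    dy = np.abs(np.arange(SH.shape[0]) - cy)
    dx = np.abs(np.arange(SH.shape[1]) - cx)
    R = np.hypot(dy[:, None], dx[None, :]) * grid
    nbin = int(r_max // bin_width)
    edges = np.arange(nbin + 1) * bin_width
    which = np.digitize(R.ravel(), edges) - 1
    ok = (which >= 0) & (which < nbin)
    num = np.bincount(which[ok], weights=SH.ravel()[ok], minlength=nbin)
    den = np.bincount(which[ok], weights=SA.ravel()[ok], minlength=nbin)
    lam = H.sum() / M.sum()
    return num / (lam ** 2 * den)


class TestAutocorrelation:
    def test_csr_is_uncorrelated(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 2000, size=(10_000, 2))
        poly = Polygon([(0, 0), (2000, 0), (2000, 2000), (0, 2000)])
        r, g = pair_autocorrelation(pts, poly, r_max=500)
        assert abs(np.nanmean(g) - 1.0) < 0.05
        # disk mask too
        disk = Polygon([(1000 + 900 * np.cos(t), 1000 + 900 * np.sin(t))
                        for t in np.linspace(0, 2 * np.pi, 64)])
        import shapely
        inside = shapely.contains_xy(disk, pts[:, 0], pts[:, 1])
        r, g = pair_autocorrelation(pts[inside], disk, r_max=500)
        assert abs(np.nanmean(g) - 1.0) < 0.05

    def test_gaussian_clusters_recover_cluster_sd(self):
        # g(r) - 1 ~ exp(-r^2 / 4 s^2) for Gaussian clusters of SD s
        rng = np.random.default_rng(1)
        s = 40.0
        centers = rng.uniform(0, 2000, size=(60, 2))
        pts = np.vstack([c + rng.normal(0, s, size=(25, 2))
                         for c in centers])
        poly = Polygon([(0, 0), (2000, 0), (2000, 2000), (0, 2000)])
        r, g = pair_autocorrelation(pts, poly, r_max=400, bin_width=10)
        ok = (r > 15) & (r < 300) & np.isfinite(g)

        def model(r, a, s_eff):
            return 1 + a * np.exp(-r ** 2 / (4 * s_eff ** 2))

        popt, _ = curve_fit(model, r[ok], g[ok], p0=(5, 30))
        assert popt[1] == pytest.approx(s, rel=0.15)

    def test_fft_matches_direct_sum_oracle(self):
        rng = np.random.default_rng(2)
        centers = rng.uniform(100, 900, size=(30, 2))
        pts = np.vstack([c + rng.normal(0, 20, size=(12, 2))
                         for c in centers])   # 360 points <= 1000
        r, g = pair_autocorrelation(pts, SQ1000, r_max=300)
        g2 = brute_force_g(pts, SQ1000, 300, 10, 5)
        ok = np.isfinite(g) & np.isfinite(g2) & (g2 > 0)
        assert np.max(np.abs(g[ok] - g2[ok]) / g2[ok]) < 0.02

    def test_requires_enough_points(self):
        with pytest.raises(ValueError, match="50 points"):
            pair_autocorrelation(np.zeros((10, 2)), SQ1000)


class TestCrosscorrelation:
    def test_independent_patterns_flat(self):
        rng = np.random.default_rng(3)
        A = rng.uniform(0, 1000, size=(4000, 2))
        B = rng.uniform(0, 1000, size=(4000, 2))
        r, c = pair_crosscorrelation(A, B, SQ1000, r_max=300)
        assert abs(np.nanmean(c) - 1.0) < 0.05

    def test_identical_patterns_equal_autocorrelation_beyond_zero(self):
        rng = np.random.default_rng(4)
        centers = rng.uniform(100, 900, size=(40, 2))
        pts = np.vstack([c + rng.normal(0, 25, size=(20, 2))
                         for c in centers])
        r, g = pair_autocorrelation(pts, SQ1000, r_max=300)
        rc, c = pair_crosscorrelation(pts, pts, SQ1000, r_max=300)
        # identical except the self-pair contribution near r = 0
        assert np.allclose(g[2:], c[2:], rtol=0.05)

    def test_co_clustered_positive_at_cluster_scale(self):
        rng = np.random.default_rng(5)
        centers = rng.uniform(0, 2000, size=(40, 2))
        A = np.vstack([c + rng.normal(0, 60, size=(20, 2)) for c in centers])
        B = np.vstack([c + rng.normal(0, 60, size=(20, 2)) for c in centers])
        poly = Polygon([(0, 0), (2000, 0), (2000, 2000), (0, 2000)])
        r, c = pair_crosscorrelation(A, B, poly, r_max=600)
        assert np.nanmean(c[(r > 20) & (r < 120)]) > 1.5
        assert abs(np.nanmean(c[r > 450]) - 1) < 0.2


class TestGFits:
    def test_two_scale_recovery_on_analytic_curve(self):
        r = np.arange(5, 800, 10.0)
        g = 1 + 3.0 * np.exp(-r / 25) + 0.3 * np.exp(-r / 150)
        fit = fit_g_two_exponential(r, g)
        assert fit.xi1 == pytest.approx(25, rel=0.1)
        assert fit.xi2 == pytest.approx(150, rel=0.1)
        assert fit.xi1 < fit.xi2

    def test_flat_g_zero_amplitudes(self):
        r = np.arange(5, 800, 10.0)
        fit = fit_g_two_exponential(r, np.ones_like(r))
        assert fit.A1 < 0.01 and fit.A2 < 0.01

    def test_scene_autocorrelation_recovers_both_scales(self, square_scene):
        # islands-in-clusters molecules: the short scale follows the island
        # geometry (exponential fit of a d=32 disk pattern gives
        # 2 xi1 ~ d/2), the long scale the 300-nm loose clusters
        cfg, truth = square_scene
        pts = truth.molecules[truth.molecules.island_id >= 0]
        r, g = pair_autocorrelation(pts, Polygon(cfg.fa_polygon), r_max=800)
        fit = fit_g_two_exponential(r, g)
        assert 2 * fit.xi1 == pytest.approx(16, rel=0.5)
        assert 2 * fit.xi2 == pytest.approx(300, rel=0.3)


class TestCTailFit:
    def test_closed_form_306(self):
        r = np.arange(5, 800, 10.0)
        c = 1 + np.exp(-r / 153.0)
        fit = fit_c_tail_exponential(r, c)
        assert 2 * fit.xi2 == pytest.approx(306, rel=0.01)

    def test_flat_tail_flagged(self):
        r = np.arange(5, 800, 10.0)
        with pytest.warns(UserWarning, match="flat|ill"):
            fit = fit_c_tail_exponential(r, np.ones_like(r))
        assert fit.flagged

    def test_shared_cluster_scenes_match_geometry_oracle(self, square_scene):
        # two protein channels in disjoint islands of the same 300-nm
        # clusters: c(r) - 1 follows the cluster-disk overlap (set
        # covariance), whose own tail fit defines the expected length
        from nanofa.synthetic import SceneConfig, generate_fa_scene
        cfg, A = square_scene
        B = generate_fa_scene(
            SceneConfig(fa_polygon=cfg.fa_polygon, island_diameter_law=32.0,
                        island_density=0.02, background_density=0.002,
                        cluster_diameter=300.0, islands_per_cluster=8,
                        n_clusters=6, seed=4),
            cluster_centers=A.clusters[["x_nm", "y_nm"]].to_numpy())
        pa = A.molecules[A.molecules.island_id >= 0]
        pb = B.molecules[B.molecules.island_id >= 0]
        r, c = pair_crosscorrelation(pa, pb, Polygon(cfg.fa_polygon),
                                     r_max=800)
        fit = fit_c_tail_exponential(r, c)

        # oracle: isotropic set covariance of a disk of radius R, for the
        # island-center displacement within one cluster ~ difference of two
        # uniform-in-disk draws; its density is prop. to the disk overlap
        R = 150.0
        rr = np.arange(155, 700, 10.0)
        ov = np.where(rr < 2 * R,
                      2 * R ** 2 * np.arccos(np.minimum(rr / (2 * R), 1))
                      - rr / 2 * np.sqrt(np.maximum(4 * R ** 2 - rr ** 2, 0)),
                      0.0)
        expected = fit_c_tail_exponential(
            np.arange(5, 700, 10.0),
            1 + 5 * np.interp(np.arange(5, 700, 10.0), rr, ov / ov[0],
                              left=1.0, right=0.0))
        assert 2 * fit.xi2 == pytest.approx(2 * expected.xi2, rel=0.3)


def test_average_correlations_sem():
    r = np.arange(5)
    curves = [(r, np.full(5, v)) for v in (1.0, 2.0, 3.0)]
    r0, mean, sem = average_correlations(curves)
    assert np.allclose(mean, 2.0)
    assert np.allclose(sem, np.std([1, 2, 3], ddof=1) / np.sqrt(3))
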