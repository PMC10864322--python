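"""Elliptical pRF model: field evaluation, forward model, two-stage fit."""

import numpy as np
import pytest

from prfaniso.hirf import HIRFParams
from prfaniso.prf import DegenerateSeriesError, PRFFitter, PRFParams, \
    evaluate_prf, predict_bold
from prfaniso.stimulus import ScanConfig, StimulusMovie


@pytest.fixture(scope="module")
def fitter(movies, hirf):
    return PRFFitter(movies, hirf)


class TestEvaluate:
    def test_isotropic_reduction(self):
        grid = np.linspace(-7.9, 7.9, 80)
        p_iso = PRFParams(2.0, 1.0, 0.7, 1.0)
        g = evaluate_prf(p_iso, grid, grid)
        xx, yy = np.meshgrid(grid, grid)
        expected = np.exp(-((xx - 2.0) ** 2 + (yy - 1.0) ** 2) / (2 * 0.7 ** 2))
        assert np.max(np.abs(g - expected)) < 1e-12

    def test_peak_value_one_at_center(self):
        grid = np.linspace(-8, 8, 401)   # grid hits the centre exactly
        g = evaluate_prf(PRFParams(2.0, 0.0, 0.5, 1.5), grid, grid)
        assert np.max(g) == pytest.approx(1.0, abs=1e-12)

    def test_half_max_axes_on_horizontal_meridian(self):
        """Centre on +x: the long half-max axis lies along x with ratio AR."""
        grid = np.arange(-7.9, 7.9, 0.01)
        p = PRFParams(3.0, 0.0, 0.5, 2.0)
        g = evaluate_prf(p, grid, grid)
        iy = np.argmin(np.abs(grid))
        ix = np.argmin(np.abs(grid - 3.0))
        x_extent = (g[iy, :] >= 0.5).sum()
        y_extent = (g[:, ix] >= 0.5).sum()
        assert x_extent / y_extent == pytest.approx(2.0, rel=0.02)

    def test_rotation_equivariance(self):
        """The oblique-centre field equals the meridian field rotated."""
        grid = np.arange(-7.9, 7.9, 0.05)
        xx, yy = np.meshgrid(grid, grid)
        g_oblique = evaluate_prf(
            PRFParams(3 / np.sqrt(2), 3 / np.sqrt(2), 0.5, 2.0), grid, grid)
        # evaluate the meridian pRF at coordinates rotated by -45 deg
        c = np.cos(np.pi / 4)
        xr = c * xx + c * yy
        yr = -c * xx + c * yy
        expected = np.exp(-((xr - 3.0) ** 2) / (2 * (0.5 * np.sqrt(2)) ** 2)
                          - yr ** 2 / (2 * (0.5 / np.sqrt(2)) ** 2))
        assert np.max(np.abs(g_oblique - expected)) < 1e-12

    def test_width_decomposition_exact(self):
        p = PRFParams(1.0, 2.0, 0.63, 1.7)
        assert p.sigma_radial * p.sigma_tangential == pytest.approx(
            p.sigma ** 2, rel=1e-12)


class TestForwardModel:
    def test_zero_movie_zero_series(self, ring_movie, hirf):
        movie = StimulusMovie(ring_movie.grid_x, ring_movie.grid_y,
                              np.zeros_like(ring_movie.frames),
                              ring_movie.frame_duration)
        pred = predict_bold(PRFParams(2, 2, 0.5), movie, hirf)
        assert np.allclose(pred, 0.0)

    def test_constant_movie_flat_series(self, ring_movie, hirf):
        movie = StimulusMovie(ring_movie.grid_x, ring_movie.grid_y,
                              np.ones_like(ring_movie.frames),
                              ring_movie.frame_duration)
        pred = predict_bold(PRFParams(2, 2, 0.5), movie, hirf,
                            frames_per_cycle=16)
        # steady state throughout thanks to the periodic edge handling
        assert np.std(pred) / np.mean(pred) < 1e-6

    def test_ring_response_peaks_when_ring_crosses_prf(self, ring_movie, hirf):
        """Response peak lags the aperture's eccentricity crossing by the
        hemodynamic delay."""
        from prfaniso.stimulus import RING_ECCENTRICITIES_DEG
        prf = PRFParams(3.0, 0.0, 0.4)
        pred = predict_bold(prf, ring_movie, hirf, frames_per_cycle=16)
        cycle = pred[:16]
        crossing = int(np.argmin(np.abs(np.asarray(RING_ECCENTRICITIES_DEG)
                                        - 3.0)))
        delay_frames = 5.0 / 1.5    # canonical peak latency / TR
        expected = crossing + delay_frames
        best = np.argmax(np.mean(pred.reshape(9, 16), axis=0))
        assert abs(best - expected) <= 1.5


class TestFitting:
    def test_noiseless_recovery(self, fitter, movies, hirf):
        truth = PRFParams(2.12, 2.12, 0.5, 1.4)
        series = np.concatenate([
            predict_bold(truth, m, hirf, frames_per_cycle=16) for m in movies])
        s1, s2 = fitter.fit_voxel(series)
        d = min(np.hypot(s1.params.x0 - 2.12, s1.params.y0 - 2.12),
                np.hypot(s1.params.x0 + 2.12, s1.params.y0 + 2.12))
        assert d < 0.05
        assert s1.r > 0.99      # isotropic stage on elliptical-truth data
        assert s2.r > 0.999
        assert s2.params.sigma_radial == pytest.approx(truth.sigma_radial,
                                                       rel=0.05)
        assert s2.params.sigma_tangential == pytest.approx(
            truth.sigma_tangential, rel=0.05)

    def test_isotropic_truth_recovers_near_unity_ar(self, fitter, movies, hirf):
        truth = PRFParams(-3.0, 1.0, 0.8, 1.0)
        series = np.concatenate([
            predict_bold(truth, m, hirf, frames_per_cycle=16) for m in movies])
        _, s2 = fitter.fit_voxel(series)
        assert abs(np.log(s2.params.ar)) < 0.05

    def test_fit_invariant_to_scale_and_offset(self, fitter, movies, hirf):
        truth = PRFParams(2.5, -1.5, 0.6, 1.2)
        series = np.concatenate([
            predict_bold(truth, m, hirf, frames_per_cycle=16) for m in movies])
        _, a = fitter.fit_voxel(series)
        _, b = fitter.fit_voxel(series * 10.0 + 5.0)
        assert a.params.sigma == pytest.approx(b.params.sigma, abs=1e-6)
        assert a.params.ar == pytest.approx(b.params.ar, abs=1e-6)

    def test_noise_series_fits_poorly(self, fitter, rng):
        series = rng.normal(0.0, 1.0, fitter.n_frames)
        s1, _ = fitter.fit_voxel(series)
        assert s1.r < 0.5

    def test_constant_series_rejected(self, fitter):
        with pytest.raises(DegenerateSeriesError):
            fitter.fit_isotropic(np.ones(fitter.n_frames))

    def test_decomposition_identity_on_fits(self, fitter, movies, hirf):
        truth = PRFParams(1.8, 3.2, 0.7, 0.8)
        series = np.concatenate([
            predict_bold(truth, m, hirf, frames_per_cycle=16) for m in movies])
        _, s2 = fitter.fit_voxel(series)
        p = s2.params
        assert p.sigma_radial * p.sigma_tangential == pytest.approx(
            p.sigma ** 2, rel=1e-12)
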