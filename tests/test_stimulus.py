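"""Stimulus design: ladders, size/frequency rules, rasterised movies."""

import numpy as np
import pytest

from prfaniso import stimulus as st


class TestSizeAndFrequencyRules:
    def test_gabor_size_anchors_and_interior(self):
        assert st.gabor_size_at(1.0) == pytest.approx(0.30, abs=1e-9)
        assert st.gabor_size_at(7.30) == pytest.approx(0.57, abs=1e-9)
        assert st.gabor_size_at(3.86) == pytest.approx(0.42, abs=0.005)

    def test_gabor_size_out_of_range(self):
        with pytest.raises(ValueError):
            st.gabor_size_at(0.5)
        with pytest.raises(ValueError):
            st.gabor_size_at(7.9)

    def test_spatial_frequency_endpoints(self):
        assert st.spatial_frequency_at(1.0) == pytest.approx(3.0, abs=1e-12)
        assert st.spatial_frequency_at(7.3) == pytest.approx(1.34, abs=0.01)

    def test_spatial_frequency_requires_positive_eccentricity(self):
        with pytest.raises(ValueError):
            st.spatial_frequency_at(0.0)

    def test_wedge_size_rule_matches_published_ladders(self):
        for eccs, radii in ((st.WEDGE_ECCENTRICITIES_SET1_DEG,
                             st.WEDGE_GABOR_RADII_SET1_DEG),
                            (st.WEDGE_ECCENTRICITIES_SET2_DEG,
                             st.WEDGE_GABOR_RADII_SET2_DEG)):
            for e, r in zip(eccs, radii):
                assert st.wedge_gabor_size_at(e) == pytest.approx(r, abs=0.01)


class TestLayouts:
    def test_ring_layout_canonical_values(self):
        layout = st.ring_layout()
        assert len(layout.eccentricities_deg) == 16
        assert len(layout.minor_radii_deg) == 16
        assert layout.eccentricities_deg[0] == pytest.approx(1.0)
        assert layout.minor_radii_deg[0] == pytest.approx(0.30)

    def test_ring_step_equals_half_width(self):
        """Consecutive centres are one minor radius (= half-width) apart.

        The published ladder is rounded to 0.01 deg, so individual steps
        can deviate by a few hundredths.
        """
        e = np.asarray(st.RING_ECCENTRICITIES_DEG)
        r = np.asarray(st.RING_MINOR_RADII_DEG)
        assert np.all(np.abs(np.diff(e) - r[1:]) <= 0.035)

    def test_generative_rule_regenerates_printed_ladder(self):
        gen = st.generated_ring_eccentricities()
        assert np.max(np.abs(gen - st.RING_ECCENTRICITIES_DEG)) < 0.02

    def test_ring_radii_follow_linear_rule(self):
        for e, r in zip(st.RING_ECCENTRICITIES_DEG, st.RING_MINOR_RADII_DEG):
            assert st.gabor_size_at(e) == pytest.approx(r, abs=0.01)

    def test_wedge_layout_interleaves_and_covers_half_turn(self):
        layout = st.wedge_layout()
        assert len(layout.eccentricity_set_1) == 7
        assert len(layout.eccentricity_set_2) == 6
        cfg = st.ScanConfig(aperture_kind="wedge_cw")
        assert layout.step_deg * cfg.frames_per_cycle == pytest.approx(180.0)

    def test_wedge_step_separation_rule(self):
        """Within each zigzag set, consecutive Gabors touch: the centre gap
        equals the sum of their radii."""
        for eccs, radii in ((st.WEDGE_ECCENTRICITIES_SET1_DEG,
                             st.WEDGE_GABOR_RADII_SET1_DEG),
                            (st.WEDGE_ECCENTRICITIES_SET2_DEG,
                             st.WEDGE_GABOR_RADII_SET2_DEG)):
            e = np.asarray(eccs)
            r = np.asarray(radii)
            gaps = np.diff(e)
            expected = r[:-1] + r[1:]
            assert np.all(np.abs(gaps - expected) <= 0.02)


class TestProbeLadder:
    def test_ladder_values(self):
        ladder = st.probe_ladder()
        v = np.asarray(ladder.ar_values)
        assert v.size == 9
        assert v[0] == pytest.approx(0.5)
        assert v[-1] == pytest.approx(2.0)
        assert v[4] == pytest.approx(1.0)
        assert v[6] == pytest.approx(1.41, abs=0.005)

    def test_ladder_log_symmetry(self):
        v = np.asarray(st.probe_ladder().ar_values)
        assert np.allclose(v * v[::-1], 1.0)


class TestDisplayGeometry:
    def test_projection_screen_visual_angles(self):
        # 34.5 x 26 cm screen viewed from 87 cm
        assert st.visual_angle_deg(26.0, 87.0) == pytest.approx(17.0, abs=0.05)
        assert st.visual_angle_deg(34.5, 87.0) == pytest.approx(22.4, abs=0.05)


class TestRasterizedMovies:
    def test_frame_count_and_binary_values(self, ring_movie):
        assert ring_movie.n_frames == 9 * 16
        assert set(np.unique(ring_movie.frames)) <= {0, 1}

    def test_active_pixels_inside_field(self, ring_movie, wedge_movie):
        for movie in (ring_movie, wedge_movie):
            yy, xx = np.meshgrid(movie.grid_y, movie.grid_x, indexing="ij")
            r = np.hypot(xx, yy)
            active_any = movie.frames.max(axis=0).astype(bool)
            assert r[active_any].max() <= 7.9

    def test_movie_identical_between_orientation_conditions(self):
        cfg_r = st.ScanConfig(grid_step_deg=0.25,
                              orientation_condition="radial")
        cfg_t = st.ScanConfig(grid_step_deg=0.25,
                              orientation_condition="tangential")
        m_r = st.rasterize_movie(cfg_r, st.ring_layout())
        m_t = st.rasterize_movie(cfg_t, st.ring_layout())
        assert np.array_equal(m_r.frames, m_t.frames)

    def test_cycles_repeat_exactly(self, ring_movie):
        frames = ring_movie.frames.reshape(9, 16, *ring_movie.frames.shape[1:])
        assert np.array_equal(frames[0], frames[4])

    def test_isolated_disc_area_matches_analytic(self):
        """One isolated Gabor disc rasterises to ~pi r^2 pixels."""
        from prfaniso.stimulus import _paint_disc
        step = 0.02
        axis = np.arange(-1.0, 1.0 + step / 2, step)
        mask = np.zeros((axis.size, axis.size), dtype=bool)
        _paint_disc(mask, axis, axis, 0.1, -0.2, 0.4)
        area = mask.sum() * step ** 2
        assert area == pytest.approx(np.pi * 0.4 ** 2, rel=0.05)

    def test_ring_cycle_covers_traversed_annulus(self, ring_movie):
        """Across one cycle nearly all of the swept annulus is stimulated."""
        union = ring_movie.frames[:16].max(axis=0).astype(bool)
        yy, xx = np.meshgrid(ring_movie.grid_y, ring_movie.grid_x,
                             indexing="ij")
        r = np.hypot(xx, yy)
        annulus = (r >= 1.0) & (r <= 7.3)
        assert union[annulus].mean() > 0.9

    def test_grid_too_coarse_rejected(self):
        cfg = st.ScanConfig(grid_step_deg=0.35)
        with pytest.raises(ValueError, match="resolve"):
            st.rasterize_movie(cfg, st.ring_layout())

    def test_timing_invariants(self):
        with pytest.raises(ValueError):
            st.ScanConfig(cycle_seconds=25.0)
        with pytest.raises(ValueError):
            st.ScanConfig(n_cycles=0)

    def test_hdf5_roundtrip(self, tmp_path, ring_movie):
        path = tmp_path / "movie.h5"
        ring_movie.save_hdf5(path)
        loaded = st.StimulusMovie.load_hdf5(path)
        assert np.array_equal(loaded.frames, ring_movie.frames)
        assert loaded.frame_duration == ring_movie.frame_duration
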