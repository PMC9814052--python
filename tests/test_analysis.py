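"""Assembly, radial integration, spot finding and feedback scheduling."""

import numpy as np
import pytest

from jfreduce import analysis as an
from jfreduce.conversion import SENTINEL, convert_frame_fixed_point
from jfreduce.geometry import DetectorGeometry


@pytest.fixture(scope="module")
def octo_geometry():
    """Eight small modules in a 4 x 2 grid with 4-pixel gaps."""
    rows, cols, gap = 16, 32, 4
    origins = tuple((i * (rows + gap), j * (cols + gap))
                    for i in range(4) for j in range(2))
    return DetectorGeometry(n_modules=8, module_rows=rows, module_cols=cols,
                            module_origins=origins,
                            beam_center=(34.0, 38.0), wavelength_A=1.0,
                            detector_distance_mm=50.0)


class TestAssembly:
    def test_single_module_identity(self, small_geometry, rng):
        pix = rng.integers(0, 100, (32, 64)).astype(np.int16)
        out = an.assemble_image({0: pix}, small_geometry)
        np.testing.assert_array_equal(out.pixels, pix)

    def test_summation_doubles_and_propagates_sentinel(self, small_geometry,
                                                       rng):
        pix = rng.integers(0, 100, (32, 64)).astype(np.int16)
        pix[5, 5] = SENTINEL
        out = an.assemble_image({0: pix}, small_geometry, sum_n=2,
                                frames_to_sum=[{0: pix}])
        finite = pix != SENTINEL
        np.testing.assert_array_equal(out.pixels[finite],
                                      2 * pix[finite].astype(np.int32))
        assert out.pixels[5, 5] == out.sentinel

    def test_gap_pixels_carry_sentinel_in_multi_module_layout(
            self, octo_geometry, rng):
        frames = {m: rng.integers(0, 50, (16, 32)).astype(np.int16)
                  for m in range(8)}
        out = an.assemble_image(frames, octo_geometry)
        gaps = octo_geometry.gap_mask()
        assert np.all(out.pixels[gaps] == out.sentinel)
        for m in range(8):
            np.testing.assert_array_equal(
                out.pixels[octo_geometry.module_slices(m)], frames[m])

    def test_missing_module_error_lists_ids(self, octo_geometry):
        with pytest.raises(ValueError, match=r"\[3, 5\]"):
            an.assemble_image(
                {m: np.zeros((16, 32), dtype=np.int16)
                 for m in range(8) if m not in (3, 5)}, octo_geometry)


class TestRadialProfile:
    def test_constant_image_gives_constant_bins(self, small_geometry):
        img = np.full(small_geometry.assembled_shape, 7, dtype=np.int16)
        prof = an.radial_profile(img, small_geometry, n_bins=20)
        populated = prof.counts > 0
        assert populated.any()
        np.testing.assert_allclose(prof.intensity[populated], 7.0)

    def test_ring_peaks_in_predicted_bin(self, module_geometry):
        geo = module_geometry
        rows, cols = np.indices(geo.assembled_shape)
        r_mm = geo.pixel_radius_mm(rows, cols)
        ring_mm = 10.0
        img = np.zeros(geo.assembled_shape, dtype=np.int16)
        img[np.abs(r_mm - ring_mm) < 0.15] = 1000
        prof = an.radial_profile(img, geo, n_bins=200)
        tth = np.arctan2(ring_mm, geo.detector_distance_mm)
        q_ring = 2.0 * np.sin(0.5 * tth) / geo.wavelength_A
        peak_bin = np.nanargmax(prof.intensity)
        assert prof.q_edges[peak_bin] <= q_ring <= prof.q_edges[peak_bin + 1]

    def test_mean_count_equals_count_weighted_profile_mean(
            self, small_geometry, rng):
        img = rng.integers(0, 50, small_geometry.assembled_shape).astype(
            np.int16)
        img[0, :5] = SENTINEL
        prof = an.radial_profile(img, small_geometry, n_bins=16)
        assert prof.mean_count() == pytest.approx(
            an.mean_count(img), rel=1e-12)

    def test_unreachable_resolution_range_raises(self, small_geometry):
        img = np.ones(small_geometry.assembled_shape, dtype=np.int16)
        with pytest.raises(ValueError, match="achievable"):
            an.radial_profile(img, small_geometry, d_range=(0.02, 0.01))

    def test_sentinel_pixels_do_not_contribute(self, small_geometry):
        img = np.full(small_geometry.assembled_shape, 5, dtype=np.int16)
        prof_full = an.radial_profile(img, small_geometry, n_bins=10)
        img2 = img.copy()
        img2[10:20, 30:40] = SENTINEL
        prof_masked = an.radial_profile(img2, small_geometry, n_bins=10)
        populated = prof_masked.counts > 0
        np.testing.assert_allclose(prof_masked.intensity[populated], 5.0)
        assert prof_masked.counts.sum() == prof_full.counts.sum() - 100


from oracles import brute_force_strong_pixels  # noqa: E402


class TestStrongPixels:
    def test_flat_image_has_no_strong_pixels(self):
        img = np.full((20, 20), 3, dtype=np.int16)
        assert an.find_strong_pixels(img).sum() == 0

    def test_single_high_pixel_above_flat_noise_is_strong(self, rng):
        img = np.clip(np.rint(rng.normal(10.0, 2.0, (40, 40))), 0,
                      None).astype(np.int16)
        img[20, 20] = 10 + 10 * 2  # +10 sigma
        mask = an.find_strong_pixels(img, w=4, snr_min=3.0, n_iter=1)
        assert mask[20, 20]

    @pytest.mark.parametrize("n_iter", [1, 2, 4])
    def test_agrees_with_brute_force_oracle(self, rng, n_iter):
        img = rng.poisson(2.0, (32, 32)).astype(np.int16)
        img[8, 9] = 60
        img[8, 10] = 45
        img[20, 25] = 80
        img[3, 3] = SENTINEL
        got = an.find_strong_pixels(img, w=3, snr_min=3.0, n_iter=n_iter)
        want = brute_force_strong_pixels(img, 3, 3.0, SENTINEL, n_iter)
        np.testing.assert_array_equal(got, want)

    def test_fully_masked_neighbourhood_is_not_strong(self):
        img = np.full((9, 9), SENTINEL, dtype=np.int16)
        assert an.find_strong_pixels(img).sum() == 0


class TestClustering:
    def test_empty_mask_gives_empty_list(self):
        img = np.zeros((10, 10), dtype=np.int16)
        spots = an.cluster_spots(np.zeros((10, 10), dtype=bool), img)
        assert len(spots) == 0

    def test_two_separated_blobs_give_two_spots(self):
        mask = np.zeros((20, 20), dtype=bool)
        img = np.zeros((20, 20), dtype=np.int16)
        mask[2:5, 2:5] = True
        img[2:5, 2:5] = 10
        mask[12:15, 12:15] = True
        img[12:15, 12:15] = 20
        spots = an.cluster_spots(mask, img, min_pix=3)
        assert len(spots) == 2
        intensities = sorted(s.intensity for s in spots)
        assert intensities == [90.0, 180.0]

    def test_min_pix_filters_small_components(self):
        mask = np.zeros((10, 10), dtype=bool)
        img = np.ones((10, 10), dtype=np.int16)
        mask[1, 1] = mask[1, 2] = True  # 2-pixel blob
        assert len(an.cluster_spots(mask, img, min_pix=3)) == 0
        assert len(an.cluster_spots(mask, img, min_pix=2)) == 1

    def test_diagonal_pixels_merge_under_8_connectivity_only(self):
        mask = np.zeros((10, 10), dtype=bool)
        img = np.ones((10, 10), dtype=np.int16)
        for i in range(4):
            mask[i, i] = True
        assert len(an.cluster_spots(mask, img, min_pix=3,
                                    connectivity=8)) == 1
        assert len(an.cluster_spots(mask, img, min_pix=3,
                                    connectivity=4)) == 0

    def test_intensity_weighted_centroid(self):
        mask = np.zeros((5, 5), dtype=bool)
        img = np.zeros((5, 5), dtype=np.int16)
        mask[2, 1:4] = True
        img[2, 1] = 1
        img[2, 2] = 2
        img[2, 3] = 1
        spots = an.cluster_spots(mask, img, min_pix=3)
        assert spots.spots[0].x == pytest.approx(2.5)  # centre of pixel col 2
        assert spots.spots[0].y == pytest.approx(2.5)

    def test_translation_equivariance(self, rng):
        img = rng.poisson(1.0, (64, 64)).astype(np.int16)
        img[20:23, 30:33] += 50
        base = an.find_spots(img, min_pix=3)
        shifted = np.roll(img, (7, -5), axis=(0, 1))
        moved = an.find_spots(shifted, min_pix=3)
        assert len(base) == len(moved) >= 1
        b = max(base, key=lambda s: s.intensity)
        m = max(moved, key=lambda s: s.intensity)
        assert m.y - b.y == pytest.approx(7, abs=1e-9)
        assert m.x - b.x == pytest.approx(-5, abs=1e-9)


class TestEndToEndSpotRecovery:
    def test_injected_spots_recovered(self, truth, module_geometry, constants,
                                      diffraction_frame):
        """At default parameters >= 95% of the 50 injected spots are found
        with centroid error <= 0.5 px."""
        frame, table = diffraction_frame
        image = convert_frame_fixed_point(frame, constants)
        spots = an.find_spots(image.pixels, module_geometry)
        hits = 0
        for s in table:
            err = min(np.hypot(f.x - s.x, f.y - s.y) for f in spots)
            hits += err <= 0.5
        assert hits >= 0.95 * len(table)


class TestReciprocalSpace:
    def test_beam_center_spot_flagged_undefined(self, module_geometry):
        bx, by = module_geometry.beam_center
        spots = an.SpotList([an.Spot(bx, by, 10.0, 3)])
        out = an.spots_to_reciprocal(spots, module_geometry)
        s = out.spots[0]
        assert s.d == np.inf
        assert np.allclose(s.s, 0.0)

    def test_closed_form_resolution_matches_vector_magnitude(
            self, module_geometry):
        geo = module_geometry
        bx, by = geo.beam_center
        spot = an.Spot(bx + 200.0, by, 10.0, 3)
        out = an.spots_to_reciprocal(an.SpotList([spot]), geo)
        r_mm = 200.0 * geo.pixel_size_um * 1e-3
        d_closed = geo.wavelength_A / (2.0 * np.sin(
            0.5 * np.arctan(r_mm / geo.detector_distance_mm)))
        assert 1.0 / np.linalg.norm(out.spots[0].s) == pytest.approx(
            d_closed, abs=1e-9)
        assert out.spots[0].d == pytest.approx(d_closed, abs=1e-9)

    def test_rotation_about_beam_axis_preserves_magnitude(
            self, module_geometry):
        geo = module_geometry
        bx, by = geo.beam_center
        mags = []
        for phi in (0.0, 0.7, 2.1):
            x = bx + 150.0 * np.cos(phi)
            y = by + 150.0 * np.sin(phi)
            out = an.spots_to_reciprocal(
                an.SpotList([an.Spot(x, y, 1.0, 3)]), geo)
            mags.append(np.linalg.norm(out.spots[0].s))
        np.testing.assert_allclose(mags, mags[0], rtol=1e-12)


class TestFeedbackScheduling:
    def test_2khz_at_100_per_second_analyses_every_20th_frame(self):
        plan = an.schedule_feedback(2000.0, preview_rate=1.0,
                                    analysis_rate=100.0)
        assert plan.analysis_stride == 20
        assert plan.preview_stride == 2000

    def test_rate_above_frame_rate_takes_every_frame_with_warning(self):
        with pytest.warns(RuntimeWarning):
            plan = an.schedule_feedback(50.0, preview_rate=100.0,
                                        analysis_rate=100.0)
        assert plan.analysis_stride == 1

    def test_selection_is_deterministic_and_gap_free(self):
        plan = an.schedule_feedback(2000.0)
        frames = range(1, 10 ** 6 + 1)
        chosen = plan.analysis_frames(frames)
        assert chosen == list(range(1, 10 ** 6 + 1, 20))
        assert len(chosen) == 10 ** 6 // 20
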