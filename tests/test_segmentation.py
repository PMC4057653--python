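"""Stage-by-stage and end-to-end pupil segmentation."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from oracles import brute_force_median
from pupilkit.phantom import PhantomSpec, ReflectionSpot, render_phantom
from pupilkit.segmentation import (
    NoPupilError,
    binarize,
    close_and_fill,
    compute_threshold,
    extract_boundary,
    median_smooth,
    segment_pupil,
)


def spot_spec(reflection=True):
    spot = ReflectionSpot(center=(512.0, 512.0), radius_px=8) if reflection else None
    return PhantomSpec(shape="circle", major_axis_px=119, minor_axis_px=119, reflection=spot)


class TestMedianSmooth:
    def test_constant_image_unchanged(self):
        img = np.full((32, 32), 77, np.uint8)
        assert np.array_equal(median_smooth(img), img)

    def test_salt_pixel_removed(self):
        img = np.zeros((32, 32), np.uint8)
        img[10, 12] = 255
        assert median_smooth(img).max() == 0

    def test_matches_brute_force_oracle(self, rng):
        img = rng.integers(0, 256, (32, 32), dtype=np.uint8)
        assert np.array_equal(median_smooth(img, 5), brute_force_median(img, 5))

    @pytest.mark.parametrize("window", [3, 7])
    def test_matches_scipy_reference(self, rng, window):
        # cross-checks the accelerated path against the library filter
        img = rng.integers(0, 256, (61, 47), dtype=np.uint8)
        ref = ndi.median_filter(img, size=window, mode="nearest")
        assert np.array_equal(median_smooth(img, window), ref)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            median_smooth(np.zeros((16, 16), np.uint8), 4)


class TestThresholdAndBinarize:
    def test_constant_image(self):
        assert compute_threshold(np.full((16, 16), 10, np.uint8)) == 10.0

    def test_two_level_mean(self):
        img = np.zeros((16, 16), np.uint8)
        img[:8] = 200
        assert compute_threshold(img) == 100.0

    def test_histogram_mean_matches_direct_mean_on_phantom(self, circle119_frame):
        t = compute_threshold(circle119_frame)
        assert abs(t - circle119_frame.pixels.mean()) <= 0.5

    def test_all_white_gives_empty_mask(self):
        img = np.full((16, 16), 255, np.uint8)
        assert not binarize(img, compute_threshold(img)).any()

    def test_threshold_zero_empty_by_strict_inequality(self):
        img = np.zeros((16, 16), np.uint8)
        assert not binarize(img, 0).any()

    def test_reflection_becomes_hole(self):
        plain = render_phantom(spot_spec(False)).pixels
        spotted = render_phantom(spot_spec(True)).pixels
        mask = binarize(spotted, 128)
        expected = (plain == 0) & (spotted == 0)
        assert np.array_equal(mask, expected)
        assert mask.sum() < (plain == 0).sum()


class TestCloseAndFill:
    def test_reflection_hole_filled_back_to_solid_disk(self):
        plain_mask = render_phantom(spot_spec(False)).pixels == 0
        spotted_mask = render_phantom(spot_spec(True)).pixels == 0
        assert np.array_equal(close_and_fill(spotted_mask), plain_mask)

    def test_solid_disk_unchanged(self):
        mask = render_phantom(spot_spec(False)).pixels == 0
        assert np.array_equal(close_and_fill(mask), mask)

    def test_distant_speck_removed_by_largest_component_rule(self):
        mask = render_phantom(spot_spec(False)).pixels == 0
        mask[10, 10:13] = True
        out = close_and_fill(mask)
        assert not out[10, 10:13].any()
        assert out.sum() >= (render_phantom(spot_spec(False)).pixels == 0).sum()

    def test_empty_mask_flagged(self):
        with pytest.raises(NoPupilError):
            close_and_fill(np.zeros((64, 64), bool))


class TestExtractBoundary:
    def test_3x3_square_has_8_boundary_points(self):
        mask = np.zeros((16, 16), bool)
        mask[5:8, 6:9] = True
        pts = extract_boundary(mask)
        assert len(pts) == 8
        assert (7.5, 6.5) not in {tuple(p) for p in pts}  # center pixel is interior

    def test_single_pixel_one_boundary_point(self):
        mask = np.zeros((16, 16), bool)
        mask[3, 4] = True
        pts = extract_boundary(mask)
        assert pts.shape == (1, 2)
        assert tuple(pts[0]) == (4.5, 3.5)

    def test_disk_span_is_diameter_minus_one(self):
        """The fencepost: a pixel-aligned diameter-119 raster disk spans 118 units.

        With the circle center on a pixel center, the extreme inner-boundary
        points sit exactly (119 - 1) / 2 pixels out on each side.
        """
        frame = render_phantom(PhantomSpec(
            shape="circle", major_axis_px=119, minor_axis_px=119, center=(512.5, 512.5)))
        pts = extract_boundary(frame.pixels == 0)
        assert pts[:, 0].max() - pts[:, 0].min() == 118.0
        assert pts[:, 1].max() - pts[:, 1].min() == 118.0

    def test_empty_mask_errors(self):
        with pytest.raises(NoPupilError, match="no pupil"):
            extract_boundary(np.zeros((8, 8), bool))


class TestSegmentPupil:
    def test_table_row_ellipse_160_119(self, ellipse_160x119_frame):
        r = segment_pupil(ellipse_160x119_frame)
        assert r.valid
        assert round(r.major_axis_px) == 159
        assert round(r.minor_axis_px) == 118
        assert abs(r.orientation_rad) < np.pi / 4  # major axis horizontal

    def test_all_white_frame_invalid_not_raising(self):
        r = segment_pupil(np.full((128, 128), 255, np.uint8))
        assert not r.valid
        assert "no pupil" in r.fail_reason

    def test_reflection_variant_shifts_axes_below_half_pixel(self):
        plain = segment_pupil(render_phantom(spot_spec(False)))
        spotted = segment_pupil(render_phantom(spot_spec(True)))
        assert abs(plain.major_axis_px - spotted.major_axis_px) < 0.5
        assert abs(plain.minor_axis_px - spotted.minor_axis_px) < 0.5

    def test_translation_equivariance(self):
        a = segment_pupil(render_phantom(PhantomSpec(
            shape="circle", major_axis_px=119, minor_axis_px=119, center=(400.0, 450.0))))
        b = segment_pupil(render_phantom(PhantomSpec(
            shape="circle", major_axis_px=119, minor_axis_px=119, center=(423.0, 437.0))))
        assert b.center[0] - a.center[0] == pytest.approx(23.0, abs=1e-9)
        assert b.center[1] - a.center[1] == pytest.approx(-13.0, abs=1e-9)

    def test_rotation_by_90_swaps_screen_roles(self, ellipse_160x119_frame):
        r0 = segment_pupil(ellipse_160x119_frame)
        r90 = segment_pupil(np.rot90(ellipse_160x119_frame.pixels).copy())
        assert r90.major_axis_px == pytest.approx(r0.major_axis_px, abs=1e-6)
        assert r90.minor_axis_px == pytest.approx(r0.minor_axis_px, abs=1e-6)
        assert abs(r90.orientation_rad) > np.pi / 4  # now vertical

    def test_fitted_major_strictly_increasing_across_circle_set(self):
        fitted = []
        for d in (119, 160, 201, 242, 283, 321):
            r = segment_pupil(render_phantom(
                PhantomSpec(shape="circle", major_axis_px=d, minor_axis_px=d)))
            fitted.append(r.major_axis_px)
        assert all(b > a for a, b in zip(fitted, fitted[1:]))
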