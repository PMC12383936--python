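"""FOV modelling: masking, cropping, mask estimation, fit/render and scan
conversion round-trips."""

import math

import numpy as np
import pytest
from scipy import ndimage

from lusaug import (
    EmptyMaskError,
    FOVGeometry,
    ShapeMismatchError,
    UltrasoundImage,
    apply_mask,
    crop_to_fov,
    estimate_fov_mask,
    fit_fov_geometry,
    inverse_scan_convert,
    render_fov_mask,
    scan_convert,
)
from lusaug.transforms.ultrasound import fan_geometry_for_frame


class TestApplyMask:
    def test_identity_mask_leaves_pixels_unchanged(self):
        img = UltrasoundImage(pixels=np.random.default_rng(0).random((16, 16)))
        out = apply_mask(img)
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_single_pixel_mask_keeps_only_that_pixel(self):
        px = np.zeros((10, 10))
        px[5, 5] = 200 / 255
        px[2, 2] = 0.5  # will be wiped
        mask = np.zeros((10, 10), dtype=np.uint8)
        mask[5, 5] = 1
        out = apply_mask(UltrasoundImage(pixels=px, mask=mask))
        assert np.count_nonzero(out.pixels) == 1
        assert out.pixels[5, 5] == pytest.approx(200 / 255)

    def test_convex_phantom_background_is_exactly_zero(self, fan_phantom):
        noisy = fan_phantom.copy()
        noisy.pixels = noisy.pixels + 0.1  # contaminate the background
        out = apply_mask(noisy)
        assert out.pixels[out.mask == 0].sum() == 0.0

    def test_shape_mismatch_is_structural_error(self):
        img = UltrasoundImage(pixels=np.ones((8, 8)))
        img.mask = np.ones((4, 4), dtype=np.uint8)
        with pytest.raises(ShapeMismatchError):
            apply_mask(img)

    def test_idempotent(self, fan_phantom):
        once = apply_mask(fan_phantom)
        twice = apply_mask(once)
        np.testing.assert_array_equal(once.pixels, twice.pixels)


class TestCropToFov:
    def test_bounding_box_dimensions(self):
        mask = np.zeros((10, 10), dtype=np.uint8)
        mask[2:8, 3:9] = 1  # rows 2-7, cols 3-8 inclusive
        img = UltrasoundImage(pixels=np.random.default_rng(1).random((10, 10)), mask=mask)
        out = crop_to_fov(apply_mask(img))
        assert out.shape == (6, 6)

    def test_full_mask_is_identity(self):
        img = UltrasoundImage(pixels=np.random.default_rng(2).random((12, 12)))
        out = crop_to_fov(img)
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_idempotent(self, fan_phantom):
        once = crop_to_fov(fan_phantom)
        twice = crop_to_fov(once)
        assert once.shape == twice.shape
        np.testing.assert_array_equal(once.pixels, twice.pixels)

    def test_empty_mask_raises(self):
        img = UltrasoundImage(pixels=np.ones((8, 8)))
        img.mask = np.zeros((8, 8), dtype=np.uint8)
        with pytest.raises(EmptyMaskError):
            crop_to_fov(img)

    def test_geometry_shifts_with_crop(self, fan_phantom):
        out = crop_to_fov(fan_phantom)
        refit = fit_fov_geometry(out.mask)
        assert refit.theta0 == pytest.approx(out.geometry.theta0, abs=0.02)
        assert refit.apex[0] == pytest.approx(out.geometry.apex[0], abs=3.0)


class TestEstimateFovMask:
    def test_recovers_phantom_mask(self):
        from lusaug import generate_phantom
        from lusaug.phantom import PhantomSpec

        g = fan_geometry_for_frame((128, 128), theta0=0.45, inner_ratio=0.3)
        img = generate_phantom(
            PhantomSpec(geometry=g, pleural_depth=0.4, label="A"),
            np.random.default_rng(7),
            shape=(128, 128),
        )
        est = estimate_fov_mask(img.pixels)
        agreement = np.mean(est == img.mask)
        assert agreement >= 0.99

    def test_all_zero_image_raises(self):
        with pytest.raises(EmptyMaskError):
            estimate_fov_mask(np.zeros((32, 32)))

    def test_largest_component_wins(self):
        px = np.zeros((40, 60))
        px[5:30, 5:25] = 0.8  # 500-px order blob
        px[33:38, 40:50] = 0.8  # small blob
        est = estimate_fov_mask(px)
        assert est[10, 10] == 1
        assert est[35, 45] == 0


class TestFitRenderRoundTrip:
    def test_rectangular_mask_is_linear(self):
        mask = np.zeros((32, 32), dtype=np.uint8)
        mask[2:30, 4:28] = 1
        g = fit_fov_geometry(mask)
        assert g.kind == "linear"
        assert g.theta0 == 0.0

    def test_curvilinear_parameter_recovery(self):
        g = FOVGeometry(
            kind="curvilinear", apex=(-36.6, 100.0), theta0=0.5, r_min=40, r_max=200
        )
        mask = render_fov_mask(g, (170, 200))
        f = fit_fov_geometry(mask)
        assert f.kind == "curvilinear"
        assert f.theta0 == pytest.approx(0.5, abs=0.02)
        assert f.r_max == pytest.approx(200, abs=2)

    def test_zero_inner_radius_is_phased(self):
        g = FOVGeometry(
            kind="phased", apex=(0.0, 60.0), theta0=0.45, r_min=0.0, r_max=110.0
        )
        mask = render_fov_mask(g, (115, 120))
        assert fit_fov_geometry(mask).kind == "phased"

    def test_fan_mask_widens_with_depth(self, fan_geometry):
        mask = render_fov_mask(fan_geometry, (64, 64))
        widths = mask.sum(axis=1)
        nz = np.flatnonzero(widths)
        # the fan widens from the inner arc down to the corner row
        assert widths[nz].max() > widths[nz[0]]
        widest = nz[np.argmax(widths[nz])]
        assert widest > nz[0]

    def test_linear_full_frame_mask_is_all_ones(self):
        g = FOVGeometry(
            kind="linear", apex=(0.0, 15.5), theta0=0.0, r_min=0.0, r_max=31.0,
            width=31.0,
        )
        assert render_fov_mask(g, (32, 32)).all()

    def test_bottom_corner_separation_increases_with_theta0(self):
        seps = []
        for theta0 in (0.3, 0.5, 0.7):
            g = FOVGeometry(
                kind="curvilinear", apex=(-30.0, 64.0), theta0=theta0,
                r_min=30, r_max=100,
            )
            (r1, c1), (r2, c2) = g.bottom_corners
            seps.append(c2 - c1)
        assert seps[0] < seps[1] < seps[2]

    def test_random_geometry_recovery_seeded(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            theta0 = rng.uniform(0.3, 0.8)
            r_max = rng.uniform(90, 200)
            r_min = rng.uniform(0.15, 0.4) * r_max
            apex_row = -r_min * math.cos(theta0) + rng.uniform(-4, 0)
            shape = (
                int(r_max + apex_row) + 3,
                int(2 * r_max * math.sin(theta0)) + 6,
            )
            g = FOVGeometry(
                kind="curvilinear", apex=(apex_row, shape[1] / 2),
                theta0=theta0, r_min=r_min, r_max=r_max,
            )
            f = fit_fov_geometry(render_fov_mask(g, shape))
            assert f.theta0 == pytest.approx(theta0, abs=0.02)
            assert f.r_max == pytest.approx(r_max, abs=2.0)


class TestScanConversion:
    def test_linear_scan_conversion_is_identity(self):
        beam = np.random.default_rng(3).random((32, 24))
        g = FOVGeometry(
            kind="linear", apex=(0.0, 11.5), theta0=0.0, r_min=0.0, r_max=31.0,
            width=23.0,
        )
        out = scan_convert(beam, g, shape=(32, 24))
        np.testing.assert_allclose(out.pixels, beam, atol=1e-12)

    def test_constant_beam_gives_constant_fov(self, fan_geometry):
        beam = np.full((60, 80), 0.7)
        out = scan_convert(beam, fan_geometry, shape=(64, 64))
        inside = out.mask.astype(bool)
        np.testing.assert_allclose(out.pixels[inside], 0.7, atol=1 / 255)

    def test_round_trip_mae_on_smooth_image(self, fan_geometry):
        rng = np.random.default_rng(4)
        beam = ndimage.gaussian_filter(rng.random((120, 140)), 6)
        beam = (beam - beam.min()) / (beam.max() - beam.min())
        cart = scan_convert(beam, fan_geometry, shape=(64, 64))
        back = inverse_scan_convert(cart)
        # compare on a common lattice by converting forward again
        cart2 = scan_convert(back, fan_geometry, shape=(64, 64))
        inside = cart.mask.astype(bool)
        mae = np.abs(cart.pixels[inside] - cart2.pixels[inside]).mean()
        assert mae < 0.02

    def test_inverse_on_linear_is_noop_rectangle(self):
        g = FOVGeometry(
            kind="linear", apex=(0.0, 15.5), theta0=0.0, r_min=0.0, r_max=31.0,
            width=31.0,
        )
        px = np.random.default_rng(5).random((32, 32))
        img = UltrasoundImage(pixels=px, geometry=g)
        np.testing.assert_array_equal(inverse_scan_convert(img), px)

    def test_geometry_outside_frame_raises(self):
        g = FOVGeometry(
            kind="linear", apex=(100.0, 200.0), theta0=0.0, r_min=100.0,
            r_max=140.0, width=20.0,
        )
        with pytest.raises(EmptyMaskError):
            render_fov_mask(g, (16, 16))
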