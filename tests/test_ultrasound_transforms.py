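"""Ultrasound-specific operators B00-B11: geometry bookkeeping, closed-form
intensity examples, noise calibration, and identity cases."""

import numpy as np
import pytest
from scipy import ndimage

from lusaug import MissingGeometryError, UltrasoundImage, fit_fov_geometry
from lusaug.image import to_uint8
from lusaug.transforms import get_transform
from lusaug.transforms.ultrasound import NoiseParams


class TestProbeTypeChange:
    def test_linear_becomes_fan(self, linear_phantom):
        out, params = get_transform("B00")(linear_phantom, np.random.default_rng(0))
        assert out.geometry.kind == "curvilinear"
        widths = out.mask.sum(axis=1)
        nz = np.flatnonzero(widths)
        assert widths[nz].max() > widths[nz[0]]

    def test_fan_becomes_linear_full_rectangle(self, fan_phantom):
        out, _ = get_transform("B00")(fan_phantom, np.random.default_rng(1))
        assert out.geometry.kind == "linear"
        assert out.mask.all()

    def test_double_application_restores_kind(self, linear_phantom):
        t = get_transform("B00")
        rng = np.random.default_rng(2)
        once, _ = t(linear_phantom, rng)
        twice, _ = t(once, rng)
        assert twice.geometry.kind == "linear"

    def test_missing_geometry_raises(self):
        img = UltrasoundImage(pixels=np.random.default_rng(3).random((32, 32)))
        with pytest.raises(MissingGeometryError):
            get_transform("B00")(img, np.random.default_rng(3))

    def test_output_geometry_agrees_with_mask(self, linear_phantom):
        out, _ = get_transform("B00")(linear_phantom, np.random.default_rng(4))
        refit = fit_fov_geometry(out.mask)
        assert refit.theta0 == pytest.approx(out.geometry.theta0, abs=0.05)


class TestConvexityChange:
    def test_unit_multiplier_near_identity(self, fan_phantom):
        smooth = fan_phantom.copy()
        smooth.pixels = ndimage.gaussian_filter(smooth.pixels, 1.5) * smooth.mask
        out = get_transform("B01").apply(smooth, multiplier=1.0)
        inside = (out.mask & smooth.mask).astype(bool)
        mae = np.abs(out.pixels[inside] - smooth.pixels[inside]).mean()
        assert mae < 0.01

    def test_multiplier_widens_bottom_corners(self, fan_phantom):
        wide = get_transform("B01").apply(fan_phantom, multiplier=1.2)
        (r1, c1), (r2, c2) = wide.geometry.bottom_corners
        (s1, d1), (s2, d2) = fan_phantom.geometry.bottom_corners
        assert (c2 - c1) > (d2 - d1)

    def test_mean_intensity_roughly_preserved(self, fan_geometry):
        beam = ndimage.gaussian_filter(np.random.default_rng(5).random((80, 100)), 5)
        beam = 0.2 + 0.6 * (beam - beam.min()) / (beam.max() - beam.min())
        from lusaug import scan_convert

        img = scan_convert(beam, fan_geometry, shape=(64, 64))
        out = get_transform("B01").apply(img, multiplier=1.15)
        m_in = img.pixels[img.mask.astype(bool)].mean()
        m_out = out.pixels[out.mask.astype(bool)].mean()
        assert m_out == pytest.approx(m_in, rel=0.05)

    def test_linear_input_is_noop(self, linear_phantom):
        out = get_transform("B01").apply(linear_phantom, multiplier=1.2)
        np.testing.assert_array_equal(out.pixels, linear_phantom.pixels)
        assert "B01" in out.meta


class TestWaveletDenoise:
    def test_constant_image_unchanged(self, flat_image):
        out = get_transform("B02").apply(flat_image)
        np.testing.assert_allclose(out.pixels, 0.5, atol=1e-10)

    def test_denoising_reduces_mse(self):
        from lusaug import generate_phantom
        from lusaug.phantom import PhantomSpec
        from lusaug.transforms.ultrasound import fan_geometry_for_frame

        g = fan_geometry_for_frame((128, 128), theta0=0.45, inner_ratio=0.3)
        clean = generate_phantom(
            PhantomSpec(
                geometry=g, pleural_depth=0.4, n_alines=2, label="A",
                speckle_texture_sigma=0.05,
            ),
            np.random.default_rng(6),
            shape=(128, 128),
        )
        rng = np.random.default_rng(60)
        noisy = clean.copy()
        noisy.pixels = np.clip(
            noisy.pixels + rng.normal(0, 0.1, noisy.shape) * noisy.mask, 0, 1
        )
        den = get_transform("B02").apply(noisy)
        inside = clean.mask.astype(bool)
        mse_before = np.mean((noisy.pixels[inside] - clean.pixels[inside]) ** 2)
        mse_after = np.mean((den.pixels[inside] - clean.pixels[inside]) ** 2)
        assert mse_after < mse_before

    def test_alpha_zero_keeps_everything(self):
        img = UltrasoundImage(pixels=np.random.default_rng(7).random((64, 64)))
        out = get_transform("B02", levels=1, alpha=0.0).apply(img)
        np.testing.assert_allclose(out.pixels, img.pixels, atol=1e-6)

    def test_too_small_image_raises(self):
        from lusaug import ParameterError

        img = UltrasoundImage(pixels=np.random.default_rng(8).random((6, 6)))
        with pytest.raises(ParameterError):
            get_transform("B02", levels=3).apply(img)


class TestClahe:
    def test_constant_fov_maps_to_constant(self, fan_phantom):
        img = fan_phantom.copy()
        img.pixels = 0.4 * img.mask
        out = get_transform("B03").apply(img, clip_limit=2.0)
        inside = img.mask.astype(bool)
        vals = out.pixels[inside]
        assert vals.std() == pytest.approx(0.0, abs=1e-12)
        assert out.pixels[~inside].sum() == 0.0

    def test_contrast_expansion_on_low_contrast_phantom(self, fan_phantom):
        img = fan_phantom.copy()
        # squeeze dynamic range into [0.4, 0.6]
        img.pixels = (0.4 + 0.2 * img.pixels) * img.mask
        out = get_transform("B03").apply(img, clip_limit=4.0)
        inside = img.mask.astype(bool)
        assert out.pixels[inside].std() > img.pixels[inside].std()

    def test_seed_determinism(self, fan_phantom):
        t = get_transform("B03")
        a, pa = t(fan_phantom, np.random.default_rng(9))
        b, pb = t(fan_phantom, np.random.default_rng(9))
        assert pa == pb
        np.testing.assert_array_equal(a.pixels, b.pixels)


class TestGammaCorrect:
    def test_unit_gamma_identity(self, fan_phantom):
        out = get_transform("B04").apply(fan_phantom, gamma=1.0)
        np.testing.assert_array_equal(out.pixels, fan_phantom.pixels)

    def test_square_law_quantization(self):
        px = np.full((4, 4), 64 / 255)
        out = get_transform("B04").apply(UltrasoundImage(pixels=px), gamma=2.0)
        assert to_uint8(out.pixels)[0, 0] == 16

    def test_monotone_for_any_gamma(self, fan_phantom):
        for gamma in (0.5, 0.9, 1.4, 2.5):
            out = get_transform("B04").apply(fan_phantom, gamma=gamma)
            a, b = fan_phantom.pixels.ravel(), out.pixels.ravel()
            order = np.argsort(a, kind="stable")
            assert (np.diff(b[order]) >= -1e-12).all()


class TestBrightnessContrast:
    def test_identity_parameters(self, fan_phantom):
        out = get_transform("B05").apply(fan_phantom, a=1.0, b=0.0)
        np.testing.assert_array_equal(out.pixels, fan_phantom.pixels)

    def test_linear_formula(self):
        px = np.full((4, 4), 100 / 255)
        out = get_transform("B05").apply(UltrasoundImage(pixels=px), a=2.0, b=10 / 255)
        np.testing.assert_allclose(out.pixels, 210 / 255)

    def test_clipping_at_one(self):
        px = np.full((4, 4), 200 / 255)
        out = get_transform("B05").apply(UltrasoundImage(pixels=px), a=2.0, b=0.0)
        np.testing.assert_array_equal(out.pixels, np.ones((4, 4)))


class TestDepthChange:
    def test_unit_zoom_identity(self, fan_phantom):
        out = get_transform("B06").apply(fan_phantom, zoom=1.0)
        np.testing.assert_array_equal(out.pixels, fan_phantom.pixels)

    @pytest.mark.parametrize("zoom", [0.85, 1.0, 1.25])
    def test_mask_and_geometry_preserved(self, fan_phantom, zoom):
        out = get_transform("B06").apply(fan_phantom, zoom=zoom)
        np.testing.assert_array_equal(out.mask, fan_phantom.mask)
        assert out.geometry == fan_phantom.geometry

    def test_bright_band_moves_to_depth_over_zoom(self):
        from lusaug import FOVGeometry

        g = FOVGeometry(
            kind="linear", apex=(0.0, 31.5), theta0=0.0, r_min=0.0, r_max=63.0,
            width=63.0,
        )
        px = np.zeros((64, 64))
        d = 40
        px[d, :] = 1.0
        img = UltrasoundImage(pixels=px, geometry=g)
        out = get_transform("B06").apply(img, zoom=1.25)
        profile = out.pixels.sum(axis=1)
        assert abs(int(np.argmax(profile)) - d / 1.25) <= 1

    def test_missing_geometry_raises(self):
        img = UltrasoundImage(pixels=np.zeros((16, 16)))
        with pytest.raises(MissingGeometryError):
            get_transform("B06")(img, np.random.default_rng(0))


class TestNoiseOperators:
    def test_zero_magnitudes_are_identity(self, fan_phantom):
        quiet = NoiseParams(speckle_sigma=0.0, gauss_sigma=0.0, sp_rate=0.0)
        for tid in ("B07", "B08", "B09"):
            out = get_transform(tid, params=quiet).apply(fan_phantom, seed=1)
            np.testing.assert_array_equal(out.pixels, fan_phantom.pixels)

    def test_zero_image_stays_zero(self):
        img = UltrasoundImage(pixels=np.zeros((32, 32)))
        for tid in ("B07", "B08"):
            out = get_transform(tid).apply(img, seed=2)
            np.testing.assert_array_equal(out.pixels, 0.0)

    def test_speckle_std_matches_attenuated_sigma(self):
        t = get_transform("B07")
        img = UltrasoundImage(pixels=np.full((256, 256), 0.5))
        out = t.apply(img, seed=3)
        rel = (out.pixels - img.pixels) / img.pixels
        assert rel.std() == pytest.approx(t.expected_field_std(), rel=0.15)

    def test_gaussian_noise_std_calibrated(self):
        img = UltrasoundImage(pixels=np.full((256, 256), 0.5))
        out = get_transform("B08").apply(img, seed=4)
        rel = out.pixels / img.pixels - 1.0
        assert rel.std() == pytest.approx(0.1, abs=0.01)

    def test_salt_pepper_binomial_count_and_mask_respect(self):
        px = np.full((100, 100), 0.5)
        img = UltrasoundImage(pixels=px)
        t = get_transform("B09", params=NoiseParams(sp_rate=0.1))
        out = t.apply(img, seed=5)
        changed = int((out.pixels != px).sum())
        assert 902 <= changed <= 1100  # central 99.9% binomial interval
        vals = np.unique(out.pixels[out.pixels != px])
        assert set(vals) <= {0.0, 1.0}

    def test_salt_pepper_leaves_masked_region(self, fan_phantom):
        t = get_transform("B09", params=NoiseParams(sp_rate=0.1))
        out = t.apply(fan_phantom, seed=6)
        outside = ~fan_phantom.mask.astype(bool)
        assert out.pixels[outside].sum() == 0.0

    def test_noise_mean_preserving_in_expectation(self):
        img = UltrasoundImage(pixels=np.full((128, 128), 0.5))
        for tid in ("B07", "B08"):
            means = [
                get_transform(tid).apply(img, seed=s).pixels.mean()
                for s in range(20)
            ]
            assert np.mean(means) == pytest.approx(0.5, rel=0.02)


class TestRotateShift:
    def test_zero_motion_identity(self, fan_phantom):
        out = get_transform("B11").apply(
            fan_phantom, angle_deg=0.0, shift_rows=0.0, shift_cols=0.0
        )
        np.testing.assert_array_equal(out.pixels, fan_phantom.pixels)

    def test_rotation_round_trip_interior_mae(self, fan_phantom):
        # band-limited content: bilinear resampling cannot be expected to
        # preserve pixel-scale speckle through two rotations
        smooth = fan_phantom.copy()
        smooth.pixels = ndimage.gaussian_filter(smooth.pixels, 1.5) * smooth.mask
        t = get_transform("B11")
        fwd = t.apply(smooth, angle_deg=10.0, shift_rows=0.0, shift_cols=0.0)
        back = t.apply(fwd, angle_deg=-10.0, shift_rows=0.0, shift_cols=0.0)
        interior = ndimage.binary_erosion(
            smooth.mask.astype(bool), iterations=6
        ) & back.mask.astype(bool)
        mae = np.abs(back.pixels[interior] - smooth.pixels[interior]).mean()
        assert mae < 0.02

    def test_pure_shift_moves_pixel(self):
        px = np.zeros((32, 32))
        px[16, 5] = 1.0
        img = UltrasoundImage(pixels=px)
        out = get_transform("B11").apply(
            img, angle_deg=0.0, shift_rows=0.0, shift_cols=10.0
        )
        assert out.pixels[16, 15] == pytest.approx(1.0)
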