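"""Semantics-preserving, FOV-aware augmentation operators for B-mode
ultrasound (B00-B11): probe-type and convexity changes, wavelet-shrinkage
denoising, CLAHE, gamma/brightness/contrast adjustment, depth-change
simulation, speckle / multiplicative-Gaussian / salt-and-pepper noise,
horizontal reflection, and rotation with translation.

Geometry bookkeeping: probe-type (B00) and convexity (B01) changes update
the stored :class:`~lusaug.geometry.FOVGeometry` consistently with the new
mask; depth change (B06) preserves mask and geometry exactly; rotation/shift
(B11) transforms the mask and drops the geometry (no longer parametric).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pywt
from scipy import ndimage

from ..errors import MissingGeometryError, ParameterError
from ..geometry import (
    CURVILINEAR,
    LINEAR,
    FOVGeometry,
    inverse_scan_convert,
    render_fov_mask,
    scan_convert,
)
from ..image import UltrasoundImage, to_uint8
from . import Transform, clip01, register, rezero, sub_seed
from .standard import HorizontalReflect, resize_image


@dataclass(frozen=True)
class NoiseParams:
    """Magnitudes of the three ultrasound noise models."""

    speckle_sigma: float = 0.25
    gauss_sigma: float = 0.1
    sp_rate: float = 0.01

    def __post_init__(self) -> None:
        if min(self.speckle_sigma, self.gauss_sigma, self.sp_rate) < 0:
            raise ParameterError("noise magnitudes must be nonnegative")
        if self.sp_rate > 0.1:
            raise ParameterError("sp_rate must be <= 0.1")


def _require_geometry(image: UltrasoundImage) -> FOVGeometry:
    if image.geometry is None:
        raise MissingGeometryError("transform requires FOV geometry")
    return image.geometry


def fan_geometry_for_frame(
    shape: tuple[int, int], theta0: float, inner_ratio: float = 0.3
) -> FOVGeometry:
    """A curvilinear geometry filling a frame as far as the frame allows.

    The fan's centreline top touches row 0, ``r_min = inner_ratio * r_max``,
    and ``r_max`` is the largest radius for which both the bottom arc and the
    bottom corners stay inside the frame.
    """
    rows, cols = shape
    r_max = min((rows - 1) / (1.0 - inner_ratio), (cols - 1) / (2.0 * math.sin(theta0)))
    r_min = inner_ratio * r_max
    return FOVGeometry(
        kind=CURVILINEAR,
        apex=(-r_min, (cols - 1) / 2.0),
        theta0=float(theta0),
        r_min=r_min,
        r_max=r_max,
    )


@register
class ProbeTypeChange(Transform):
    """B00 — resample to the other probe family's FOV shape.

    Linear frames are scan-converted onto a random curvilinear fan;
    curvilinear and phased frames are inverse-scan-converted to a linear
    rectangle filling the frame.
    """

    id = "B00"
    name = "probe_type_change"
    requires_geometry = True

    def __init__(self, theta0_range: tuple[float, float] = (0.3, 0.7), inner_ratio: float = 0.3):
        self.theta0_range = (float(theta0_range[0]), float(theta0_range[1]))
        self.inner_ratio = float(inner_ratio)

    def sample_params(self, image, rng):
        geometry = _require_geometry(image)
        if geometry.kind == LINEAR:
            return {"theta0": float(rng.uniform(*self.theta0_range))}
        return {"theta0": None}

    def apply(self, image, *, theta0=None):
        geometry = _require_geometry(image)
        shape = image.shape
        if geometry.kind == LINEAR:
            if theta0 is None:
                raise ParameterError("linear-to-fan conversion needs theta0")
            beam = inverse_scan_convert(image)
            fan = fan_geometry_for_frame(shape, theta0, self.inner_ratio)
            out = scan_convert(beam, fan, shape=shape)
            return image.copy(pixels=out.pixels, mask=out.mask, geometry=fan)
        beam = inverse_scan_convert(image)
        rect = image.copy(
            pixels=np.clip(beam, 0.0, 1.0),
            mask=np.ones(beam.shape, dtype=np.uint8),
            geometry=None,
        )
        rect = resize_image(rect, shape)
        rect.geometry = FOVGeometry(
            kind=LINEAR,
            apex=(0.0, (shape[1] - 1) / 2.0),
            theta0=0.0,
            r_min=0.0,
            r_max=float(shape[0] - 1),
            width=float(shape[1] - 1),
        )
        rect.mask = np.ones(shape, dtype=np.uint8)
        return rezero(rect)


@register
class ConvexityChange(Transform):
    """B01 — rescale the angular half-width theta0, moving the bottom corners.

    Samples a multiplier ``m`` and resamples beam-space content onto the same
    geometry with ``theta0' = clamp(m * theta0, 0.1, 1.2)``.  Linear inputs
    are returned unchanged (logged as a no-op).
    """

    id = "B01"
    name = "convexity_change"
    requires_geometry = True

    def __init__(self, multiplier_range: tuple[float, float] = (0.7, 1.3)):
        self.multiplier_range = (float(multiplier_range[0]), float(multiplier_range[1]))

    def sample_params(self, image, rng):
        return {"multiplier": float(rng.uniform(*self.multiplier_range))}

    def apply(self, image, *, multiplier):
        geometry = _require_geometry(image)
        if geometry.kind == LINEAR:
            out = image.copy()
            out.meta["B01"] = "no-op on linear FOV"
            return out
        theta0 = min(max(multiplier * geometry.theta0, 0.1), 1.2)
        # oversample the intermediate beam lattice 2x so the cart -> beam ->
        # cart chain stays interpolation-limited, not lattice-limited
        n_r = 2 * max(int(round(geometry.r_max - geometry.r_min)), 2)
        n_theta = 2 * max(int(round(2.0 * geometry.theta0 * geometry.r_max)), 2)
        beam = inverse_scan_convert(image, n_theta=n_theta, n_r=n_r)
        new_geom = replace(geometry, theta0=theta0)
        out = scan_convert(beam, new_geom, shape=image.shape)
        return image.copy(pixels=out.pixels, mask=out.mask, geometry=new_geom)


@register
class WaveletDenoise(Transform):
    """B02 — wavelet-shrinkage denoising with a level-dependent retention rule.

    After an L-level 2-D decomposition, each detail band at level ``j``
    (1 = coarsest detail) retains only its ``n_j = M / (j + 1)**alpha``
    largest-magnitude coefficients, where ``M`` is the size of the coarsest
    approximation band; everything else is zeroed before reconstruction.
    ``alpha = 3`` is the denoising/compression regime; ``alpha -> 0`` keeps
    every coefficient (``n_j = M`` >= band size) and is a near-identity.
    """

    id = "B02"
    name = "wavelet_denoise"

    def __init__(self, levels: int = 3, alpha: float = 3.0, wavelet: str = "db2"):
        self.levels = int(levels)
        self.alpha = float(alpha)
        self.wavelet = wavelet

    def apply(self, image):
        if min(image.shape) < 2**self.levels:
            raise ParameterError(
                f"image must be at least {2**self.levels} px per side for "
                f"{self.levels} decomposition levels"
            )
        coeffs = pywt.wavedec2(image.pixels, self.wavelet, level=self.levels)
        m = coeffs[0].size
        new_coeffs = [coeffs[0]]
        for j, triple in enumerate(coeffs[1:], start=1):
            n_keep = int(m / (j + 1) ** self.alpha)
            kept = []
            for band in triple:
                if n_keep >= band.size:
                    kept.append(band)
                elif n_keep <= 0:
                    kept.append(np.zeros_like(band))
                else:
                    flat = np.abs(band).ravel()
                    cutoff = np.partition(flat, flat.size - n_keep)[flat.size - n_keep]
                    kept.append(np.where(np.abs(band) >= cutoff, band, 0.0))
            new_coeffs.append(tuple(kept))
        rec = pywt.waverec2(new_coeffs, self.wavelet)
        rec = rec[: image.shape[0], : image.shape[1]]
        out = image.copy(pixels=clip01(rec))
        return rezero(out)


@register
class Clahe(Transform):
    """B03 — contrast-limited adaptive histogram equalization.

    Histograms are built per tile over the 8-bit quantized in-FOV pixels
    only; each histogram is clipped at ``clip_limit`` times the uniform bin
    height with the excess redistributed evenly, and pixel mappings are
    bilinearly interpolated between tile centres.  Tiles without FOV pixels
    inherit the global in-FOV histogram, so a constant FOV maps to a constant.
    """

    id = "B03"
    name = "clahe"

    def __init__(
        self,
        clip_limit_range: tuple[float, float] = (1.0, 4.0),
        tile_grid: tuple[int, int] = (8, 8),
        n_bins: int = 256,
    ):
        self.clip_limit_range = (float(clip_limit_range[0]), float(clip_limit_range[1]))
        self.tile_grid = (int(tile_grid[0]), int(tile_grid[1]))
        self.n_bins = int(n_bins)

    def sample_params(self, image, rng):
        return {"clip_limit": float(rng.uniform(*self.clip_limit_range))}

    def _tile_mapping(self, values: np.ndarray, clip_limit: float) -> np.ndarray:
        hist = np.bincount(values, minlength=self.n_bins).astype(np.float64)
        total = hist.sum()
        clip_height = clip_limit * total / self.n_bins
        excess = np.maximum(hist - clip_height, 0.0).sum()
        hist = np.minimum(hist, clip_height) + excess / self.n_bins
        cdf = np.cumsum(hist)
        return cdf / cdf[-1] * (self.n_bins - 1)

    def apply(self, image, *, clip_limit):
        rows, cols = image.shape
        ty, tx = self.tile_grid
        quant = to_uint8(image.pixels)
        inside = image.mask.astype(bool)
        if not inside.any():
            return image.copy()

        row_edges = np.linspace(0, rows, ty + 1).astype(int)
        col_edges = np.linspace(0, cols, tx + 1).astype(int)
        global_map = self._tile_mapping(quant[inside], clip_limit)

        mappings = np.empty((ty, tx, self.n_bins), dtype=np.float64)
        for i in range(ty):
            for j in range(tx):
                sl = (
                    slice(row_edges[i], row_edges[i + 1]),
                    slice(col_edges[j], col_edges[j + 1]),
                )
                tile_inside = inside[sl]
                if tile_inside.any():
                    mappings[i, j] = self._tile_mapping(
                        quant[sl][tile_inside], clip_limit
                    )
                else:
                    mappings[i, j] = global_map

        centres_r = (row_edges[:-1] + row_edges[1:]) / 2.0
        centres_c = (col_edges[:-1] + col_edges[1:]) / 2.0
        rr, cc = np.mgrid[0:rows, 0:cols]
        fi = np.interp(rr, centres_r, np.arange(ty))
        fj = np.interp(cc, centres_c, np.arange(tx))
        i0 = np.clip(np.floor(fi).astype(int), 0, ty - 1)
        j0 = np.clip(np.floor(fj).astype(int), 0, tx - 1)
        i1 = np.minimum(i0 + 1, ty - 1)
        j1 = np.minimum(j0 + 1, tx - 1)
        wi = fi - i0
        wj = fj - j0

        v = quant
        mapped = (
            (1 - wi) * (1 - wj) * mappings[i0, j0, v]
            + (1 - wi) * wj * mappings[i0, j1, v]
            + wi * (1 - wj) * mappings[i1, j0, v]
            + wi * wj * mappings[i1, j1, v]
        )
        out = image.copy(pixels=clip01(mapped / (self.n_bins - 1)))
        return rezero(out)


@register
class GammaCorrect(Transform):
    """B04 — power-law intensity remapping, gamma drawn log-uniformly."""

    id = "B04"
    name = "gamma_correct"

    def __init__(self, gamma_range: tuple[float, float] = (0.7, 1.5)):
        self.gamma_range = (float(gamma_range[0]), float(gamma_range[1]))

    def sample_params(self, image, rng):
        lo, hi = self.gamma_range
        return {"gamma": float(math.exp(rng.uniform(math.log(lo), math.log(hi))))}

    def apply(self, image, *, gamma):
        out = image.copy()
        if gamma != 1.0:
            out.pixels = np.power(out.pixels, gamma)
        return rezero(out)


@register
class BrightnessContrast(Transform):
    """B05 — linear intensity transform ``a * x + b`` with clipping."""

    id = "B05"
    name = "brightness_contrast"

    def __init__(
        self,
        a_range: tuple[float, float] = (0.8, 1.2),
        b_range: tuple[float, float] = (-0.12, 0.12),
    ):
        self.a_range = (float(a_range[0]), float(a_range[1]))
        self.b_range = (float(b_range[0]), float(b_range[1]))

    def sample_params(self, image, rng):
        return {
            "a": float(rng.uniform(*self.a_range)),
            "b": float(rng.uniform(*self.b_range)),
        }

    def apply(self, image, *, a, b):
        out = image.copy()
        if a != 1.0 or b != 0.0:
            out.pixels = clip01(a * out.pixels + b)
        return rezero(out)


@register
class DepthChange(Transform):
    """B06 — simulate a depth-control change: random zoom that preserves the
    FOV shape.  Content is rescaled radially about the apex (fans) or
    vertically about the top edge of the FOV (linear); mask and geometry are
    unchanged and content is re-zeroed outside them.
    """

    id = "B06"
    name = "depth_change"
    requires_geometry = True

    def __init__(self, zoom_range: tuple[float, float] = (0.85, 1.25)):
        self.zoom_range = (float(zoom_range[0]), float(zoom_range[1]))

    def sample_params(self, image, rng):
        _require_geometry(image)
        return {"zoom": float(rng.uniform(*self.zoom_range))}

    def apply(self, image, *, zoom):
        geometry = _require_geometry(image)
        if zoom == 1.0:
            return image.copy()
        rows, cols = image.shape
        rr, cc = np.mgrid[0:rows, 0:cols].astype(np.float64)
        if geometry.kind == LINEAR:
            src_r = geometry.r_min + (rr - geometry.r_min) * zoom
            src_c = cc
        else:
            src_r = geometry.apex[0] + (rr - geometry.apex[0]) * zoom
            src_c = geometry.apex[1] + (cc - geometry.apex[1]) * zoom
        pixels = ndimage.map_coordinates(
            image.pixels, [src_r.ravel(), src_c.ravel()], order=1, cval=0.0
        ).reshape(rows, cols)
        out = image.copy(pixels=clip01(pixels))
        return rezero(out)


def _smoothed_noise_std_factor(smooth_sigma: float) -> float:
    """Std attenuation of white noise after Gaussian smoothing (2-D)."""
    radius = max(int(math.ceil(3.0 * smooth_sigma)), 1)
    x = np.arange(-radius, radius + 1)
    k = np.exp(-0.5 * (x / smooth_sigma) ** 2)
    k /= k.sum()
    k2d = np.outer(k, k)
    return float(np.sqrt((k2d**2).sum()))


@register
class SpeckleNoise(Transform):
    """B07 — synthetic speckle: a spatially correlated multiplicative field.

    ``out = clip(x + x * s)`` where ``s`` is zero-mean Gaussian with std
    ``speckle_sigma``, smoothed by a sigma=1 px Gaussian kernel to induce the
    short-range correlation characteristic of speckle.
    """

    id = "B07"
    name = "speckle_noise"

    def __init__(self, params: NoiseParams | None = None, smooth_sigma: float = 1.0):
        self.params = params or NoiseParams()
        self.smooth_sigma = float(smooth_sigma)

    def sample_params(self, image, rng):
        return {"seed": sub_seed(rng)}

    def apply(self, image, *, seed):
        out = image.copy()
        sigma = self.params.speckle_sigma
        if sigma > 0:
            field_rng = np.random.default_rng(seed)
            s = field_rng.normal(0.0, sigma, size=image.shape)
            s = ndimage.gaussian_filter(s, self.smooth_sigma, mode="reflect")
            out.pixels = clip01(out.pixels + out.pixels * s)
        return rezero(out)

    def expected_field_std(self) -> float:
        """Std of the smoothed speckle field (used by calibration checks)."""
        return self.params.speckle_sigma * _smoothed_noise_std_factor(self.smooth_sigma)


@register
class GaussianNoise(Transform):
    """B08 — i.i.d. multiplicative Gaussian noise: ``clip(x * (1 + n))``."""

    id = "B08"
    name = "gaussian_noise"

    def __init__(self, params: NoiseParams | None = None):
        self.params = params or NoiseParams()

    def sample_params(self, image, rng):
        return {"seed": sub_seed(rng)}

    def apply(self, image, *, seed):
        out = image.copy()
        sigma = self.params.gauss_sigma
        if sigma > 0:
            n = np.random.default_rng(seed).normal(0.0, sigma, size=image.shape)
            out.pixels = clip01(out.pixels * (1.0 + n))
        return rezero(out)


@register
class SaltPepper(Transform):
    """B09 — each in-FOV pixel is replaced by 0 or 1 with probability sp_rate."""

    id = "B09"
    name = "salt_pepper"

    def __init__(self, params: NoiseParams | None = None):
        self.params = params or NoiseParams()

    def sample_params(self, image, rng):
        return {"seed": sub_seed(rng)}

    def apply(self, image, *, seed):
        out = image.copy()
        rate = self.params.sp_rate
        if rate > 0:
            field_rng = np.random.default_rng(seed)
            hit = field_rng.random(image.shape) < rate
            salt = field_rng.random(image.shape) < 0.5
            hit &= out.mask.astype(bool)
            out.pixels = np.where(hit, np.where(salt, 1.0, 0.0), out.pixels)
        return rezero(out)


@register
class HorizontalReflectUS(HorizontalReflect):
    """B10 — horizontal reflection (ultrasound pipeline alias of A01)."""

    id = "B10"


@register
class RotateShift(Transform):
    """B11 — random rotation about the centre plus a random translation.

    Bilinear interpolation with constant-0 fill; the mask is transformed
    identically and re-binarized, and the parametric geometry is dropped
    (the FOV is no longer an upright rectangle or fan).
    """

    id = "B11"
    name = "rotate_shift"

    def __init__(
        self, angle_range_deg: tuple[float, float] = (-15.0, 15.0), shift_frac: float = 0.1
    ):
        self.angle_range_deg = (float(angle_range_deg[0]), float(angle_range_deg[1]))
        self.shift_frac = float(shift_frac)

    def sample_params(self, image, rng):
        rows, cols = image.shape
        return {
            "angle_deg": float(rng.uniform(*self.angle_range_deg)),
            "shift_rows": float(rng.uniform(-self.shift_frac, self.shift_frac) * rows),
            "shift_cols": float(rng.uniform(-self.shift_frac, self.shift_frac) * cols),
        }

    def apply(self, image, *, angle_deg, shift_rows, shift_cols):
        if angle_deg == 0.0 and shift_rows == 0.0 and shift_cols == 0.0:
            return image.copy()
        rows, cols = image.shape
        centre = np.array([(rows - 1) / 2.0, (cols - 1) / 2.0])
        shift = np.array([shift_rows, shift_cols])
        phi = math.radians(angle_deg)
        # forward map: p' = R (p - centre) + centre + shift; ndimage wants inverse
        rot = np.array([[math.cos(phi), -math.sin(phi)], [math.sin(phi), math.cos(phi)]])
        inv = rot.T
        offset = centre - inv @ (centre + shift)
        pixels = ndimage.affine_transform(
            image.pixels, inv, offset=offset, order=1, cval=0.0
        )
        mask_f = ndimage.affine_transform(
            image.mask.astype(np.float64), inv, offset=offset, order=1, cval=0.0
        )
        out = image.copy(
            pixels=clip01(pixels), mask=(mask_f >= 0.5).astype(np.uint8), geometry=None
        )
        return rezero(out)
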