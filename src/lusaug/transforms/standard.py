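"""The baseline augmentation operators used across imaging domains (A00-A05):
random crop-and-resize, horizontal reflection, colour jitter, grayscale
conversion, Gaussian blur, and solarization.

Ultrasound is single-channel, so the saturation/hue legs of colour jitter and
the grayscale conversion are identities here; they are kept so that pipelines
remain faithful to their published composition, and their application is still
logged in provenance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from ..errors import ParameterError
from ..image import UltrasoundImage
from . import Transform, clip01, register, rezero

#: output size of every builtin pipeline (display resolution of the encoder)
DEFAULT_OUT_SIZE = (128, 128)


def resize_image(
    image: UltrasoundImage, out_size: tuple[int, int]
) -> UltrasoundImage:
    """Bilinear resize of pixels and mask; the mask is re-binarized at 0.5.

    Resampling invalidates the stored FOV geometry unless the shape is
    unchanged, in which case this is the identity.
    """
    out_size = (int(out_size[0]), int(out_size[1]))
    if image.shape == out_size:
        return image.copy()
    pixels = _sk_resize(
        image.pixels, out_size, order=1, preserve_range=True, anti_aliasing=False
    )
    mask = (
        _sk_resize(
            image.mask.astype(np.float64),
            out_size,
            order=1,
            preserve_range=True,
            anti_aliasing=False,
        )
        >= 0.5
    ).astype(np.uint8)
    out = image.copy(pixels=clip01(pixels), mask=mask, geometry=None)
    return rezero(out)


@dataclass(frozen=True)
class CropParams:
    """Sampling ranges for random crop-and-resize.

    ``c_min`` is the minimum crop area as a fraction of the frame area (the
    hyperparameter *c*, default 0.08, i.e. crops cover 8-100% of the image);
    aspect ratios (width/height) are drawn log-uniformly from
    ``aspect_range``.
    """

    c_min: float = 0.08
    c_max: float = 1.0
    aspect_range: tuple[float, float] = (3.0 / 4.0, 4.0 / 3.0)
    out_size: tuple[int, int] = DEFAULT_OUT_SIZE

    def __post_init__(self) -> None:
        if not 0.0 < self.c_min <= self.c_max <= 1.0:
            raise ParameterError("need 0 < c_min <= c_max <= 1")
        lo, hi = self.aspect_range
        if not lo <= hi:
            raise ParameterError("aspect_range must be (low, high) with low <= high")


def sample_crop_window(
    shape: tuple[int, int], params: CropParams, rng: np.random.Generator
) -> tuple[int, int, int, int]:
    """Draw one crop window ``(row0, col0, height, width)``.

    The area fraction is uniform on ``[c_min, c_max]`` and the aspect ratio
    log-uniform on ``aspect_range``; windows that do not fit the frame are
    rejected (up to 10 attempts), after which a centred window scaled by
    ``sqrt(c_min)`` is used.
    """
    rows, cols = shape
    area = rows * cols
    lo, hi = params.aspect_range
    for _ in range(10):
        frac = rng.uniform(params.c_min, params.c_max)
        aspect = math.exp(rng.uniform(math.log(lo), math.log(hi)))
        target = frac * area
        # ceil keeps the realised window area at or above the sampled target,
        # so every draw honours the c_min lower bound after discretisation
        h = int(math.ceil(math.sqrt(target / aspect)))
        w = int(math.ceil(math.sqrt(target * aspect)))
        if 0 < h <= rows and 0 < w <= cols:
            r0 = int(rng.integers(0, rows - h + 1))
            c0 = int(rng.integers(0, cols - w + 1))
            return r0, c0, h, w
    scale = math.sqrt(params.c_min)
    h = max(int(math.ceil(rows * scale)), 1)
    w = max(int(math.ceil(cols * scale)), 1)
    return (rows - h) // 2, (cols - w) // 2, h, w


@register
class CropAndResize(Transform):
    """A00 — random crop covering 8-100% of the frame, resized to a fixed size."""

    id = "A00"
    name = "crop_and_resize"

    def __init__(self, params: CropParams | None = None, **kw):
        if params is None:
            params = CropParams(**kw) if kw else CropParams()
        self.params = params

    def sample_params(self, image, rng):
        if min(image.shape) < 8:
            raise ParameterError("crop requires an image of at least 8x8")
        r0, c0, h, w = sample_crop_window(image.shape, self.params, rng)
        return {"row0": r0, "col0": c0, "height": h, "width": w}

    def apply(self, image, *, row0, col0, height, width):
        window = image.copy(
            pixels=image.pixels[row0 : row0 + height, col0 : col0 + width].copy(),
            mask=image.mask[row0 : row0 + height, col0 : col0 + width].copy(),
            geometry=None,
        )
        return resize_image(window, self.params.out_size)


def horizontal_reflect(image: UltrasoundImage) -> UltrasoundImage:
    """Reflect pixels and mask about the central vertical axis."""
    geometry = image.geometry
    if geometry is not None:
        cols = image.shape[1]
        geometry = geometry.shifted(0.0, 0.0)  # copy
        from dataclasses import replace

        geometry = replace(
            geometry, apex=(geometry.apex[0], cols - 1 - geometry.apex[1])
        )
    return image.copy(
        pixels=image.pixels[:, ::-1].copy(),
        mask=image.mask[:, ::-1].copy(),
        geometry=geometry,
    )


@register
class HorizontalReflect(Transform):
    """A01 — horizontal reflection."""

    id = "A01"
    name = "horizontal_reflect"

    def apply(self, image):
        return horizontal_reflect(image)


@register
class ColourJitter(Transform):
    """A02 — brightness/contrast/saturation/hue jitter, applied in random order.

    On single-channel ultrasound the saturation and hue legs collapse to
    identities; they are drawn and logged regardless so provenance mirrors
    the published operator.
    """

    id = "A02"
    name = "colour_jitter"

    def __init__(self, strengths: tuple[float, float, float, float] = (0.8, 0.8, 0.8, 0.2)):
        self.strengths = tuple(float(s) for s in strengths)

    def sample_params(self, image, rng):
        b, c, s, h = self.strengths
        factors = {
            "brightness": float(rng.uniform(max(0.0, 1 - b), 1 + b)),
            "contrast": float(rng.uniform(max(0.0, 1 - c), 1 + c)),
            "saturation": float(rng.uniform(max(0.0, 1 - s), 1 + s)),
            "hue": float(rng.uniform(-h, h)),
        }
        order = list(factors)
        rng.shuffle(order)
        return {"order": order, **factors}

    def apply(self, image, *, order, brightness, contrast, saturation, hue):
        out = image.copy()
        px = out.pixels
        inside = out.mask.astype(bool)
        for op in order:
            if op == "brightness" and brightness != 1.0:
                px = clip01(px * brightness)
            elif op == "contrast" and contrast != 1.0:
                mean = float(px[inside].mean()) if inside.any() else 0.0
                px = clip01(px * contrast + mean * (1.0 - contrast))
            # saturation / hue: identity for single-channel input
        out.pixels = px
        return rezero(out)


@register
class ToGrayscale(Transform):
    """A03 — grayscale conversion; identity on single-channel input."""

    id = "A03"
    name = "to_grayscale"

    def apply(self, image):
        return image.copy()

    @staticmethod
    def collapse(rgb: np.ndarray) -> np.ndarray:
        """Channel-mean collapse of an (H, W, 3) array to (H, W)."""
        return np.asarray(rgb, dtype=np.float64).mean(axis=-1)


@register
class GaussianBlur(Transform):
    """A04 — isotropic Gaussian blur with sigma drawn uniformly."""

    id = "A04"
    name = "gaussian_blur"

    def __init__(self, sigma_range: tuple[float, float] = (0.1, 2.0)):
        self.sigma_range = (float(sigma_range[0]), float(sigma_range[1]))

    def sample_params(self, image, rng):
        return {"sigma": float(rng.uniform(*self.sigma_range))}

    def apply(self, image, *, sigma):
        out = image.copy()
        if sigma > 0:
            radius = max(int(math.ceil(3.0 * sigma)), 1)
            out.pixels = clip01(
                ndimage.gaussian_filter(
                    out.pixels, sigma=sigma, mode="reflect", truncate=radius / sigma
                )
            )
        return rezero(out)


@register
class Solarize(Transform):
    """A05 — pixels at or above a threshold are inverted (v -> 1 - v)."""

    id = "A05"
    name = "solarize"

    def __init__(self, threshold: float = 0.5):
        self.threshold = float(threshold)

    def apply(self, image):
        out = image.copy()
        hot = out.pixels >= self.threshold
        out.pixels = np.where(hot, 1.0 - out.pixels, out.pixels)
        return rezero(out)
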