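"""In-memory container for a B-mode ultrasound frame.

An :class:`UltrasoundImage` bundles the pixel grid, the binary field-of-view
(FOV) mask, and (optionally) a parametric description of the FOV shape.
Pixels are stored as ``float64`` in ``[0, 1]`` while in memory; 8-bit PNG is
the interchange format on disk.  Coordinates are 0-based ``(row, col)`` with
the origin at the top-left corner; depth increases with row.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
from PIL import Image as _PILImage


def to_unit(pixels: np.ndarray) -> np.ndarray:
    """Convert an 8-bit (or float) grid to float64 in [0, 1]."""
    arr = np.asarray(pixels)
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    out = arr.astype(np.float64)
    return np.clip(out, 0.0, 1.0)


def to_uint8(pixels: np.ndarray) -> np.ndarray:
    """Quantize a [0, 1] grid to 8 bits with round-half-up."""
    scaled = np.clip(np.asarray(pixels, dtype=np.float64), 0.0, 1.0) * 255.0
    return np.floor(scaled + 0.5).astype(np.uint8)


@dataclass
class UltrasoundImage:
    """A grayscale ultrasound frame with its FOV mask and metadata.

    Parameters
    ----------
    pixels
        2-D float64 array in [0, 1].
    mask
        2-D uint8 array of the same shape; 1 inside the FOV.  Defaults to
        all-ones.
    geometry
        Optional :class:`~lusaug.geometry.FOVGeometry` describing the FOV
        shape.  Transforms that resample the frame may drop it (set to None)
        when it no longer describes the mask.
    patient_id
        Opaque label used for patient-level splitting.
    class_label
        Optional categorical phantom ground-truth label.
    """

    pixels: np.ndarray
    mask: Optional[np.ndarray] = None
    geometry: Optional[object] = None
    patient_id: str = ""
    class_label: Optional[str] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D grayscale grid")
        if self.mask is None:
            self.mask = np.ones(self.pixels.shape, dtype=np.uint8)
        else:
            self.mask = (np.asarray(self.mask) > 0).astype(np.uint8)
        if self.mask.shape != self.pixels.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} != pixels shape {self.pixels.shape}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def copy(self, **changes) -> "UltrasoundImage":
        out = replace(self, **changes)
        if "pixels" not in changes:
            out.pixels = self.pixels.copy()
        if "mask" not in changes:
            out.mask = self.mask.copy()
        if "meta" not in changes:
            out.meta = dict(self.meta)
        return out

    # ------------------------------------------------------------------ I/O
    @classmethod
    def load(cls, path: str | Path, mask_path: str | Path | None = None) -> "UltrasoundImage":
        """Read a grayscale PNG (JPEG accepted, lossy) and optional mask PNG."""
        img = _PILImage.open(path).convert("L")
        pixels = to_unit(np.asarray(img, dtype=np.uint8))
        mask = None
        if mask_path is not None:
            m = _PILImage.open(mask_path).convert("L")
            mask = (np.asarray(m) > 127).astype(np.uint8)
        return cls(pixels=pixels, mask=mask)

    def save(self, path: str | Path, mask_path: str | Path | None = None) -> None:
        """Write the frame (and optionally its mask) as 8-bit grayscale PNG."""
        _PILImage.fromarray(to_uint8(self.pixels), mode="L").save(path)
        if mask_path is not None:
            _PILImage.fromarray((self.mask * 255).astype(np.uint8), mode="L").save(mask_path)
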