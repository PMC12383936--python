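"""Field-of-view (FOV) geometry: modelling, estimation, and scan conversion.

Ultrasound frames carry echo data only inside the probe's field of view: a
rectangle for linear arrays, a fan (annular sector) for curvilinear and
phased arrays.  This module provides

* :class:`FOVGeometry` — a parametric FOV description (probe kind, beam apex,
  angular half-width ``theta0``, radial range);
* semantics-preserving preprocessing: :func:`apply_mask` (element-wise
  multiplication with the binary FOV mask) and :func:`crop_to_fov` (crop to
  the smallest rectangle enclosing the mask);
* :func:`estimate_fov_mask` — a simple mask estimator for clean/synthetic
  frames (largest above-threshold connected component, closed and filled);
* :func:`render_fov_mask` / :func:`fit_fov_geometry` — rasterise a geometry
  to a mask and recover a geometry from a mask;
* :func:`scan_convert` / :func:`inverse_scan_convert` — resample between
  beam space (depth x beam angle) and Cartesian display coordinates.

Conventions: 0-based ``(row, col)`` coordinates, origin top-left, depth
increasing with row.  The beam angle ``theta`` is measured from the vertical
centreline, positive rightward, so a Cartesian point ``p`` maps to
``r = |p - apex|`` and ``theta = atan2(col - apex_col, row - apex_row)``.
For a fan, the outer arc meets the lateral edges at the bottom corners
``apex + r_max * (cos theta0, ±sin theta0)``; their lateral separation
``2 r_max sin(theta0)`` grows monotonically with ``theta0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import ndimage

from .errors import (
    EmptyMaskError,
    FitError,
    ParameterError,
    ShapeMismatchError,
)
from .image import UltrasoundImage

LINEAR = "linear"
CURVILINEAR = "curvilinear"
PHASED = "phased"

#: below this r_min / r_max ratio a fan is classified as a phased array
PHASED_RATIO = 0.05

#: maximum mean perpendicular residual (px) of the lateral-edge line fit
EDGE_FIT_TOL = 1.5


@dataclass(frozen=True)
class FOVGeometry:
    """Parametric description of an ultrasound field of view.

    For fans (``curvilinear``/``phased``), ``apex`` is the beam origin in
    frame coordinates (possibly above the frame, ``apex[0] < 0``) and
    ``r_min``/``r_max`` are radial distances from the apex in pixels.  For
    ``linear`` probes the FOV is the rectangle with rows ``[r_min, r_max]``
    and columns centred on ``apex[1]`` with lateral extent ``width``;
    ``theta0`` is 0 by definition.
    """

    kind: str
    apex: tuple[float, float]
    theta0: float
    r_min: float
    r_max: float
    width: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in (LINEAR, CURVILINEAR, PHASED):
            raise ParameterError(f"unknown FOV kind {self.kind!r}")
        if self.kind == LINEAR:
            if self.theta0 != 0.0:
                raise ParameterError("linear FOV requires theta0 = 0")
            if self.width <= 0:
                raise ParameterError("linear FOV requires positive width")
        else:
            if not 0.0 < self.theta0 < math.pi / 2:
                raise ParameterError("fan FOV requires 0 < theta0 < pi/2")
        if not self.r_min < self.r_max:
            raise ParameterError("r_min must be < r_max")
        if self.kind == PHASED and self.r_min > PHASED_RATIO * self.r_max:
            raise ParameterError("phased FOV requires r_min <= 0.05 * r_max")

    @property
    def bottom_corners(self) -> tuple[tuple[float, float], tuple[float, float]]:
        """The points where the outer arc meets the lateral FOV edges."""
        if self.kind == LINEAR:
            half = self.width / 2.0
            return (
                (self.r_max, self.apex[1] - half),
                (self.r_max, self.apex[1] + half),
            )
        dr = self.r_max * math.cos(self.theta0)
        dc = self.r_max * math.sin(self.theta0)
        return (
            (self.apex[0] + dr, self.apex[1] - dc),
            (self.apex[0] + dr, self.apex[1] + dc),
        )

    def shifted(self, d_row: float, d_col: float) -> "FOVGeometry":
        """Geometry after translating the frame origin by ``(d_row, d_col)``."""
        apex = (self.apex[0] - d_row, self.apex[1] - d_col)
        if self.kind == LINEAR:
            return replace(
                self, apex=apex, r_min=self.r_min - d_row, r_max=self.r_max - d_row
            )
        return replace(self, apex=apex)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "apex_row": float(self.apex[0]),
            "apex_col": float(self.apex[1]),
            "theta0": float(self.theta0),
            "r_min": float(self.r_min),
            "r_max": float(self.r_max),
            "width": float(self.width),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FOVGeometry":
        return cls(
            kind=d["kind"],
            apex=(float(d["apex_row"]), float(d["apex_col"])),
            theta0=float(d["theta0"]),
            r_min=float(d["r_min"]),
            r_max=float(d["r_max"]),
            width=float(d.get("width", 0.0)),
        )


# --------------------------------------------------------------------------
# Semantics-preserving preprocessing
# --------------------------------------------------------------------------

def apply_mask(image: UltrasoundImage) -> UltrasoundImage:
    """Zero every pixel outside the FOV mask (element-wise multiplication)."""
    if image.mask.shape != image.pixels.shape:
        raise ShapeMismatchError("mask and pixels differ in shape")
    return image.copy(pixels=image.pixels * image.mask)


def crop_to_fov(image: UltrasoundImage) -> UltrasoundImage:
    """Crop to the smallest rectangle that encapsulates the FOV mask."""
    rows = np.flatnonzero(image.mask.any(axis=1))
    cols = np.flatnonzero(image.mask.any(axis=0))
    if rows.size == 0:
        raise EmptyMaskError("cannot crop to an empty FOV mask")
    r0, r1 = int(rows[0]), int(rows[-1]) + 1
    c0, c1 = int(cols[0]), int(cols[-1]) + 1
    geometry = image.geometry
    if geometry is not None:
        geometry = geometry.shifted(r0, c0)
    return image.copy(
        pixels=image.pixels[r0:r1, c0:c1].copy(),
        mask=image.mask[r0:r1, c0:c1].copy(),
        geometry=geometry,
    )


def preprocess(image: UltrasoundImage) -> UltrasoundImage:
    """Mask multiplication followed by FOV cropping."""
    return crop_to_fov(apply_mask(image))


def estimate_fov_mask(
    pixels: np.ndarray,
    threshold: float = 2.0 / 255.0,
    closing_size: int = 5,
) -> np.ndarray:
    """Estimate a binary FOV mask from a clean frame.

    Returns the hole-filled largest connected component of above-threshold
    pixels after morphological closing.  Intended for synthetic or
    already-cleaned frames with (near-)zero background; frames from real
    machines with burnt-in annotation should use externally supplied masks.
    """
    from .image import to_unit

    grid = to_unit(pixels)
    fg = grid > threshold
    if not fg.any():
        raise EmptyMaskError("no pixel above the FOV threshold")
    fg = ndimage.binary_closing(fg, structure=np.ones((closing_size, closing_size)))
    labels, n = ndimage.label(fg)
    if n == 0:
        raise EmptyMaskError("no connected component above the FOV threshold")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    mask = labels == largest
    mask = ndimage.binary_fill_holes(mask)
    return mask.astype(np.uint8)


# --------------------------------------------------------------------------
# Rendering and fitting
# --------------------------------------------------------------------------

def render_fov_mask(geometry: FOVGeometry, shape: tuple[int, int]) -> np.ndarray:
    """Rasterise a geometry: 1 where the pixel centre lies inside the FOV."""
    rows, cols = shape
    rr, cc = np.mgrid[0:rows, 0:cols].astype(np.float64)
    if geometry.kind == LINEAR:
        half = geometry.width / 2.0
        mask = (
            (rr >= geometry.r_min)
            & (rr <= geometry.r_max)
            & (cc >= geometry.apex[1] - half)
            & (cc <= geometry.apex[1] + half)
        )
    else:
        dr = rr - geometry.apex[0]
        dc = cc - geometry.apex[1]
        r = np.hypot(dr, dc)
        theta = np.arctan2(dc, dr)
        mask = (
            (r >= geometry.r_min)
            & (r <= geometry.r_max)
            & (np.abs(theta) <= geometry.theta0)
        )
    if not mask.any():
        raise EmptyMaskError("geometry lies entirely outside the frame")
    return mask.astype(np.uint8)


def _tls_line(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Total-least-squares line through Nx2 points.

    Returns (centroid, unit direction oriented with increasing row,
    mean perpendicular residual).
    """
    centroid = points.mean(axis=0)
    centred = points - centroid
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    direction = vt[0]
    if direction[0] < 0:
        direction = -direction
    normal = np.array([-direction[1], direction[0]])
    residual = float(np.mean(np.abs(centred @ normal)))
    return centroid, direction, residual


def fit_fov_geometry(mask: np.ndarray) -> FOVGeometry:
    """Recover an :class:`FOVGeometry` from a binary mask.

    Row-widths constant within pixelation tolerance -> linear rectangle.
    Otherwise the two lateral edges are fit with total-least-squares lines
    over the rows above the widest row (where the extreme columns lie on the
    straight edges, not on the outer arc); the apex is their intersection.
    """
    mask = (np.asarray(mask) > 0).astype(np.uint8)
    row_any = mask.any(axis=1)
    row_idx = np.flatnonzero(row_any)
    if row_idx.size == 0:
        raise EmptyMaskError("cannot fit geometry to an empty mask")

    left = np.argmax(mask[row_idx], axis=1).astype(np.float64)
    right = (mask.shape[1] - 1 - np.argmax(mask[row_idx][:, ::-1], axis=1)).astype(
        np.float64
    )
    widths = right - left + 1.0

    if widths.max() - widths.min() <= 2.0:
        r0, r1 = float(row_idx[0]), float(row_idx[-1])
        c0, c1 = float(left.min()), float(right.max())
        return FOVGeometry(
            kind=LINEAR,
            apex=(r0, (c0 + c1) / 2.0),
            theta0=0.0,
            r_min=r0,
            r_max=r1,
            width=c1 - c0,
        )

    # fan: edges are straight above the widest row
    widest = int(np.argmax(widths))
    lo, hi = 1, widest - 1  # trim one row at each end against arc contamination
    if hi - lo < 5:
        raise FitError("too few straight-edge rows to fit a fan FOV")
    rows_sub = row_idx[lo:hi].astype(np.float64)
    pl = np.column_stack([rows_sub, left[lo:hi]])
    pr = np.column_stack([rows_sub, right[lo:hi]])
    cl, dl, res_l = _tls_line(pl)
    cr, dr_, res_r = _tls_line(pr)
    if max(res_l, res_r) > EDGE_FIT_TOL:
        raise FitError(
            f"lateral-edge residual {max(res_l, res_r):.2f} px exceeds "
            f"{EDGE_FIT_TOL} px; mask fits neither FOV model"
        )

    # apex = intersection of the two edge lines
    a = np.column_stack([dl, -dr_])
    b = cr - cl
    try:
        t, _ = np.linalg.solve(a, b)
    except np.linalg.LinAlgError as exc:  # parallel edges
        raise FitError("lateral edges are parallel; no apex") from exc
    apex = cl + t * dl

    angle_l = math.atan2(abs(dl[1]), dl[0])
    angle_r = math.atan2(abs(dr_[1]), dr_[0])
    theta0 = (angle_l + angle_r) / 2.0

    rr, cc = np.nonzero(mask)
    radii = np.hypot(rr - apex[0], cc - apex[1])
    # pixel centres under-cover the true radial band by ~half a pixel
    r_min = max(float(radii.min()) - 0.5, 0.0)
    r_max = float(radii.max()) + 0.5
    kind = PHASED if r_min <= PHASED_RATIO * r_max else CURVILINEAR
    if kind == PHASED:
        r_min = min(r_min, PHASED_RATIO * r_max)
    return FOVGeometry(
        kind=kind,
        apex=(float(apex[0]), float(apex[1])),
        theta0=float(theta0),
        r_min=r_min,
        r_max=r_max,
    )


# --------------------------------------------------------------------------
# Scan conversion
# --------------------------------------------------------------------------

def _default_frame_shape(geometry: FOVGeometry) -> tuple[int, int]:
    if geometry.kind == LINEAR:
        rows = int(math.ceil(geometry.r_max)) + 1
        cols = int(math.ceil(geometry.apex[1] + geometry.width / 2.0)) + 1
    else:
        rows = int(math.ceil(geometry.apex[0] + geometry.r_max)) + 1
        cols = int(
            math.ceil(geometry.apex[1] + geometry.r_max * math.sin(geometry.theta0))
        ) + 1
    return rows, cols


def scan_convert(
    beam_image: np.ndarray,
    geometry: FOVGeometry,
    shape: Optional[tuple[int, int]] = None,
) -> UltrasoundImage:
    """Resample a beam-space grid (rows = depth, cols = beam angle) to
    Cartesian display coordinates under ``geometry``.

    In-FOV output pixels are bilinearly interpolated from beam space at the
    ``(r, theta)`` computed from the apex; pixels outside the rendered mask
    are 0.  For a linear geometry this reduces to placing the (resized) beam
    rectangle in the frame.
    """
    beam = np.asarray(beam_image, dtype=np.float64)
    if shape is None:
        shape = _default_frame_shape(geometry)
    mask = render_fov_mask(geometry, shape)
    pixels = np.zeros(shape, dtype=np.float64)

    rr, cc = np.nonzero(mask)
    if geometry.kind == LINEAR:
        half = geometry.width / 2.0
        i = (rr - geometry.r_min) / max(geometry.r_max - geometry.r_min, 1e-9)
        j = (cc - (geometry.apex[1] - half)) / max(geometry.width, 1e-9)
    else:
        r = np.hypot(rr - geometry.apex[0], cc - geometry.apex[1])
        theta = np.arctan2(cc - geometry.apex[1], rr - geometry.apex[0])
        i = (r - geometry.r_min) / max(geometry.r_max - geometry.r_min, 1e-9)
        j = (theta + geometry.theta0) / max(2.0 * geometry.theta0, 1e-9)
    coords = np.vstack(
        [i * (beam.shape[0] - 1), j * (beam.shape[1] - 1)]
    )
    pixels[rr, cc] = ndimage.map_coordinates(beam, coords, order=1, cval=0.0)
    np.clip(pixels, 0.0, 1.0, out=pixels)
    return UltrasoundImage(pixels=pixels, mask=mask, geometry=geometry)


def inverse_scan_convert(
    image: UltrasoundImage,
    n_theta: Optional[int] = None,
    n_r: Optional[int] = None,
) -> np.ndarray:
    """Resample a fan-geometry frame onto a regular ``(r, theta)`` lattice.

    Row count is ``round(r_max - r_min)`` (same depth resolution); the
    angular sample count defaults to the outer-arc length in pixels.  A
    linear input is returned as its in-FOV rectangle unchanged (no-op).
    """
    geometry = image.geometry
    if geometry is None:
        raise ParameterError("inverse scan conversion requires FOV geometry")
    if geometry.kind == LINEAR:
        r0 = int(round(geometry.r_min))
        r1 = int(round(geometry.r_max)) + 1
        c0 = int(round(geometry.apex[1] - geometry.width / 2.0))
        c1 = int(round(geometry.apex[1] + geometry.width / 2.0)) + 1
        r0, c0 = max(r0, 0), max(c0, 0)
        return image.pixels[r0:r1, c0:c1].copy()

    if n_r is None:
        n_r = max(int(round(geometry.r_max - geometry.r_min)), 2)
    if n_theta is None:
        n_theta = max(int(round(2.0 * geometry.theta0 * geometry.r_max)), 2)
    r = geometry.r_min + (geometry.r_max - geometry.r_min) * np.arange(n_r) / (n_r - 1)
    theta = -geometry.theta0 + 2.0 * geometry.theta0 * np.arange(n_theta) / (n_theta - 1)
    rg, tg = np.meshgrid(r, theta, indexing="ij")
    rows = geometry.apex[0] + rg * np.cos(tg)
    cols = geometry.apex[1] + rg * np.sin(tg)
    beam = ndimage.map_coordinates(
        image.pixels, np.vstack([rows.ravel(), cols.ravel()]), order=1, cval=0.0
    ).reshape(n_r, n_theta)
    return np.clip(beam, 0.0, 1.0)
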