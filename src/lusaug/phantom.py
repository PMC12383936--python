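"""Synthetic lung-ultrasound phantoms with ground-truth masks and labels.

The phantoms are schematic rather than physically simulated: their purpose
is to place the canonical lung-ultrasound findings at known locations so
that augmentation invariants and the ablation harness can be exercised with
ground truth.  Each frame is rendered in beam space (depth x beam angle) and
scan-converted under a linear or fan geometry, and contains

* multiplicative speckle texture, log-compressed to mimic B-mode dynamic
  range;
* a bright pleural line at a configurable fraction of the maximum depth;
* optional A-line reverberations — dimming replicas of the pleural line at
  integer multiples of the probe-pleura distance (normal aerated lung);
* optional B-line rays — bright paths from the pleural line to the outer
  arc (interstitial fluid);
* an optional anechoic (dark) pleural-effusion region.

Class labels: ``A`` (A-lines, no B-lines), ``B`` (at least one B-line),
``effusion``, ``normal``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ParameterError
from .geometry import CURVILINEAR, LINEAR, PHASED, FOVGeometry, scan_convert
from .image import UltrasoundImage
from .transforms.ultrasound import fan_geometry_for_frame

CLASSES = ("A", "B", "effusion", "normal")

#: log-compression gain mimicking B-mode dynamic range
LOG_GAIN = 20.0


@dataclass
class PhantomSpec:
    """Recipe for one phantom frame."""

    geometry: FOVGeometry
    pleural_depth: float = 0.35
    n_alines: int = 2
    n_blines: int = 0
    effusion: bool = False
    speckle_texture_sigma: float = 0.4
    label: str = "A"

    def __post_init__(self) -> None:
        if not 0.1 < self.pleural_depth < 0.6:
            raise ParameterError("pleural_depth must lie in (0.1, 0.6)")
        if self.n_alines < 0 or self.n_blines < 0:
            raise ParameterError("artifact counts must be nonnegative")
        if self.label not in CLASSES:
            raise ParameterError(f"label must be one of {CLASSES}")
        if self.label == "A" and self.n_blines != 0:
            raise ParameterError("label 'A' requires n_blines = 0")
        if self.label == "B" and self.n_blines < 1:
            raise ParameterError("label 'B' requires n_blines >= 1")


def _log_compress(x: np.ndarray) -> np.ndarray:
    return np.log1p(LOG_GAIN * np.clip(x, 0.0, None)) / math.log1p(LOG_GAIN)


def generate_phantom(
    spec: PhantomSpec,
    rng: np.random.Generator,
    shape: Optional[tuple[int, int]] = None,
) -> UltrasoundImage:
    """Render one phantom frame under ``spec.geometry``."""
    g = spec.geometry
    n_r = max(int(round(g.r_max - g.r_min)), 16)
    if g.kind == LINEAR:
        n_theta = max(int(round(g.width)), 16)
    else:
        n_theta = max(int(round(2.0 * g.theta0 * g.r_max)), 16)

    # radial coordinate of each beam row, as a fraction of r_max
    r_frac = (g.r_min + (g.r_max - g.r_min) * np.arange(n_r) / (n_r - 1)) / g.r_max

    # tissue background with mild depth attenuation
    base = 0.30 * (1.0 - 0.35 * r_frac)[:, None] * np.ones((n_r, n_theta))

    # pleural line: bright band at pleural_depth * r_max
    band_h = max(n_r // 40, 2)
    amp = 0.9

    def _band_rows(frac: float) -> slice | None:
        centre = (frac * g.r_max - g.r_min) / (g.r_max - g.r_min)
        if not 0.0 <= centre <= 1.0:
            return None
        i = int(round(centre * (n_r - 1)))
        return slice(max(i - band_h // 2, 0), min(i + band_h // 2 + 1, n_r))

    pleura = _band_rows(spec.pleural_depth)
    if pleura is not None:
        base[pleura, :] += amp

    # A-line reverberations at integer multiples of the probe-pleura distance
    for k in range(1, spec.n_alines + 1):
        rows = _band_rows(spec.pleural_depth * (k + 1))
        if rows is not None:
            base[rows, :] += amp * 0.35**k

    # B-line rays: bright fixed-angle columns from the pleura to max depth
    below = r_frac >= spec.pleural_depth
    ray_w = max(n_theta // 16, 2)
    for _ in range(spec.n_blines):
        j = int(rng.integers(ray_w, n_theta - ray_w))
        base[np.ix_(below, np.arange(j - ray_w, j + ray_w + 1))] += 0.8

    # pleural effusion: anechoic wedge below the pleural line
    if spec.effusion:
        j0 = int(rng.integers(0, max(n_theta // 2, 1)))
        j1 = min(j0 + max(n_theta // 3, 2), n_theta)
        deep = r_frac >= min(spec.pleural_depth + 0.08, 0.95)
        base[np.ix_(deep, np.arange(j0, j1))] = 0.02

    # multiplicative speckle, then log compression
    texture = 1.0 + spec.speckle_texture_sigma * rng.standard_normal((n_r, n_theta))
    beam = _log_compress(np.clip(base * np.clip(texture, 0.05, None), 0.0, None))
    beam = np.clip(beam, 0.0, 1.0)

    out = scan_convert(beam, g, shape=shape)
    out.class_label = spec.label
    return out


@dataclass
class PhantomDataset:
    """Generated frames plus a tabular manifest (patient/video/frame index)."""

    images: list[UltrasoundImage]
    manifest: pd.DataFrame

    def __len__(self) -> int:
        return len(self.images)


def random_geometry(
    rng: np.random.Generator, shape: tuple[int, int], kind: Optional[str] = None
) -> FOVGeometry:
    """Draw a plausible FOV geometry fitting ``shape``."""
    rows, cols = shape
    if kind is None:
        kind = rng.choice([LINEAR, CURVILINEAR, PHASED], p=[0.3, 0.5, 0.2])
    if kind == LINEAR:
        width = cols * rng.uniform(0.7, 0.95)
        top = rows * rng.uniform(0.0, 0.05)
        bottom = rows * rng.uniform(0.9, 1.0) - 1
        return FOVGeometry(
            kind=LINEAR,
            apex=(top, (cols - 1) / 2.0),
            theta0=0.0,
            r_min=top,
            r_max=bottom,
            width=width,
        )
    theta0 = rng.uniform(0.35, 0.6)
    inner = 0.02 if kind == PHASED else rng.uniform(0.2, 0.35)
    g = fan_geometry_for_frame(shape, theta0, inner_ratio=inner)
    if kind == PHASED:
        return FOVGeometry(
            kind=PHASED,
            apex=g.apex,
            theta0=g.theta0,
            r_min=g.r_min,
            r_max=g.r_max,
        )
    return g


def _spec_for_label(
    label: str, geometry: FOVGeometry, rng: np.random.Generator
) -> PhantomSpec:
    inner_frac = geometry.r_min / geometry.r_max
    lo = min(max(0.12, inner_frac + 0.05), 0.5)
    pleural_depth = float(rng.uniform(lo, min(lo + 0.15, 0.55)))
    common = dict(
        geometry=geometry,
        pleural_depth=pleural_depth,
        speckle_texture_sigma=float(rng.uniform(0.25, 0.4)),
        label=label,
    )
    if label == "A":
        return PhantomSpec(n_alines=int(rng.integers(2, 4)), n_blines=0, **common)
    if label == "B":
        return PhantomSpec(
            n_alines=0, n_blines=int(rng.integers(1, 4)), **common
        )
    if label == "effusion":
        return PhantomSpec(n_alines=0, n_blines=0, effusion=True, **common)
    return PhantomSpec(n_alines=0, n_blines=0, **common)


def generate_dataset(
    n_patients: int,
    videos_per_patient: int = 2,
    frames_per_video: int = 3,
    class_mix: Optional[dict[str, float]] = None,
    rng: int | np.random.Generator = 0,
    shape: tuple[int, int] = (128, 128),
) -> PhantomDataset:
    """Generate a patient/video/frame-structured phantom dataset.

    Each patient gets one FOV geometry; each video gets one class label and
    one phantom recipe, shared by all its frames (labels apply at the video
    level); frames differ in their speckle realisation.
    """
    if n_patients < 1 or videos_per_patient < 1 or frames_per_video < 1:
        raise ParameterError("counts must be >= 1")
    if class_mix is None:
        class_mix = {c: 0.25 for c in CLASSES}
    labels = list(class_mix)
    probs = np.array([class_mix[c] for c in labels], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-8:
        raise ParameterError("class_mix must sum to 1")
    if not set(labels) <= set(CLASSES):
        raise ParameterError(f"class_mix keys must be among {CLASSES}")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))

    images: list[UltrasoundImage] = []
    records: list[dict] = []
    for p in range(n_patients):
        patient_id = f"P{p:04d}"
        geometry = random_geometry(rng, shape)
        for v in range(videos_per_patient):
            label = str(rng.choice(labels, p=probs))
            spec = _spec_for_label(label, geometry, rng)
            for f in range(frames_per_video):
                img = generate_phantom(spec, rng, shape=shape)
                img.patient_id = patient_id
                img.meta.update(video=v, frame=f)
                images.append(img)
                records.append(
                    {
                        "patient_id": patient_id,
                        "video_id": f"{patient_id}_V{v}",
                        "frame": f,
                        "label": label,
                        "fov_kind": geometry.kind,
                    }
                )
    return PhantomDataset(images=images, manifest=pd.DataFrame(records))
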