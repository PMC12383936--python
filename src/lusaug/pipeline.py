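"""Augmentation pipelines and positive-pair generation.

A pipeline is an ordered sequence of transforms, each applied with an
independent Bernoulli probability, followed by a final resize to the
encoder's input resolution (128x128 by default).  Three builtin pipelines
ship with the package:

* ``standard_aug`` — the baseline used across imaging domains:
  crop-and-resize (p=1.0), horizontal reflection (0.5), colour jitter (0.8),
  grayscale (0.2), Gaussian blur (0.5), solarization (0.1);
* ``aug_us_o`` — the twelve ultrasound-specific, semantics-preserving
  transforms B00-B11 with their published probabilities;
* ``aug_us_d`` — the distilled pipeline [B03, A02, B11, A00], containing
  exactly the transforms whose omission significantly lowered downstream
  performance, each keeping its source pipeline's probability.

Randomness contract: all draws derive from one master seed.  Per-transform
sub-streams are seeded from ``(seed, image_index, view_index, transform id)``
so that removing one transform from a pipeline does not shift any other
transform's draws, and the Bernoulli gate is drawn from a separate stream so
skipped transforms consume no randomness.  This keeps leave-one-out
comparisons maximally paired.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .errors import ParameterError
from .image import UltrasoundImage
from .transforms import Transform, get_transform
from .transforms.standard import DEFAULT_OUT_SIZE, resize_image

BUILTIN_NAMES = ("standard_aug", "aug_us_o", "aug_us_d")


@dataclass(frozen=True)
class TransformSpec:
    """One pipeline entry: transform id, application probability, overrides."""

    id: str
    probability: float
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ParameterError(f"probability {self.probability} outside [0, 1]")

    def build(self) -> Transform:
        return get_transform(self.id, **self.params)


@dataclass
class AugmentationPipeline:
    """An ordered, probabilistic sequence of transforms plus a final resize."""

    name: str
    specs: list[TransformSpec]
    out_size: tuple[int, int] = DEFAULT_OUT_SIZE

    def __post_init__(self) -> None:
        ids = [s.id for s in self.specs]
        if len(set(ids)) != len(ids):
            raise ParameterError(f"duplicate transform ids in pipeline {self.name!r}")
        self._transforms = {s.id: s.build() for s in self.specs}

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.specs]

    def transform(self, transform_id: str) -> Transform:
        return self._transforms[transform_id]

    def spec(self, transform_id: str) -> TransformSpec:
        for s in self.specs:
            if s.id == transform_id:
                return s
        raise ParameterError(f"transform {transform_id!r} not in pipeline {self.name!r}")

    # ------------------------------------------------------------- config IO
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "out_size": list(self.out_size),
            "transforms": [
                {"id": s.id, "probability": s.probability, "params": dict(s.params)}
                for s in self.specs
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AugmentationPipeline":
        specs = [
            TransformSpec(
                id=t["id"],
                probability=float(t["probability"]),
                params=dict(t.get("params") or {}),
            )
            for t in d["transforms"]
        ]
        out_size = tuple(d.get("out_size", DEFAULT_OUT_SIZE))
        return cls(name=d["name"], specs=specs, out_size=out_size)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "AugmentationPipeline":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def builtin_pipeline(name: str) -> AugmentationPipeline:
    """Load one of the three packaged pipelines by name."""
    if name not in BUILTIN_NAMES:
        raise ParameterError(
            f"unknown pipeline {name!r}; expected one of {BUILTIN_NAMES}"
        )
    ref = importlib.resources.files("lusaug") / "configs" / f"{name}.yaml"
    return AugmentationPipeline.from_dict(yaml.safe_load(ref.read_text()))


def ablate(pipeline: AugmentationPipeline, omit_id: str) -> AugmentationPipeline:
    """A copy of ``pipeline`` with one transform omitted (order preserved)."""
    if omit_id not in pipeline.ids:
        raise ParameterError(f"transform {omit_id!r} not in pipeline {pipeline.name!r}")
    return AugmentationPipeline(
        name=f"{pipeline.name}-minus-{omit_id}",
        specs=[s for s in pipeline.specs if s.id != omit_id],
        out_size=pipeline.out_size,
    )


# --------------------------------------------------------------------------
# Seeding
# --------------------------------------------------------------------------

def _tid_int(transform_id: str) -> int:
    return (ord(transform_id[0]) - ord("A")) * 100 + int(transform_id[1:])


def _stream(
    seed: int, image_index: int, view_index: int, transform_id: str, role: int
) -> np.random.Generator:
    ss = np.random.SeedSequence(
        [int(seed), int(image_index), int(view_index), _tid_int(transform_id), role]
    )
    return np.random.default_rng(ss)


def _coerce_seed(rng) -> int:
    if isinstance(rng, (int, np.integer)):
        return int(rng)
    if isinstance(rng, np.random.Generator):
        return int(rng.integers(0, 2**31))
    raise ParameterError("rng must be an integer seed or a numpy Generator")


# --------------------------------------------------------------------------
# Application
# --------------------------------------------------------------------------

def apply_pipeline(
    image: UltrasoundImage,
    pipeline: AugmentationPipeline,
    rng: int | np.random.Generator,
    image_index: int = 0,
    view_index: int = 0,
) -> tuple[UltrasoundImage, list[dict]]:
    """Run a pipeline once and return ``(view, provenance)``.

    Each transform's Bernoulli gate and parameters come from sub-streams
    keyed on the master seed and the transform's identity; provenance is the
    ordered list of ``{"id", "params"}`` for the transforms that fired.
    """
    seed = _coerce_seed(rng)
    out = image
    provenance: list[dict] = []
    for spec in pipeline.specs:
        gate = _stream(seed, image_index, view_index, spec.id, 0)
        if gate.random() >= spec.probability:
            continue
        t = pipeline.transform(spec.id)
        prng = _stream(seed, image_index, view_index, spec.id, 1)
        try:
            params = t.sample_params(out, prng)
            out = t.apply(out, **params)
        except Exception as exc:
            raise type(exc)(f"[{spec.id}] {exc}") from exc
        provenance.append({"id": spec.id, "params": params})
    out = resize_image(out, pipeline.out_size)
    return out, provenance


def replay(
    image: UltrasoundImage,
    pipeline: AugmentationPipeline,
    provenance: Sequence[dict],
) -> UltrasoundImage:
    """Re-apply logged transforms with logged parameters (bit-exact)."""
    out = image
    for entry in provenance:
        t = pipeline.transform(entry["id"])
        out = t.apply(out, **entry["params"])
    return resize_image(out, pipeline.out_size)


@dataclass
class PositivePair:
    """Two augmented views of the same source frame, with provenance."""

    view_a: UltrasoundImage
    view_b: UltrasoundImage
    provenance_a: list[dict]
    provenance_b: list[dict]


def positive_pair(
    image: UltrasoundImage,
    pipeline: AugmentationPipeline,
    rng: int | np.random.Generator,
    image_index: int = 0,
) -> PositivePair:
    """Two independent pipeline draws on the same source image."""
    seed = _coerce_seed(rng)
    view_a, prov_a = apply_pipeline(image, pipeline, seed, image_index, view_index=0)
    view_b, prov_b = apply_pipeline(image, pipeline, seed, image_index, view_index=1)
    return PositivePair(view_a, view_b, prov_a, prov_b)
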