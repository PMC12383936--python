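"""Stochastic, seedable image transforms.

Every transform is a small class with two halves:

* ``sample_params(image, rng)`` draws all randomness for one invocation and
  returns it as a JSON-serialisable dict (noise transforms return a sub-seed
  rather than the noise field itself);
* ``apply(image, **params)`` is fully deterministic given those parameters.

Calling the transform performs both steps and returns ``(output, params)``,
which is what pipeline provenance records — replaying ``apply`` with logged
parameters reproduces a view bit-exactly.

Transforms are registered under their alphanumeric identifiers ("A00" ...
"B11"); :func:`get_transform` instantiates one with parameter overrides.
"""

from __future__ import annotations

from typing import Callable, Type

import numpy as np

from ..errors import ParameterError
from ..image import UltrasoundImage

_REGISTRY: dict[str, Type["Transform"]] = {}


def register(cls: Type["Transform"]) -> Type["Transform"]:
    if not cls.id:
        raise ParameterError(f"{cls.__name__} has no transform id")
    _REGISTRY[cls.id] = cls
    return cls


def registered_ids() -> list[str]:
    return sorted(_REGISTRY)


def get_transform(transform_id: str, **overrides) -> "Transform":
    """Instantiate a registered transform with parameter overrides."""
    try:
        cls = _REGISTRY[transform_id]
    except KeyError:
        raise ParameterError(f"unknown transform id {transform_id!r}") from None
    return cls(**overrides)


class Transform:
    """Base class: a stochastic operator on :class:`UltrasoundImage`."""

    id: str = ""
    name: str = ""
    requires_geometry: bool = False

    def sample_params(self, image: UltrasoundImage, rng: np.random.Generator) -> dict:
        return {}

    def apply(self, image: UltrasoundImage, **params) -> UltrasoundImage:
        raise NotImplementedError

    def __call__(
        self, image: UltrasoundImage, rng: np.random.Generator
    ) -> tuple[UltrasoundImage, dict]:
        params = self.sample_params(image, rng)
        return self.apply(image, **params), params

    def __repr__(self) -> str:  # pragma: no cover
        return f"<{type(self).__name__} {self.id}>"


# ---------------------------------------------------------------- helpers

def rezero(image: UltrasoundImage) -> UltrasoundImage:
    """Enforce the preprocessed-ultrasound invariant: background exactly 0."""
    image.pixels = image.pixels * image.mask
    return image


def clip01(pixels: np.ndarray) -> np.ndarray:
    return np.clip(pixels, 0.0, 1.0)


def sub_seed(rng: np.random.Generator) -> int:
    """Draw a reproducible 31-bit sub-seed for a regenerable noise field."""
    return int(rng.integers(0, 2**31))


from . import standard, ultrasound  # noqa: E402,F401  (registers A00..B11)
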