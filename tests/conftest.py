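"""Shared fixtures: small phantoms at each FOV shape, generated at test time."""

import numpy as np
import pytest

from lusaug import FOVGeometry, UltrasoundImage, generate_phantom
from lusaug.phantom import PhantomSpec
from lusaug.transforms.ultrasound import fan_geometry_for_frame


@pytest.fixture(scope="session")
def linear_geometry():
    return FOVGeometry(
        kind="linear", apex=(0.0, 31.5), theta0=0.0, r_min=0.0, r_max=63.0, width=56.0
    )


@pytest.fixture(scope="session")
def fan_geometry():
    return fan_geometry_for_frame((64, 64), theta0=0.45, inner_ratio=0.3)


@pytest.fixture()
def linear_phantom(linear_geometry):
    spec = PhantomSpec(
        geometry=linear_geometry, pleural_depth=0.3, n_alines=2, label="A"
    )
    return generate_phantom(spec, np.random.default_rng(11), shape=(64, 64))


@pytest.fixture()
def fan_phantom(fan_geometry):
    spec = PhantomSpec(
        geometry=fan_geometry, pleural_depth=0.4, n_alines=0, n_blines=2, label="B"
    )
    return generate_phantom(spec, np.random.default_rng(12), shape=(64, 64))


@pytest.fixture()
def flat_image():
    """A constant mid-gray frame with a full mask."""
    return UltrasoundImage(pixels=np.full((64, 64), 0.5))
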