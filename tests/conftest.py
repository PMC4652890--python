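"""Shared fixtures: small textures, arenas and a prebuilt eye.

Everything is generated programmatically with fixed seeds; session scope
amortizes scene compilation across tests.
"""

import numpy as np
import pytest

from comanav.environments import (make_cubic_box, make_random_checkerboard,
                                  Texture)
from comanav.retina import Eye, RetinaGeometry


@pytest.fixture(scope="session")
def geometry() -> RetinaGeometry:
    return RetinaGeometry()


@pytest.fixture(scope="session")
def checker_box():
    """40 cm cubic box with a 1 mm random checkerboard on the walls."""
    tex = make_random_checkerboard(1.0, (400.0, 400.0), seed=7)
    return make_cubic_box(wall_texture=tex, seed=7)


@pytest.fixture(scope="session")
def checker_box_eye(checker_box, geometry) -> Eye:
    return Eye(checker_box, geometry, supersample=2)


@pytest.fixture(scope="session")
def uniform_box():
    """Closed box with every surface at constant brightness 0.7."""
    tex = Texture(grid=np.full((4, 4), 0.7), texel_size_mm=100.0, kind="image")
    return make_cubic_box(wall_texture=tex, floor_texture=tex,
                          ceiling_texture=tex)
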