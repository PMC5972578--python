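import numpy as np
import pytest

from endograd import synthgrain
from endograd.imgio import EndospermMask, mask_from_polygon
from endograd.mlclassify import ProteinMask


@pytest.fixture(scope="session")
def small_scene():
    """One reduced-canvas synthetic section shared across tests."""
    config = synthgrain.small_config(seed=11)
    image, mask, truth = synthgrain.generate_section(config)
    return config, image, mask, truth


@pytest.fixture(scope="session")
def disc_mask():
    """Filled disc of radius 50 px on a 120x120 canvas."""
    angles = np.linspace(0, 2 * np.pi, 256, endpoint=False)
    verts = np.column_stack([60 + 50 * np.sin(angles), 60 + 50 * np.cos(angles)])
    return mask_from_polygon(verts, (120, 120))


def square_mask(side: int = 20, origin: int = 5, canvas: int = 32) -> EndospermMask:
    verts = np.array([[origin, origin], [origin, origin + side],
                      [origin + side, origin + side], [origin + side, origin]],
                     dtype=float)
    return mask_from_polygon(verts, (canvas, canvas))


def full_protein(mask: EndospermMask, replicate_id: int = 1) -> ProteinMask:
    return ProteinMask(protein=mask.region.copy(), replicate_id=replicate_id)
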