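import numpy as np
import pytest

from physatrack import make_arena
from physatrack.labels import Label
from physatrack.segmentation import TrinarizedFrame


def disc_mask(shape, center, radius):
    rows, cols = np.ogrid[: shape[0], : shape[1]]
    return (rows - center[0]) ** 2 + (cols - center[1]) ** 2 <= radius**2


@pytest.fixture
def small_arena():
    """64x64 arena, radius 28 px, 56 mm diameter -> mm_per_px = 1."""
    return make_arena((31.5, 31.5), 28, 56.0, (64, 64))


def trin_frame(arena, slime=None, mucus=None, index=0):
    """Build a TrinarizedFrame from explicit class masks (restricted to the arena)."""
    labels = np.zeros(arena.mask.shape, dtype=np.uint8)
    if slime is not None:
        labels[np.asarray(slime, bool) & arena.mask] = Label.SLIME
    if mucus is not None:
        labels[np.asarray(mucus, bool) & arena.mask & (labels == 0)] = Label.MUCUS
    return TrinarizedFrame(labels, index, arena)
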