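import numpy as np
import pytest

from gazefuse.backends import DetectedBox, SemanticSegmentation
from gazefuse.gaze_io import VideoMeta


@pytest.fixture
def meta_30fps():
    return VideoMeta(width=192, height=128, fps=30.0, duration=10.0)


@pytest.fixture
def simple_seg():
    """A 'car' rectangle [20,60) x [30,70) on a 'road' background, 100x100."""
    label_map = np.zeros((100, 100), dtype=np.int32)
    label_map[30:70, 20:60] = 1
    return SemanticSegmentation(label_map=label_map, vocabulary={0: "road", 1: "car"})


def random_mask_and_box(rng, size=64):
    """A random boolean mask plus a random valid box within a size x size frame."""
    from gazefuse.fusion import BinaryMask

    density = rng.uniform(0.05, 0.9)
    pixels = rng.random((size, size)) < density
    if not pixels.any():
        pixels[rng.integers(size), rng.integers(size)] = True
    x1 = int(rng.integers(0, size - 1))
    y1 = int(rng.integers(0, size - 1))
    x2 = int(rng.integers(x1 + 1, size + 1))
    y2 = int(rng.integers(y1 + 1, size + 1))
    mask = BinaryMask(pixels=pixels, source_label="car", component_mode="class")
    box = DetectedBox(x1, y1, x2, y2, label="car", confidence=float(rng.uniform(0, 1)))
    return mask, box
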