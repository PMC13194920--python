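import numpy as np
import pytest

from rodmorph.io import LabelMask


@pytest.fixture
def pixel_size():
    return 0.065


@pytest.fixture
def rod_mask():
    """Axis-aligned 3x11 rectangle instance inside background."""
    labels = np.zeros((9, 17), dtype=np.int64)
    labels[3:6, 3:14] = 1
    return LabelMask(labels=labels, pixel_size=1.0)


@pytest.fixture
def two_instance_mask():
    """One border-touching instance, one interior instance."""
    labels = np.zeros((12, 12), dtype=np.int64)
    labels[0:3, 4:8] = 5     # touches top row
    labels[6:9, 4:8] = 9     # interior
    return LabelMask(labels=labels, pixel_size=1.0)


def random_label_mask(rng, shape=(24, 24), n_cells=3):
    """Small random instance mask: non-overlapping rectangles."""
    labels = np.zeros(shape, dtype=np.int64)
    for k in range(n_cells):
        h = rng.integers(2, 6)
        w = rng.integers(2, 6)
        for _ in range(50):
            r = rng.integers(0, shape[0] - h)
            c = rng.integers(0, shape[1] - w)
            if not labels[r:r + h, c:c + w].any():
                labels[r:r + h, c:c + w] = k + 1
                break
    return LabelMask(labels=labels, pixel_size=1.0)
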