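import numpy as np
import pytest

from gliomaseg.labels import LabelMap


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_label_map(rng: np.random.Generator, h: int = 16, w: int = 16) -> LabelMap:
    """A random valid BRATS label map (background-weighted)."""
    vals = rng.choice([0, 0, 0, 1, 2, 4], size=(h, w))
    return LabelMap(vals)
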