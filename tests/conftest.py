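import numpy as np
import pytest

from cribnet.labels import LabelSet
from cribnet.preprocess import tile
from cribnet.synthesis import desk_config, generate_biopsy


@pytest.fixture(scope="session")
def labelset() -> LabelSet:
    return LabelSet()


@pytest.fixture(scope="session")
def synthetic_biopsy(labelset):
    """One desk-scale biopsy containing both cribriform and fused glands."""
    return generate_biopsy(desk_config(seed=5), labelset)


@pytest.fixture(scope="session")
def tiled_biopsy(synthetic_biopsy):
    samples, report = tile(synthetic_biopsy.image, synthetic_biopsy.masks,
                           patch=256, stride=128, pool_factor=4)
    return samples, report


def one_hot_from_labelmap(labelmap: np.ndarray, n_classes: int = 7) -> np.ndarray:
    out = np.zeros((n_classes,) + labelmap.shape, dtype=np.uint8)
    for l in range(n_classes):
        out[l] = labelmap == l
    return out
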