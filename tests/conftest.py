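import numpy as np
import pytest

from phca import (
    BlobSpec,
    LabelledDataset,
    PointCloud,
    make_gaussian_classes,
)


def diagram_multiset(diagram, drop_zero=False, decimals=9):
    """Rows of a diagram as a sorted list of rounded (dim, birth, death)."""
    rows = [
        (int(d), round(b, decimals), round(dt, decimals))
        for d, b, dt, _ in diagram.rows()
        if not (drop_zero and abs(dt - b) <= 10 ** -decimals)
    ]
    return sorted(rows)


@pytest.fixture
def unit_square():
    return PointCloud.from_coords([(0, 0), (1, 0), (0, 1), (1, 1)])


@pytest.fixture
def two_class_line():
    """Two 1-d classes A={0,3}, B={10,13}."""
    return LabelledDataset.from_arrays(
        np.array([[0.0], [3.0], [10.0], [13.0]]),
        np.array(["A", "A", "B", "B"]),
    )


@pytest.fixture
def separable_blobs():
    return make_gaussian_classes(BlobSpec(n_classes=3, sizes=50, seed=7))


def random_cloud(seed, n=None, dim=None):
    rng = np.random.default_rng(seed)
    n = n or int(rng.integers(2, 9))
    dim = dim or int(rng.integers(1, 4))
    return PointCloud(rng.normal(size=(n, dim)))
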