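import numpy as np
import pytest

from semnf.rsa import AnchorSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def anchors4():
    """Deterministic 4-state anchor set with realistic correlation structure."""
    from semnf.synthetic import make_anchors
    anchors, _ = make_anchors(n_cond=4, voxel_count=300, seed=11)
    return anchors


def planted_configuration(n: int, dims: int, seed: int, voxels: int | None = None):
    """A random dims-D point configuration embedded isometrically into voxel
    space, so Euclidean pattern distances equal the planted point distances.

    Returns (planted points, AnchorSet of matching patterns).
    """
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, dims))
    V = voxels or dims + 1
    assert V > dims
    Q, _ = np.linalg.qr(rng.standard_normal((V, V)))
    P = X @ Q[:, :dims].T
    # guard the zero-variance AnchorSet invariant (probability-zero event)
    assert np.all(P.std(axis=1) > 0)
    labels = tuple(f"s{i}" for i in range(n))
    return X, AnchorSet(labels=labels, patterns=P)
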