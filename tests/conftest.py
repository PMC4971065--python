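import numpy as np
import pytest

from microstate_rsn import Montage, builtin_montage


@pytest.fixture(scope="session")
def montage64():
    return builtin_montage("standard-10-20-64")


@pytest.fixture()
def ring8():
    """Small 8-channel circular montage for cheap tests."""
    ang = np.linspace(0, 2 * np.pi, 8, endpoint=False)
    pos = np.column_stack([np.cos(ang), np.sin(ang)])
    return Montage(tuple(f"ch{i}" for i in range(8)), pos)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def orthonormal_templates(K: int, C: int, rng: np.random.Generator) -> np.ndarray:
    """Random average-referenced, mutually orthogonal unit-norm maps."""
    X = rng.normal(size=(C, C))
    X -= X.mean(axis=0)
    Q, _ = np.linalg.qr(X)
    # columns of Q orthonormal; re-center (centered input keeps them near-centered)
    T = Q[:, :K].T
    T -= T.mean(axis=1, keepdims=True)
    T /= np.linalg.norm(T, axis=1, keepdims=True)
    return T
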