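import numpy as np
import pytest

import gradmap as gm


@pytest.fixture(scope="session")
def icosphere_162():
    return gm.make_icosphere(subdivisions=2)


@pytest.fixture(scope="session")
def icosphere_642():
    return gm.make_icosphere(subdivisions=3)


@pytest.fixture(scope="session")
def weights_162(icosphere_162):
    return gm.build_spatial_weights(icosphere_162)


@pytest.fixture(scope="session")
def moran_basis_162(weights_162):
    return gm.moran_basis(weights_162)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tetrahedron():
    """Regular tetrahedron with unit edge length."""
    verts = np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
    ) / np.sqrt(8)
    faces = np.array([[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]])
    return gm.TriangleMesh(vertices=verts, faces=faces)


def brute_force_morans_i(u: np.ndarray, W: np.ndarray) -> float:
    """Independent double-loop Moran's I oracle."""
    u = np.asarray(u, dtype=float)
    l = u.size
    ubar = u.mean()
    num = 0.0
    s0 = 0.0
    for i in range(l):
        for j in range(l):
            num += W[i, j] * (u[i] - ubar) * (u[j] - ubar)
            s0 += W[i, j]
    return (l / s0) * num / np.sum((u - ubar) ** 2)
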