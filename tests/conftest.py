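import numpy as np
import pytest

from cellmech.mesh import TriMesh, build_sphere_mesh, update_differentials


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_sphere():
    """42-node icosphere of radius 1 µm."""
    return build_sphere_mesh(1000.0, 42)


@pytest.fixture
def perturbed_sphere(rng):
    """42-node sphere with ~3% random node displacement (non-equilibrium)."""
    m = build_sphere_mesh(1000.0, 42)
    m.positions = m.positions + rng.normal(0.0, 30.0, m.positions.shape)
    update_differentials(m)
    return m


@pytest.fixture
def flat_patch():
    """Two coplanar unit triangles in the z = 0 plane (1 µm square)."""
    verts = 1000.0 * np.array(
        [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)
    tris = np.array([[0, 1, 2], [0, 2, 3]])
    return TriMesh(verts, tris)
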