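"""Shared fixtures: small meshes, synthetic geometry, and record sets."""
import numpy as np
import pytest

from woundmap.meshing import TriangleMesh


@pytest.fixture
def rng():
    # function-scoped: every test sees the same fresh, seeded generator,
    # independent of execution order
    return np.random.default_rng(12345)


def grid_mesh(nx, ny, spacing=1.0, height=None):
    """Regular planar (or height-field) triangle grid used across tests."""
    xs, ys = np.meshgrid(np.arange(nx) * spacing, np.arange(ny) * spacing)
    z = np.zeros_like(xs) if height is None else height(xs, ys)
    V = np.column_stack([xs.ravel(), ys.ravel(), z.ravel()])
    tris = []
    for j in range(ny - 1):
        for i in range(nx - 1):
            a = j * nx + i
            tris.append((a, a + 1, a + nx + 1))
            tris.append((a, a + nx + 1, a + nx))
    return TriangleMesh(V, np.array(tris))


def cylinder_mesh(radius=4.0, arc=1.6, length=6.0, n=40):
    """Developable cylinder patch mesh: arc (radians) by length, arc-length
    parameterized so its exact area is arc * radius * length."""
    def height(xs, ys):
        return radius * (np.cos(xs / radius) - 1.0)
    nx = n
    ny = n
    sp_x = arc * radius / (nx - 1)
    sp_y = length / (ny - 1)
    xs, ys = np.meshgrid(np.linspace(-arc * radius / 2, arc * radius / 2, nx),
                         np.linspace(0, length, ny))
    V = np.column_stack([radius * np.sin(xs.ravel() / radius), ys.ravel(),
                         radius * (np.cos(xs.ravel() / radius) - 1.0)])
    tris = []
    for j in range(ny - 1):
        for i in range(nx - 1):
            a = j * nx + i
            tris.append((a, a + 1, a + nx + 1))
            tris.append((a, a + nx + 1, a + nx))
    del sp_x, sp_y
    return TriangleMesh(V, np.array(tris)), arc * radius * length


@pytest.fixture
def square_mesh():
    return grid_mesh(2, 2)


@pytest.fixture(scope="session")
def clinical_records():
    from woundmap.evaluation import load_clinical_dataset
    return load_clinical_dataset()
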