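"""Shared fixtures: small synthetic specimens generated once per session."""

import numpy as np
import pytest

from talusmorph import generate_cylinder_patch, generate_trochlea
from talusmorph.mesh_io import SurfaceMesh
from talusmorph.synthetic import TrochleaSpec, preset_spec


@pytest.fixture(scope="session")
def tetrahedron():
    vertices = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
    faces = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return SurfaceMesh(vertices, faces, "tetra")


@pytest.fixture(scope="session")
def unit_cube_mesh():
    import trimesh

    box = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    return SurfaceMesh(np.asarray(box.vertices), np.asarray(box.faces), "cube")


@pytest.fixture(scope="session")
def cylinder_patch():
    """Radius-20 cylinder patch plus ground truth (the exact oracle)."""
    return generate_cylinder_patch(20.0, grid=257)


@pytest.fixture(scope="session")
def asym_spec():
    return preset_spec("asymmetric")


@pytest.fixture(scope="session")
def asym_trochlea(asym_spec):
    """Noise-free asymmetric trochlea at the full validation grid (200x200)."""
    return generate_trochlea(asym_spec)


@pytest.fixture(scope="session")
def small_trochlea():
    """Coarse trochlea for fast tests where sub-percent accuracy is not needed."""
    spec = preset_spec("asymmetric", grid_nx=64, grid_ny=64)
    return generate_trochlea(spec)
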