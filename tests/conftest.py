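"""Shared fixtures: analytic meshes, synthetic knees and a small cohort run.

Everything is generated programmatically; session scope keeps the expensive
objects (marching-cubes meshes, the cohort grid) built once.
"""

import numpy as np
import pytest

from kneedrill.landmarks import compute_landmarks
from kneedrill.mesh import SurfaceMesh
from kneedrill.synthetic import KneeParams, _ellipsoid, _mesh_from_implicit, generate_knee, sample_cohort
from kneedrill.pipeline import run_grid

SPHERE_RADIUS = 20.0
SPHERE_PITCH = 0.75


def make_box(center=(0.0, 0.0, 0.0), half=(0.5, 0.5, 0.5)) -> SurfaceMesh:
    """Exact 12-triangle axis-aligned box."""
    c = np.asarray(center, float)
    h = np.asarray(half, float)
    corners = np.array([[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)],
                       dtype=float)
    verts = c + corners * h
    # faces indexed into the (sx, sy, sz) corner ordering above
    quads = [
        (0, 1, 3, 2),  # -x
        (4, 6, 7, 5),  # +x
        (0, 4, 5, 1),  # -y
        (2, 3, 7, 6),  # +y
        (0, 2, 6, 4),  # -z
        (1, 5, 7, 3),  # +z
    ]
    faces = []
    for a, b, cc, d in quads:
        faces += [(a, b, cc), (a, cc, d)]
    return SurfaceMesh(verts, np.asarray(faces), validate=True)


@pytest.fixture(scope="session")
def unit_cube() -> SurfaceMesh:
    return make_box()


@pytest.fixture(scope="session")
def sphere_mesh() -> SurfaceMesh:
    """Marching-cubes sphere of radius 20 mm at 0.75 mm pitch."""
    f = _ellipsoid((0.0, 0.0, 0.0), (SPHERE_RADIUS,) * 3)
    return _mesh_from_implicit(f, (-SPHERE_RADIUS,) * 3, (SPHERE_RADIUS,) * 3, SPHERE_PITCH)


@pytest.fixture(scope="session")
def knee():
    return generate_knee(KneeParams(), seed=1)


@pytest.fixture(scope="session")
def knee_landmarks(knee):
    return compute_landmarks(knee.femur, knee.tibia)


@pytest.fixture(scope="session")
def cohort10():
    """The default seeded synthetic cohort (n=10, seed 42)."""
    return sample_cohort(10, seed=42)


@pytest.fixture(scope="session")
def grid_results(cohort10):
    """Full 4x3 condition grid over the default cohort."""
    return run_grid(cohort10)
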