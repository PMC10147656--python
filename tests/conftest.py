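"""Shared fixtures: probe contexts, reference simulations, synthetic meshes.

All fixtures are generated programmatically at test time; there are no
stored data files. Seeds are fixed so the suite is deterministic.
"""
from __future__ import annotations

import numpy as np
import pytest

from microrheo.core import ProbeContext, water_context
from microrheo.mapping import SurfaceMesh
from microrheo.simulate import TrapParams, simulate_trapped_bead

#: Trap stiffnesses of the reference instrument configuration (N/m).
KAPPA_X = 3.2e-7
KAPPA_Y = 3.2e-7
KAPPA_Z = 6.7e-8


@pytest.fixture(scope="session")
def ctx() -> ProbeContext:
    """6 µm polystyrene bead (a = 3 µm) in water at 25 °C."""
    return water_context()


@pytest.fixture(scope="session")
def trap() -> TrapParams:
    return TrapParams(KAPPA_X, KAPPA_Y, KAPPA_Z)


@pytest.fixture(scope="session")
def ou_trajectory(ctx, trap):
    """Reference trapped-bead record: 3×10^5 frames at 300 Hz, 3 axes."""
    return simulate_trapped_bead(ctx, trap, dt=1 / 300.0, n_steps=300_000, seed=101)


def latlong_sphere(radius: float, n_lat: int = 20,
                   centre=(0.0, 0.0, 0.0)) -> SurfaceMesh:
    """Triangulated lat-long sphere used as a synthetic cell-cluster surface."""
    th = np.linspace(0.0, np.pi, n_lat)
    ph = np.linspace(0.0, 2 * np.pi, 2 * n_lat, endpoint=False)
    verts = []
    index = {}
    for i, t in enumerate(th):
        for j, p in enumerate(ph):
            index[(i, j)] = len(verts)
            verts.append([radius * np.sin(t) * np.cos(p) + centre[0],
                          radius * np.sin(t) * np.sin(p) + centre[1],
                          radius * np.cos(t) + centre[2]])
    faces = []
    for i in range(n_lat - 1):
        for j in range(2 * n_lat):
            j2 = (j + 1) % (2 * n_lat)
            faces.append([index[(i, j)], index[(i + 1, j)], index[(i + 1, j2)]])
            faces.append([index[(i, j)], index[(i + 1, j2)], index[(i, j2)]])
    return SurfaceMesh(vertices=np.array(verts), faces=np.array(faces))


@pytest.fixture(scope="session")
def sphere_mesh() -> SurfaceMesh:
    """Unit-radius synthetic sphere mesh (stand-in for a segmented cluster)."""
    return latlong_sphere(1.0, n_lat=24)
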