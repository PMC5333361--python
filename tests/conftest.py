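from __future__ import annotations

import numpy as np
import pytest
import trimesh

from cardax.io_formats import SurfaceMesh
from cardax.polarity_stats import BootstrapThresholdTable, mesh_geodesic_distances


@pytest.fixture(scope="session")
def unit_sphere() -> SurfaceMesh:
    """Unit icosphere (162 vertices), the spherical template for region scans."""
    return SurfaceMesh.from_trimesh(trimesh.creation.icosphere(subdivisions=2, radius=1.0))


@pytest.fixture(scope="session")
def sphere_geodesic(unit_sphere) -> np.ndarray:
    return mesh_geodesic_distances(unit_sphere)


@pytest.fixture(scope="session")
def flat_mesh() -> SurfaceMesh:
    """Triangulated 100×100 μm square in the z = 0 plane (normal +z)."""
    m = 10
    xs = np.linspace(0.0, 100.0, m + 1)
    xx, yy = np.meshgrid(xs, xs, indexing="ij")
    verts = np.stack([xx.ravel(), yy.ravel(), np.zeros((m + 1) ** 2)], axis=1)
    faces = []
    for i in range(m):
        for j in range(m):
            v00 = i * (m + 1) + j
            v10 = (i + 1) * (m + 1) + j
            faces.append([v00, v10, v00 + 1])
            faces.append([v10, v10 + 1, v00 + 1])
    return SurfaceMesh(verts, np.array(faces))


@pytest.fixture(scope="session")
def threshold_table() -> BootstrapThresholdTable:
    """Shared E1(5%) table (modest replicate count keeps the suite fast)."""
    return BootstrapThresholdTable(B=3000, seed=11)
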