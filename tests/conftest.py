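"""Shared fixtures: surfaces are computed once per session at study defaults."""

import numpy as np
import pytest

import arealaw as al
from arealaw.workbench import compute_mesh


@pytest.fixture(scope="session")
def default_config():
    return al.PipelineConfig()


@pytest.fixture(scope="session")
def sphere_structure():
    """Single hydrogen atom: its isosurface is exactly the 1.1 Å vdW sphere."""
    return al.make_fixture(al.FixtureSpec(kind="single_sphere", radius=1.1))


@pytest.fixture(scope="session")
def sphere_mesh(sphere_structure, default_config):
    return compute_mesh(sphere_structure, default_config)


@pytest.fixture(scope="session")
def benzene_structure():
    return al.embed_from_smiles("c1ccccc1", seed=2024, mol_id="benzene")


@pytest.fixture(scope="session")
def benzene_mesh(benzene_structure, default_config):
    return compute_mesh(benzene_structure, default_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_density_field(rng, n_atoms=None):
    """Random multi-atom field for derivative and invariance checks."""
    n = int(n_atoms or rng.integers(2, 7))
    positions = rng.uniform(-2.0, 2.0, size=(n, 3))
    radii = rng.uniform(1.1, 2.0, size=n)
    atoms = [al.AtomRecord("C", p, r) for p, r in zip(positions, radii)]
    return al.DensityField(atoms, sigma=float(rng.uniform(0.08, 0.3)))


def synthetic_mesh(shape_indices, areas=None):
    """Minimal mesh carrying prescribed per-triangle shape indices and areas.

    Geometry is a fan of right triangles scaled so each has the requested
    area; only the statistical fields matter for shapestats tests.
    """
    s = np.asarray(shape_indices, dtype=float)
    m = len(s)
    areas = np.ones(m) if areas is None else np.asarray(areas, dtype=float)
    verts = []
    tris = []
    for i, a in enumerate(areas):
        side = np.sqrt(2.0 * a)
        z = float(i)
        verts += [[0.0, 0.0, z], [side, 0.0, z], [0.0, side, z]]
        tris.append([3 * i, 3 * i + 1, 3 * i + 2])
    mesh = al.SurfaceMesh(vertices=np.array(verts), triangles=np.array(tris))
    mesh.triangle_shape_index = s
    mesh.triangle_valid = np.ones(m, dtype=bool)
    return mesh
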