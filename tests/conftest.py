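"""Shared fixtures: canonical solids and small synthetic teeth.

Session-scoped where construction is expensive; all geometry generated
in-process so the suite ships no binary fixtures.
"""

from __future__ import annotations

import numpy as np
import pytest
import trimesh

from rootmorph.mesh_core import TriangleMesh
from rootmorph.synthetic_data import (
    ResorptionSpec,
    ToothTemplateSpec,
    apply_resorption,
    default_lacuna_sites,
    generate_tooth,
)


def tm(mesh: trimesh.Trimesh) -> TriangleMesh:
    return TriangleMesh(mesh.vertices, mesh.faces)


@pytest.fixture()
def unit_cube() -> TriangleMesh:
    box = trimesh.creation.box(extents=[1, 1, 1])
    box.apply_translation([0.5, 0.5, 0.5])
    return tm(box)


@pytest.fixture(scope="session")
def sphere_r3() -> TriangleMesh:
    return tm(trimesh.creation.icosphere(subdivisions=4, radius=3.0))


@pytest.fixture(scope="session")
def concentric_spheres() -> dict:
    return {
        r: tm(trimesh.creation.icosphere(subdivisions=3, radius=r))
        for r in (5.0, 4.8, 4.5)
    }


@pytest.fixture(scope="session")
def p1_tooth():
    spec = ToothTemplateSpec.for_class("P1")
    return generate_tooth(spec, seed=11)


@pytest.fixture(scope="session")
def m1_tooth():
    spec = ToothTemplateSpec.for_class("M1")
    return generate_tooth(spec, seed=7)


@pytest.fixture(scope="session")
def resorbed_m1(m1_tooth):
    """An M1 pair with apical truncation + buccal lacunae, truth attached."""
    mesh, lm = m1_tooth
    rng = np.random.default_rng(21)
    spec = ResorptionSpec(
        apical_truncation={"M1m": 0.37, "M1d": 0.43, "M1p": 0.56},
        lacuna_sites=default_lacuna_sites(mesh, lm, rng, n_per_root=3),
        target_volume_loss=26.21,
    )
    t1, truth = apply_resorption(mesh, lm, spec, seed=22)
    return mesh, lm, t1, truth
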