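"""Shared fixtures: meshes and cached study solves (built once per session)."""

from __future__ import annotations

import logging

import numpy as np
import pytest
from hypothesis import settings

from spinefem import (
    GeometryParams,
    build_motion_segment,
    condition_materials,
    generate_fibers,
    make_motion_state,
    solve_static,
)
from spinefem.geometry import REGION_ID, Mesh
from spinefem.materials import MaterialConfig

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")

logging.getLogger("spinefem").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_params() -> GeometryParams:
    return GeometryParams()


@pytest.fixture(scope="session")
def segment_mesh(default_params) -> Mesh:
    """Default-resolution segment with fibers (shared, treat as read-only)."""
    mesh = build_motion_segment(default_params)
    return generate_fibers(mesh, default_params)


@pytest.fixture(scope="session")
def coarse_mesh() -> Mesh:
    p = GeometryParams(
        n_circumferential=8,
        n_radial_np=1,
        n_radial_per_annulus_layer=1,
        n_axial_disc=2,
        n_axial_vertebra=2,
    )
    return generate_fibers(build_motion_segment(p), p)


@pytest.fixture(scope="session")
def axial_solutions(segment_mesh):
    """All four disc conditions solved under 500 N axial compression."""
    case = make_motion_state(segment_mesh, "axial_compression", 500.0)
    cfg = MaterialConfig()
    out = {}
    for cond in ("normal", "degenerative", "np_removed", "np_replaced"):
        out[cond] = solve_static(
            segment_mesh, condition_materials(cond, cfg), case.system
        )
    return out


def unit_hex_mesh(E_label_region: str = "np") -> Mesh:
    """Single unit-cube hexahedron tagged as one region, with face node sets."""
    nodes = np.array(
        [
            [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
            [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1],
        ],
        dtype=float,
    )
    return Mesh(
        nodes=nodes,
        hexes=np.array([[0, 1, 2, 3, 4, 5, 6, 7]]),
        hex_region=np.array([REGION_ID[E_label_region]]),
        trusses=np.zeros((0, 2), int),
        truss_region=np.zeros(0, int),
        truss_area=np.zeros(0),
        truss_tension_only=np.zeros(0, bool),
        node_sets={
            "bottom": np.array([0, 1, 2, 3]),
            "top": np.array([4, 5, 6, 7]),
        },
    )


class UniformMaterials:
    """Minimal material assignment: one isotropic solid everywhere."""

    def __init__(self, E, nu, truss_E=0.0):
        from spinefem.materials import MaterialProperties

        self._solid = MaterialProperties(E=E, nu=nu, label="uniform")
        self._truss = (
            MaterialProperties(E=truss_E, nu=0.3, tension_only=True, label="t")
            if truss_E
            else None
        )

    def lookup(self, region):
        if region.startswith(("ligament", "annulus_fiber")):
            return self._truss
        return self._solid
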