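"""Loading protocols: the five motion states and the verification sweep.

Axial load enters through 40 designated points on the L4 top surface with
the total force split 3:1 between cortical-shell and cancellous points
(per-point weights realize the split exactly).  Torqued motion states add
a 7.5 N*m moment at a master point rigidly coupled to the L4 top surface;
the L5 base is clamped in every state.

Sign conventions (Z up, +Y anterior, +X left): forward flexion tips L4
anteriorly (moment about -X), backward extension the reverse (+X); left
axial rotation is counter-clockwise viewed from above (+Z moment), right
rotation -Z.  ``flip_sagittal_moment`` regenerates the mirrored convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .fem import LoadSystem
from .geometry import Mesh

__all__ = [
    "MOTION_STATES",
    "LoadCase",
    "apply_axial_load",
    "make_motion_state",
    "make_sweep",
]

MOTION_STATES = (
    "axial_compression",
    "forward_flexion",
    "backward_extension",
    "left_axial_rotation",
    "right_axial_rotation",
)

#: moment unit axis per torqued state (right-hand rule)
_MOMENT_AXIS = {
    "forward_flexion": np.array([-1.0, 0.0, 0.0]),
    "backward_extension": np.array([1.0, 0.0, 0.0]),
    "left_axial_rotation": np.array([0.0, 0.0, 1.0]),
    "right_axial_rotation": np.array([0.0, 0.0, -1.0]),
}


@dataclass
class LoadCase:
    """One motion state (or one sweep level) with its realized load system."""

    motion_state: str
    axial_force: float = 500.0  # N
    torque_nm: float = 7.5  # N*m magnitude (0 for pure compression)
    cortical_cancellous_ratio: Tuple[float, float] = (3.0, 1.0)
    sweep_loads: Optional[List[float]] = None
    system: Optional[LoadSystem] = None  # realized on a concrete mesh

    def __post_init__(self):
        if self.axial_force < 0:
            raise ValueError("axial_force must be >= 0")
        if self.torque_nm < 0:
            raise ValueError("torque magnitude must be >= 0")
        if any(p <= 0 for p in self.cortical_cancellous_ratio):
            raise ValueError("force split ratio parts must be > 0")


def apply_axial_load(
    mesh: Mesh,
    magnitude: float,
    ratio: Tuple[float, float] = (3.0, 1.0),
) -> np.ndarray:
    """(N, 3) nodal force vector for a -Z load over the 40 top points.

    The cortical subset carries ratio[0]/(ratio[0]+ratio[1]) of the total,
    the cancellous subset the rest; within each subset per-point forces are
    equal.  The resultant equals -magnitude in Z exactly.
    """
    if any(p <= 0 for p in ratio):
        raise ValueError("ratio parts must be > 0")
    cort = mesh.node_set("l4_top_cortical_points")
    canc = mesh.node_set("l4_top_cancellous_points")
    if len(cort) == 0 or len(canc) == 0:
        raise ValueError("load point subsets must be non-empty")
    f = np.zeros((mesh.n_nodes, 3))
    share_c = ratio[0] / (ratio[0] + ratio[1])
    f[cort, 2] = -magnitude * share_c / len(cort)
    f[canc, 2] = -magnitude * (1.0 - share_c) / len(canc)
    return f


def make_motion_state(
    mesh: Mesh,
    state: str,
    axial: float = 500.0,
    torque_nm: float = 7.5,
    ratio: Tuple[float, float] = (3.0, 1.0),
    flip_sagittal_moment: bool = False,
) -> LoadCase:
    """Realize one of the five motion states on a concrete mesh.

    Pure axial compression distributes the load over the 40 points with no
    master coupling; the four torqued states couple the L4 top surface to
    its neutral (master) point and apply the moment there, with the axial
    force carried by the master as well.
    """
    if state not in MOTION_STATES:
        raise ValueError(f"unknown motion state '{state}'; one of {MOTION_STATES}")
    fixed = mesh.node_set("l5_bottom")
    if state == "axial_compression":
        system = LoadSystem(
            forces=apply_axial_load(mesh, axial, ratio),
            fixed_nodes=fixed,
        )
        return LoadCase(state, axial, 0.0, ratio, system=system)

    axis = _MOMENT_AXIS[state].copy()
    if flip_sagittal_moment and state in ("forward_flexion", "backward_extension"):
        axis = -axis
    system = LoadSystem(
        forces=np.zeros((mesh.n_nodes, 3)),
        fixed_nodes=fixed,
        couple_set="l4_top",
        master_force=np.array([0.0, 0.0, -axial]),
        master_moment=axis * torque_nm * 1000.0,  # N*m -> N*mm
    )
    return LoadCase(state, axial, torque_nm, ratio, system=system)


def make_sweep(
    mesh: Mesh,
    loads: Sequence[float] = (1000.0, 2000.0, 3000.0, 4000.0, 5000.0, 6000.0),
    ratio: Tuple[float, float] = (3.0, 1.0),
) -> List[LoadCase]:
    """Vertical verification sweep: one pure-compression case per magnitude."""
    if len(loads) == 0:
        raise ValueError("sweep load list must be non-empty")
    if any(m <= 0 for m in loads):
        raise ValueError("sweep loads must be positive")
    cases = []
    for m in loads:
        system = LoadSystem(
            forces=apply_axial_load(mesh, m, ratio),
            fixed_nodes=mesh.node_set("l5_bottom"),
        )
        cases.append(
            LoadCase("vertical_sweep", m, 0.0, ratio,
                     sweep_loads=list(loads), system=system)
        )
    return cases


def load_audit(mesh: Mesh, case: LoadCase) -> dict:
    """Resultant force/moment audit of a realized load case."""
    s = case.system
    total_f = s.forces.sum(axis=0) + s.master_force
    # moment about the mesh origin from nodal forces
    m_nodal = np.cross(mesh.nodes, s.forces).sum(axis=0)
    return {
        "state": case.motion_state,
        "total_force_N": total_f.tolist(),
        "nodal_moment_Nmm": m_nodal.tolist(),
        "master_moment_Nmm": s.master_moment.tolist(),
    }
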