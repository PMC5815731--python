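"""Small-strain linear-elastic FE solver for the motion-segment meshes.

Element technology
------------------
* 8-node hexahedra with 2x2x2 Gauss integration and the mean-dilatation
  B-bar modification (volumetric strain replaced by its element average),
  which keeps near-incompressible regions (Poisson ratio up to 0.4999)
  free of volumetric locking while passing the constant-stress patch test.
* 2-node trusses (ligaments, annulus fibers) contributing EA/L along the
  element axis.  Tension-only trusses are handled by a fixed-point
  active-set iteration: solve, deactivate members in compression,
  re-solve until the active set is stable.
* Rigid coupling of a node set to a 6-dof master point and trilinear
  embedding of fiber nodes in host hexes are both realized through a
  global master-slave transformation T, so the reduced operator stays
  symmetric and constraint forces are transmitted exactly.

All quantities in N / mm / MPa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .elements import physical_gradients
from .geometry import Mesh
from .materials import MaterialAssignment

__all__ = [
    "LoadSystem",
    "SolutionField",
    "assemble",
    "solve_static",
    "von_mises",
    "rigid_couple",
]

_FORCE_TOL = 1e-8  # N, tension-only hysteresis
_MAX_ACTIVE_SET_ITERS = 20


@dataclass
class LoadSystem:
    """Nodal forces plus constraints for one static solve."""

    forces: np.ndarray  # (N, 3) nodal external forces
    fixed_nodes: np.ndarray  # node ids clamped in all dofs
    couple_set: Optional[str] = None  # node-set name rigidly tied to a master
    master_force: np.ndarray = field(default_factory=lambda: np.zeros(3))
    master_moment: np.ndarray = field(default_factory=lambda: np.zeros(3))  # N*mm
    # optional single-dof constraints as (node, axis) pairs
    fixed_dofs: Optional[np.ndarray] = None


@dataclass
class SolutionField:
    """Displacements, stresses and solver diagnostics for one solve."""

    u: np.ndarray  # (N, 3) nodal displacements, mm
    master_u: Optional[np.ndarray]  # (6,) translations+rotations of the master
    element_stress: np.ndarray  # (H, 6) Voigt avg stress (xx,yy,zz,xy,yz,zx)
    element_vm: np.ndarray  # (H,) von Mises, MPa
    truss_force: np.ndarray  # (T,) axial force, N (+ = tension)
    truss_active: np.ndarray  # (T,) bool
    reactions: np.ndarray  # (N, 3), nonzero only at constrained nodes
    iterations: int  # tension-only loop count
    residual: float  # relative equilibrium residual of the last solve
    strain_energy: float  # N*mm
    hex_active: np.ndarray  # (H,) bool (False for deactivated regions)


def von_mises(stress: np.ndarray) -> np.ndarray:
    """Von Mises equivalent stress of symmetric tensors.

    Accepts shape (..., 3, 3) tensors or (..., 6) Voigt vectors ordered
    (xx, yy, zz, xy, yz, zx).
    """
    s = np.asarray(stress, dtype=float)
    if s.shape[-2:] == (3, 3):
        sxx, syy, szz = s[..., 0, 0], s[..., 1, 1], s[..., 2, 2]
        sxy, syz, szx = s[..., 0, 1], s[..., 1, 2], s[..., 2, 0]
    else:
        sxx, syy, szz, sxy, syz, szx = (s[..., i] for i in range(6))
    return np.sqrt(
        0.5 * ((sxx - syy) ** 2 + (syy - szz) ** 2 + (szz - sxx) ** 2)
        + 3.0 * (sxy**2 + syz**2 + szx**2)
    )


def _isotropic_D(E: np.ndarray, nu: np.ndarray) -> np.ndarray:
    """Voigt 6x6 isotropic elasticity matrices for arrays of (E, nu)."""
    lam = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    mu = E / (2.0 * (1.0 + nu))
    D = np.zeros(E.shape + (6, 6))
    for i in range(3):
        for j in range(3):
            D[..., i, j] = lam
        D[..., i, i] += 2.0 * mu
    for i in range(3, 6):
        D[..., i, i] = mu
    return D


def _hex_material_arrays(mesh: Mesh, materials: MaterialAssignment):
    """Per-hex (E, nu, active) from the region map."""
    H = len(mesh.hexes)
    E = np.zeros(H)
    nu = np.zeros(H)
    active = np.zeros(H, dtype=bool)
    for rid in np.unique(mesh.hex_region):
        name = mesh.region_name(rid)
        props = materials.lookup(name)
        m = mesh.hex_region == rid
        if props is None:
            continue
        E[m] = props.E
        nu[m] = props.nu
        active[m] = True
    return E, nu, active


def _build_B(mesh: Mesh, hex_sel: np.ndarray):
    """B-bar strain-displacement matrices for the selected hexes.

    Returns (Bbar (E,8,6,24), detJ (E,8), dof index map (E,24)).
    """
    if len(hex_sel) == 0:
        return (
            np.zeros((0, 8, 6, 24)),
            np.zeros((0, 8)),
            np.zeros((0, 24), dtype=int),
        )
    coords = mesh.nodes[mesh.hexes[hex_sel]]
    grads, detJ = physical_gradients(coords)  # (E,8gp,8n,3), (E,8)
    if detJ.min() <= 0:
        bad = hex_sel[np.nonzero(detJ.min(axis=1) <= 0)[0][0]]
        raise ValueError(f"inverted hexahedron: element {bad}")
    En = len(hex_sel)
    # flat dilatation operator b[e, gp, 3a+j] = dN_a/dx_j
    b = grads.reshape(En, 8, 24)
    vol = detJ.sum(axis=1)
    bbar = np.einsum("egk,eg->ek", b, detJ) / vol[:, None]

    B = np.zeros((En, 8, 6, 24))
    dN = grads  # alias
    a = np.arange(8)
    B[:, :, 0, 3 * a + 0] = dN[:, :, a, 0]
    B[:, :, 1, 3 * a + 1] = dN[:, :, a, 1]
    B[:, :, 2, 3 * a + 2] = dN[:, :, a, 2]
    B[:, :, 3, 3 * a + 0] = dN[:, :, a, 1]
    B[:, :, 3, 3 * a + 1] = dN[:, :, a, 0]
    B[:, :, 4, 3 * a + 1] = dN[:, :, a, 2]
    B[:, :, 4, 3 * a + 2] = dN[:, :, a, 1]
    B[:, :, 5, 3 * a + 0] = dN[:, :, a, 2]
    B[:, :, 5, 3 * a + 2] = dN[:, :, a, 0]
    # mean-dilatation correction on the normal-strain rows
    corr = (bbar[:, None, :] - b) / 3.0  # (E, 8gp, 24)
    for row in range(3):
        B[:, :, row, :] += corr

    dofs = (3 * mesh.hexes[hex_sel][:, :, None] + np.arange(3)).reshape(En, 24)
    return B, detJ, dofs


def assemble(
    mesh: Mesh,
    materials: MaterialAssignment,
    truss_active: Optional[np.ndarray] = None,
) -> sp.csr_matrix:
    """Global stiffness operator (3N x 3N, symmetric) before constraints.

    ``truss_active`` masks tension-only members; by default all trusses
    contribute.  Regions marked inactive in ``materials`` are skipped.
    """
    N = mesh.n_nodes
    E_h, nu_h, active_h = _hex_material_arrays(mesh, materials)
    sel = np.nonzero(active_h)[0]
    B, detJ, dofs = _build_B(mesh, sel)
    D = _isotropic_D(E_h[sel], nu_h[sel])
    Ke = np.einsum("egik,eij,egjl,eg->ekl", B, D, B, detJ, optimize=True)

    rows = np.repeat(dofs, 24, axis=1).ravel()
    cols = np.tile(dofs, (1, 24)).ravel()
    data = Ke.ravel()

    t_rows, t_cols, t_data = _truss_triplets(mesh, materials, truss_active)
    K = sp.coo_matrix(
        (
            np.concatenate([data, t_data]),
            (np.concatenate([rows, t_rows]), np.concatenate([cols, t_cols])),
        ),
        shape=(3 * N, 3 * N),
    ).tocsr()
    return K


def _truss_triplets(mesh, materials, truss_active):
    T = len(mesh.trusses)
    if T == 0:
        return np.zeros(0, int), np.zeros(0, int), np.zeros(0)
    if truss_active is None:
        truss_active = np.ones(T, dtype=bool)
    E_t = np.zeros(T)
    for rid in np.unique(mesh.truss_region):
        props = materials.lookup(mesh.region_name(rid))
        if props is not None:
            E_t[mesh.truss_region == rid] = props.E
    sel = np.nonzero(truss_active & (E_t > 0))[0]
    n0, n1 = mesh.trusses[sel, 0], mesh.trusses[sel, 1]
    dx = mesh.nodes[n1] - mesh.nodes[n0]
    L = np.linalg.norm(dx, axis=1)
    d = dx / L[:, None]
    k = E_t[sel] * mesh.truss_area[sel] / L
    ddT = k[:, None, None] * d[:, :, None] * d[:, None, :]  # (t,3,3)
    Ke = np.concatenate(
        [
            np.concatenate([ddT, -ddT], axis=2),
            np.concatenate([-ddT, ddT], axis=2),
        ],
        axis=1,
    )  # (t, 6, 6)
    dofs = np.concatenate(
        [3 * n0[:, None] + np.arange(3), 3 * n1[:, None] + np.arange(3)], axis=1
    )  # (t, 6)
    rows = np.repeat(dofs, 6, axis=1).ravel()
    cols = np.tile(dofs, (1, 6)).ravel()
    return rows, cols, Ke.ravel()


def rigid_couple(mesh: Mesh, node_set: str) -> Tuple[np.ndarray, np.ndarray]:
    """Master point (centroid) and slave ids for a rigid coupling."""
    ids = mesh.node_set(node_set)
    if len(ids) == 0:
        raise ValueError(f"node set '{node_set}' is empty")
    return mesh.nodes[ids].mean(axis=0), np.asarray(ids)


def _transformation(mesh: Mesh, loads: LoadSystem):
    """Master-slave reduction T with full dofs = 3N, reduced dofs =
    [6 master dofs if coupling] + 3 per retained node.

    Returns (T csr, retained-node index map, master slice or None,
    slave node mask)."""
    N = mesh.n_nodes
    slave = np.zeros(N, dtype=bool)
    slave[mesh.embedded_nodes] = True
    if loads.couple_set is not None:
        center, coupled = rigid_couple(mesh, loads.couple_set)
        if slave[coupled].any():
            raise ValueError("coupled nodes may not also be embedded slaves")
        slave[coupled] = True
    else:
        center, coupled = None, np.zeros(0, int)

    n_master = 6 if loads.couple_set is not None else 0
    retained = np.nonzero(~slave)[0]
    red_of = -np.ones(N, dtype=int)
    red_of[retained] = n_master + 3 * np.arange(len(retained))
    n_red = n_master + 3 * len(retained)

    rows, cols, vals = [], [], []
    # retained nodes: identity
    r = np.repeat(3 * retained, 3) + np.tile(np.arange(3), len(retained))
    c = np.repeat(red_of[retained], 3) + np.tile(np.arange(3), len(retained))
    rows.append(r)
    cols.append(c)
    vals.append(np.ones(len(r)))

    # rigid slaves: u_s = u_m + theta x r
    if n_master:
        lever = mesh.nodes[coupled] - center  # (S, 3)
        for s_i, node in enumerate(coupled):
            rx, ry, rz = lever[s_i]
            # (full dof row, reduced col, value)
            ent = [
                (3 * node + 0, 0, 1.0), (3 * node + 1, 1, 1.0), (3 * node + 2, 2, 1.0),
                (3 * node + 0, 4, rz), (3 * node + 0, 5, -ry),
                (3 * node + 1, 5, rx), (3 * node + 1, 3, -rz),
                (3 * node + 2, 3, ry), (3 * node + 2, 4, -rx),
            ]
            for rr, cc, vv in ent:
                rows.append(np.array([rr]))
                cols.append(np.array([cc]))
                vals.append(np.array([vv]))

    # embedded slaves: u_s = sum_k w_k u_host_k
    if len(mesh.embedded_nodes):
        hosts = mesh.embedded_hosts
        if slave[hosts].any():
            raise ValueError("embedded host nodes may not be slaves")
        for j in range(3):
            r = (3 * mesh.embedded_nodes[:, None] + j).repeat(8, axis=1).ravel()
            c = (red_of[hosts] + j).ravel()
            rows.append(r)
            cols.append(c)
            vals.append(mesh.embedded_weights.ravel())

    T = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(3 * N, n_red),
    ).tocsr()
    master = slice(0, 6) if n_master else None
    return T, red_of, master, slave, center


def solve_static(
    mesh: Mesh,
    materials: MaterialAssignment,
    loads: LoadSystem,
) -> SolutionField:
    """Static equilibrium with tension-only active-set iteration.

    Raises ``RuntimeError`` if the active set fails to stabilize within
    the iteration cap, and ``ValueError`` for singular constraint setups.
    """
    N = mesh.n_nodes
    f_full = np.asarray(loads.forces, dtype=float).reshape(3 * N)
    T, red_of, master, slave, _center = _transformation(mesh, loads)
    n_red = T.shape[1]

    fixed = np.asarray(loads.fixed_nodes, dtype=int)
    if slave[fixed].any():
        raise ValueError("fixed nodes may not be constraint slaves")
    fixed_red = (red_of[fixed][:, None] + np.arange(3)).ravel()
    if loads.fixed_dofs is not None and len(loads.fixed_dofs):
        fd = np.asarray(loads.fixed_dofs, dtype=int).reshape(-1, 2)
        if slave[fd[:, 0]].any():
            raise ValueError("fixed dofs may not belong to constraint slaves")
        fixed_red = np.concatenate([fixed_red, red_of[fd[:, 0]] + fd[:, 1]])

    f_red_base = T.T @ f_full
    if master is not None:
        f_red_base = f_red_base.copy()
        f_red_base[0:3] += loads.master_force
        f_red_base[3:6] += loads.master_moment

    active = np.ones(len(mesh.trusses), dtype=bool)

    E_t, A_t, L_t, d_t = _truss_kinematics(mesh, materials)

    u_full = np.zeros(3 * N)
    iters = 0
    residual = np.nan
    K = None
    for iters in range(1, _MAX_ACTIVE_SET_ITERS + 1):
        K = assemble(mesh, materials, truss_active=active)
        K_red = (T.T @ K @ T).tocsr()

        keep = np.ones(n_red, dtype=bool)
        keep[fixed_red] = False
        # pin dofs with no stiffness (nodes of deactivated regions)
        diag = K_red.diagonal()
        keep &= (diag > 0) | (np.arange(n_red) < (6 if master is not None else 0))
        if master is not None and (diag[0:6] <= 0).any():
            # a master dof with no attached stiffness cannot be equilibrated
            if np.abs(f_red_base[0:6][diag[0:6] <= 0]).max() > 0:
                raise ValueError("load applied to unconstrained master dof")
            keep[0:6] &= diag[0:6] > 0

        idx = np.nonzero(keep)[0]
        K_ff = K_red[np.ix_(idx, idx)].tocsc()
        f_f = f_red_base[idx]
        try:
            lu = spla.splu(K_ff)
        except RuntimeError as exc:
            raise ValueError(f"singular system (insufficient constraints): {exc}")
        u_f = lu.solve(f_f)
        if not np.all(np.isfinite(u_f)):
            raise ValueError("singular system (insufficient constraints)")
        u_red = np.zeros(n_red)
        u_red[idx] = u_f
        u_full = T @ u_red

        fn = np.linalg.norm(f_f)
        residual = (
            np.linalg.norm(K_ff @ u_f - f_f) / fn if fn > 0 else 0.0
        )
        if residual > 1e-6:
            raise ValueError(
                f"singular system (insufficient constraints): relative "
                f"equilibrium residual {residual:.2e}"
            )

        if not len(mesh.trusses):
            break
        elong = np.einsum(
            "tj,tj->t",
            d_t,
            u_full.reshape(N, 3)[mesh.trusses[:, 1]]
            - u_full.reshape(N, 3)[mesh.trusses[:, 0]],
        )
        force = E_t * A_t / L_t * elong
        new_active = np.where(
            mesh.truss_tension_only, force > -_FORCE_TOL, True
        )
        if np.array_equal(new_active, active):
            break
        active = new_active
    else:
        raise RuntimeError(
            f"tension-only active set did not converge in "
            f"{_MAX_ACTIVE_SET_ITERS} iterations"
        )

    u = u_full.reshape(N, 3)
    master_u = u_red[0:6].copy() if master is not None else None

    # stress recovery
    E_h, nu_h, active_h = _hex_material_arrays(mesh, materials)
    sel = np.nonzero(active_h)[0]
    B, detJ, dofs = _build_B(mesh, sel)
    D = _isotropic_D(E_h[sel], nu_h[sel])
    ue = u_full[dofs]  # (E, 24)
    strain_gp = np.einsum("egik,ek->egi", B, ue)
    stress_gp = np.einsum("eij,egj->egi", D, strain_gp)
    avg = np.einsum("egi,eg->ei", stress_gp, detJ) / detJ.sum(axis=1)[:, None]
    element_stress = np.zeros((len(mesh.hexes), 6))
    element_stress[sel] = avg
    element_vm = von_mises(element_stress)
    element_vm[~active_h] = 0.0

    # truss forces in the converged state
    if len(mesh.trusses):
        elong = np.einsum(
            "tj,tj->t", d_t, u[mesh.trusses[:, 1]] - u[mesh.trusses[:, 0]]
        )
        truss_force = E_t * A_t / L_t * elong
        truss_force[~active] = 0.0
    else:
        truss_force = np.zeros(0)

    # reactions at constrained dofs
    r_full = ((K @ u_full) - f_full).reshape(N, 3)
    reactions = np.zeros((N, 3))
    reactions[fixed] = r_full[fixed]
    if loads.fixed_dofs is not None and len(loads.fixed_dofs):
        fd = np.asarray(loads.fixed_dofs, dtype=int).reshape(-1, 2)
        reactions[fd[:, 0], fd[:, 1]] = r_full[fd[:, 0], fd[:, 1]]

    strain_energy = 0.5 * float(u_full @ (K @ u_full))

    return SolutionField(
        u=u,
        master_u=master_u,
        element_stress=element_stress,
        element_vm=element_vm,
        truss_force=truss_force,
        truss_active=active,
        reactions=reactions,
        iterations=iters,
        residual=float(residual),
        strain_energy=strain_energy,
        hex_active=active_h,
    )


def _truss_kinematics(mesh: Mesh, materials: MaterialAssignment):
    T = len(mesh.trusses)
    E_t = np.zeros(T)
    for rid in np.unique(mesh.truss_region) if T else []:
        props = materials.lookup(mesh.region_name(rid))
        if props is not None:
            E_t[mesh.truss_region == rid] = props.E
    if T:
        dx = mesh.nodes[mesh.trusses[:, 1]] - mesh.nodes[mesh.trusses[:, 0]]
        L = np.linalg.norm(dx, axis=1)
        d = dx / L[:, None]
    else:
        L = np.zeros(0)
        d = np.zeros((0, 3))
    return E_t, mesh.truss_area.copy() if T else np.zeros(0), L, d


def nodal_von_mises(
    mesh: Mesh,
    solution: SolutionField,
    regions: Optional[Tuple[str, ...]] = None,
) -> np.ndarray:
    """Element-to-node averaged von Mises stress, optionally restricted to a
    set of regions (so soft-tissue values are not contaminated by adjacent
    bone).  Nodes touched by no selected element report 0."""
    from .geometry import REGION_ID

    N = mesh.n_nodes
    vm = np.zeros(N)
    wt = np.zeros(N)
    if regions is None:
        sel = np.nonzero(solution.hex_active)[0]
    else:
        rids = {REGION_ID[r] for r in regions}
        sel = np.nonzero(
            solution.hex_active & np.isin(mesh.hex_region, list(rids))
        )[0]
    for e in sel:
        vm[mesh.hexes[e]] += solution.element_vm[e]
        wt[mesh.hexes[e]] += 1.0
    nz = wt > 0
    vm[nz] /= wt[nz]
    return vm
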