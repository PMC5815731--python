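"""Solver verification: patch test, locking, rigid-body modes, trusses,
tension-only behaviour, rigid coupling, von Mises, dense-solve oracle."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from spinefem import (
    LoadSystem,
    assemble,
    condition_materials,
    make_motion_state,
    solve_static,
    von_mises,
)
from spinefem.geometry import REGION_ID, Mesh

from conftest import UniformMaterials, unit_hex_mesh


def block_mesh(nx, ny, nz, L=1.0):
    """Regular nx x ny x nz block of unit-ish hexes, region 'np'."""
    xs = np.linspace(0, L * nx, nx + 1)
    ys = np.linspace(0, L * ny, ny + 1)
    zs = np.linspace(0, L * nz, nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    hexes = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                hexes.append(
                    [
                        nid(i, j, k), nid(i + 1, j, k),
                        nid(i + 1, j + 1, k), nid(i, j + 1, k),
                        nid(i, j, k + 1), nid(i + 1, j, k + 1),
                        nid(i + 1, j + 1, k + 1), nid(i, j + 1, k + 1),
                    ]
                )
    hexes = np.array(hexes)
    bottom = np.nonzero(nodes[:, 2] == 0)[0]
    top = np.nonzero(nodes[:, 2] == zs[-1])[0]
    return Mesh(
        nodes=nodes,
        hexes=hexes,
        hex_region=np.full(len(hexes), REGION_ID["np"]),
        trusses=np.zeros((0, 2), int),
        truss_region=np.zeros(0, int),
        truss_area=np.zeros(0),
        truss_tension_only=np.zeros(0, bool),
        node_sets={"bottom": bottom, "top": top},
    )


def uniaxial_patch(mesh, E, nu, p=2.0):
    """Top traction p in +z, bottom restrained in z only, lateral free."""
    top = mesh.node_set("top")
    bottom = mesh.node_set("bottom")
    f = np.zeros((mesh.n_nodes, 3))
    # consistent nodal load for a uniform traction on the regular top face
    area = (
        (mesh.nodes[:, 0].max() - mesh.nodes[:, 0].min())
        * (mesh.nodes[:, 1].max() - mesh.nodes[:, 1].min())
    )
    w = np.zeros(mesh.n_nodes)
    for h in mesh.hexes:
        face = [n for n in h[4:] if n in set(top)]
        if len(face) == 4:
            quad = mesh.nodes[face]
            d1 = quad[2, :2] - quad[0, :2]
            d2 = quad[3, :2] - quad[1, :2]
            a = 0.5 * abs(d1[0] * d2[1] - d1[1] * d2[0])
            for n in face:
                w[n] += a / 4.0
    f[:, 2] = p * w
    fixed_dofs = [(n, 2) for n in bottom]
    # statically determinate in-plane support
    x0 = bottom[np.lexsort(mesh.nodes[bottom, :2].T)][0]
    others = [n for n in bottom if n != x0]
    x1 = others[np.argmax(mesh.nodes[others, 0])]
    fixed_dofs += [(x0, 0), (x0, 1), (x1, 1)]
    return LoadSystem(
        forces=f,
        fixed_nodes=np.zeros(0, int),
        fixed_dofs=np.array(fixed_dofs),
    )


class TestElementStiffness:
    def test_single_hex_has_exactly_six_rigid_body_modes(self):
        mesh = unit_hex_mesh()
        K = assemble(mesh, UniformMaterials(1.0, 0.3)).toarray()
        assert np.allclose(K, K.T, atol=1e-12)
        eig = np.linalg.eigvalsh(K)
        assert (np.abs(eig) < 1e-10).sum() == 6
        assert eig[6] > 1e-6

    def test_truss_axial_stiffness(self):
        nodes = np.array([[0.0, 0, 0], [0, 0, 2.0]])
        mesh = Mesh(
            nodes=nodes,
            hexes=np.zeros((0, 8), int),
            hex_region=np.zeros(0, int),
            trusses=np.array([[0, 1]]),
            truss_region=np.array([REGION_ID["ligament_flavum"]]),
            truss_area=np.array([3.0]),
            truss_tension_only=np.array([False]),
            node_sets={},
        )
        K = assemble(mesh, UniformMaterials(1.0, 0.3, truss_E=10.0)).toarray()
        k_ax = 10.0 * 3.0 / 2.0  # EA/L
        assert K[2, 2] == pytest.approx(k_ax)
        assert K[2, 5] == pytest.approx(-k_ax)
        assert abs(K[0, 0]) < 1e-12 and abs(K[1, 1]) < 1e-12  # no transverse

    def test_rigid_motion_produces_no_forces(self, coarse_mesh):
        K = assemble(coarse_mesh, condition_materials("normal"))
        rng = np.random.default_rng(0)
        theta = rng.normal(size=3) * 1e-3
        t = rng.normal(size=3)
        u = (t + np.cross(theta, coarse_mesh.nodes)).ravel()
        scale = abs(K).max() * np.abs(u).max()
        assert np.abs(K @ u).max() < 1e-8 * scale


class TestStaticSolve:
    @pytest.mark.parametrize("nu", [0.3, 0.4999])
    def test_uniaxial_patch_test(self, nu):
        """Uniform traction must reproduce the closed-form uniform state,
        including at the near-incompressible limit (no volumetric locking)."""
        E, p = 10.0, 2.0
        mesh = block_mesh(2, 2, 2, L=0.5)
        sol = solve_static(mesh, UniformMaterials(E, nu), uniaxial_patch(mesh, E, nu, p))
        top = mesh.node_set("top")
        H = mesh.nodes[:, 2].max()
        tol = 1e-3 if nu == 0.3 else 1e-2
        assert sol.u[top, 2] == pytest.approx(p * H / E, rel=tol)
        assert sol.element_stress[:, 2] == pytest.approx(p, rel=tol)
        assert np.abs(sol.element_stress[:, :2]).max() < tol * p

    def test_linearity_under_load_doubling(self):
        mesh = block_mesh(1, 1, 2)
        loads = uniaxial_patch(mesh, 5.0, 0.25, p=1.0)
        loads2 = uniaxial_patch(mesh, 5.0, 0.25, p=2.0)
        u1 = solve_static(mesh, UniformMaterials(5.0, 0.25), loads).u
        u2 = solve_static(mesh, UniformMaterials(5.0, 0.25), loads2).u
        assert np.allclose(u2, 2.0 * u1, atol=1e-12)

    def test_tension_only_truss_sheds_compression(self):
        """A tension-only member across a compressed hex must carry zero
        force, with the parallel continuum taking the whole load."""
        mesh = unit_hex_mesh()
        mesh.trusses = np.array([[0, 4]])  # vertical edge
        mesh.truss_region = np.array([REGION_ID["ligament_flavum"]])
        mesh.truss_area = np.array([1.0])
        mesh.truss_tension_only = np.array([True])
        mats = UniformMaterials(10.0, 0.3, truss_E=100.0)
        f = np.zeros((8, 3))
        f[[4, 5, 6, 7], 2] = -0.5  # compression
        loads = LoadSystem(forces=f, fixed_nodes=np.array([0, 1, 2, 3]))
        sol = solve_static(mesh, mats, loads)
        assert not sol.truss_active[0]
        assert sol.truss_force[0] == 0.0
        # same model loaded in tension: the member engages
        f2 = -f
        sol2 = solve_static(
            mesh, mats, LoadSystem(forces=f2, fixed_nodes=np.array([0, 1, 2, 3]))
        )
        assert sol2.truss_active[0]
        assert sol2.truss_force[0] > 0

    def test_dense_oracle_equivalence(self):
        """Sparse solve against a brute-force dense solve on a <=200-dof mesh."""
        mesh = block_mesh(2, 2, 2)  # 81 dofs
        mats = UniformMaterials(7.0, 0.35)
        rng = np.random.default_rng(1)
        f = rng.normal(size=(mesh.n_nodes, 3)) * 0.1
        bottom = mesh.node_set("bottom")
        f[bottom] = 0.0
        loads = LoadSystem(forces=f, fixed_nodes=bottom)
        sol = solve_static(mesh, mats, loads)

        K = assemble(mesh, mats).toarray()
        free = np.setdiff1d(
            np.arange(3 * mesh.n_nodes),
            (3 * bottom[:, None] + np.arange(3)).ravel(),
        )
        u_dense = np.zeros(3 * mesh.n_nodes)
        u_dense[free] = np.linalg.solve(K[np.ix_(free, free)], f.ravel()[free])
        assert np.abs(sol.u.ravel() - u_dense).max() < 1e-9

    def test_invariance_under_node_renumbering(self):
        mesh = block_mesh(2, 1, 2)
        rng = np.random.default_rng(3)
        perm = rng.permutation(mesh.n_nodes)  # new_id = perm[old_id]
        mesh2 = Mesh(
            nodes=mesh.nodes.copy()[np.argsort(perm)],
            hexes=perm[mesh.hexes],
            hex_region=mesh.hex_region.copy(),
            trusses=mesh.trusses.copy(),
            truss_region=mesh.truss_region.copy(),
            truss_area=mesh.truss_area.copy(),
            truss_tension_only=mesh.truss_tension_only.copy(),
            node_sets={k: perm[v] for k, v in mesh.node_sets.items()},
        )
        mats = UniformMaterials(4.0, 0.3)
        f = np.zeros((mesh.n_nodes, 3))
        f[mesh.node_set("top"), 2] = -1.0
        sol1 = solve_static(
            mesh, mats, LoadSystem(forces=f, fixed_nodes=mesh.node_set("bottom"))
        )
        f2 = np.zeros_like(f)
        f2[perm] = f
        sol2 = solve_static(
            mesh2, mats, LoadSystem(forces=f2, fixed_nodes=mesh2.node_set("bottom"))
        )
        assert np.abs(sol2.u[perm] - sol1.u).max() < 1e-6 * np.abs(sol1.u).max()

    def test_singular_system_reported(self):
        mesh = unit_hex_mesh()
        f = np.zeros((8, 3))
        f[4, 2] = 1.0
        with pytest.raises((ValueError, RuntimeError)):
            solve_static(
                mesh,
                UniformMaterials(1.0, 0.3),
                LoadSystem(forces=f, fixed_nodes=np.zeros(0, int)),
            )


class TestEquilibrium:
    def test_reactions_balance_applied_loads(self, segment_mesh, axial_solutions):
        total_applied = -500.0
        for cond, sol in axial_solutions.items():
            resultant = sol.reactions.sum(axis=0)
            assert abs(resultant[2] + total_applied) < 1e-6 * 500.0, cond
            assert abs(resultant[0]) < 1e-6 * 500.0
            assert abs(resultant[1]) < 1e-6 * 500.0
            assert sol.strain_energy >= 0.0
            assert sol.residual < 1e-8

    def test_active_tension_members_not_in_compression(self, axial_solutions):
        for sol in axial_solutions.values():
            assert sol.truss_force.min() > -1e-6


class TestRigidCoupling:
    def test_coupled_surface_moves_rigidly_and_moment_balances(self, segment_mesh):
        case = make_motion_state(segment_mesh, "left_axial_rotation")
        mats = condition_materials("normal")
        sol = solve_static(segment_mesh, mats, case.system)
        ids = segment_mesh.node_set("l4_top")
        center = segment_mesh.nodes[ids].mean(axis=0)
        um, theta = sol.master_u[:3], sol.master_u[3:]
        lever = segment_mesh.nodes[ids] - center
        predicted = um + np.cross(theta, lever)
        assert np.abs(sol.u[ids] - predicted).max() < 1e-9
        # global moment balance about the master point: reactions at the
        # fixed base must balance the applied 7.5 N*m torque exactly
        m_react = np.cross(segment_mesh.nodes - center, sol.reactions).sum(axis=0)
        applied = case.system.master_moment
        assert m_react[2] == pytest.approx(-applied[2], rel=1e-6)


class TestVonMises:
    def test_canonical_states(self):
        s = np.zeros((3, 3))
        s[0, 0] = 5.0
        assert von_mises(s) == pytest.approx(5.0)
        assert von_mises(2.0 * np.eye(3)) == pytest.approx(0.0, abs=1e-12)
        tau = np.zeros((3, 3))
        tau[0, 1] = tau[1, 0] = 3.0
        assert von_mises(tau) == pytest.approx(np.sqrt(3) * 3.0)

    @given(v=st.lists(st.floats(-50, 50), min_size=6, max_size=6),
           p=st.floats(-100, 100))
    def test_pressure_invariance_and_voigt_tensor_agreement(self, v, p):
        voigt = np.array(v)
        t = np.array(
            [
                [v[0], v[3], v[5]],
                [v[3], v[1], v[4]],
                [v[5], v[4], v[2]],
            ]
        )
        assert von_mises(voigt) == pytest.approx(von_mises(t), abs=1e-9)
        shifted = voigt.copy()
        shifted[:3] += p
        assert von_mises(shifted) == pytest.approx(von_mises(voigt), abs=1e-6)
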