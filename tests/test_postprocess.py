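"""Study metrics: endplate sites, percent increase, bulge, displacements,
symmetry of the solved fields."""

import numpy as np
import pytest

from spinefem import (
    LoadSystem,
    bulge_displacement,
    cep_site_stresses,
    condition_materials,
    make_motion_state,
    make_sweep,
    percent_increase,
    solve_static,
)
from spinefem.postprocess import (
    axial_displacement,
    disc_center_stress,
    make_report,
    np_mean_pressure,
)


class TestPercentIncrease:
    def test_printed_relation(self):
        s = 0.7
        assert percent_increase(1.6463 * s, s) == pytest.approx(64.63, abs=0.01)

    def test_identity_and_sign(self):
        assert percent_increase(2.0, 2.0) == 0.0
        assert percent_increase(1.0, 2.0) == -50.0

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_increase(1.0, 0.0)


class TestZeroLoad:
    def test_all_metrics_vanish_without_load(self, segment_mesh):
        loads = LoadSystem(
            forces=np.zeros((segment_mesh.n_nodes, 3)),
            fixed_nodes=segment_mesh.node_set("l5_bottom"),
        )
        sol = solve_static(segment_mesh, condition_materials("normal"), loads)
        sites = cep_site_stresses(sol, segment_mesh)
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in sites.values())
        assert bulge_displacement(sol, segment_mesh) == pytest.approx(0.0, abs=1e-12)
        assert axial_displacement(sol, segment_mesh) == pytest.approx(0.0, abs=1e-12)
        vm, zz = disc_center_stress(sol, segment_mesh)
        assert vm == pytest.approx(0.0, abs=1e-12)
        assert np_mean_pressure(sol, segment_mesh) == pytest.approx(0.0, abs=1e-12)


class TestFieldStructure:
    def test_left_right_margin_symmetry_under_axial_load(
        self, segment_mesh, axial_solutions
    ):
        sites = cep_site_stresses(axial_solutions["normal"], segment_mesh)
        assert sites["cep_upper_left_margin"] == pytest.approx(
            sites["cep_upper_right_margin"], rel=0.01
        )
        assert sites["cep_lower_left_margin"] == pytest.approx(
            sites["cep_lower_right_margin"], rel=0.01
        )

    def test_sagittal_mirror_symmetry_of_axial_solution(
        self, segment_mesh, axial_solutions
    ):
        from scipy.spatial import cKDTree

        u = axial_solutions["normal"].u
        mirrored = segment_mesh.nodes.copy()
        mirrored[:, 0] *= -1
        _, idx = cKDTree(segment_mesh.nodes).query(mirrored)
        u_m = u[idx] * np.array([-1.0, 1.0, 1.0])
        assert np.abs(u - u_m).max() < 0.01 * np.abs(u).max()

    def test_flexion_loads_anterior_endplate_more_than_posterior(
        self, segment_mesh
    ):
        case = make_motion_state(segment_mesh, "forward_flexion")
        sol = solve_static(segment_mesh, condition_materials("normal"), case.system)
        sites = cep_site_stresses(sol, segment_mesh)
        assert (
            sites["cep_upper_anterior_central"]
            > sites["cep_upper_posterior_central"]
        )

    def test_left_right_rotation_mirror_equivalence(self, segment_mesh):
        mats = condition_materials("normal")
        left = solve_static(
            segment_mesh, mats,
            make_motion_state(segment_mesh, "left_axial_rotation").system,
        )
        right = solve_static(
            segment_mesh, mats,
            make_motion_state(segment_mesh, "right_axial_rotation").system,
        )
        from scipy.spatial import cKDTree

        mirrored = segment_mesh.nodes.copy()
        mirrored[:, 0] *= -1
        _, idx = cKDTree(segment_mesh.nodes).query(mirrored)
        u_mirror_of_left = left.u[idx] * np.array([-1.0, 1.0, 1.0])
        assert np.abs(right.u - u_mirror_of_left).max() < 0.01 * np.abs(
            left.u
        ).max()

    def test_bulge_scales_linearly_with_axial_load(self, segment_mesh):
        mats = condition_materials("normal")
        cases = make_sweep(segment_mesh, [1000.0, 2000.0])
        b1 = bulge_displacement(
            solve_static(segment_mesh, mats, cases[0].system), segment_mesh
        )
        b2 = bulge_displacement(
            solve_static(segment_mesh, mats, cases[1].system), segment_mesh
        )
        assert b2 == pytest.approx(2.0 * b1, rel=1e-9)

    def test_report_peak_is_max_over_sites(self, segment_mesh, axial_solutions):
        rep = make_report("normal", "axial_compression",
                          axial_solutions["normal"], segment_mesh)
        assert rep.cep_peak == max(rep.cep_site_stress.values())
        assert rep.cep_global_max >= rep.cep_peak
        assert all(v >= 0 for v in rep.cep_site_stress.values())
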