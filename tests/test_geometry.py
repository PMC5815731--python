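"""Mesh generator: printed cross-section areas, fiber architecture, node
sets, symmetry and validity."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from spinefem import GeometryParams, build_motion_segment, generate_fibers
from spinefem.elements import jacobians
from spinefem.geometry import REGION_NAMES, region_areas

DISC_REGIONS = ("np", "annulus_layer1", "annulus_layer2", "annulus_layer3")


class TestCrossSectionAreas:
    def test_np_area_matches_printed_value(self, segment_mesh):
        areas = region_areas(segment_mesh, 0.0)
        assert 485.6 <= areas["np"] <= 505.4  # 495.5 mm^2 +/- 2%

    def test_total_disc_area_matches_printed_value(self, segment_mesh):
        areas = region_areas(segment_mesh, 0.0)
        total = sum(areas[r] for r in DISC_REGIONS)
        assert 1274.0 <= total <= 1326.0  # 1300 mm^2 +/- 2%

    def test_annulus_layer_ratios(self, segment_mesh):
        areas = region_areas(segment_mesh, 0.0)
        fracs = [areas[f"annulus_layer{i}"] / 1300.0 for i in (1, 2, 3)]
        assert fracs == pytest.approx([0.25, 0.21, 0.165], rel=0.02)

    def test_refinement_leaves_region_areas_unchanged(self, default_params):
        """Doubling the circumferential resolution must not move the areas."""
        from dataclasses import replace

        fine = build_motion_segment(
            replace(default_params,
                    n_circumferential=2 * default_params.n_circumferential)
        )
        coarse = build_motion_segment(default_params)
        a0 = region_areas(coarse, 0.0)
        a1 = region_areas(fine, 0.0)
        for r in DISC_REGIONS:
            assert a1[r] == pytest.approx(a0[r], rel=0.005)

    def test_region_area_sum_matches_polygon_oracle(self, segment_mesh):
        """Brute-force shoelace of the outer boundary polygon vs region sum."""
        areas = region_areas(segment_mesh, 0.0)
        total = sum(areas[r] for r in DISC_REGIONS)
        rings = dict(segment_mesh.meta["rings"])
        xy = segment_mesh.meta["xy"][rings["annulus_3_outer"]]
        x, y = xy[:, 0], xy[:, 1]
        poly = 0.5 * abs(
            np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        )
        assert total == pytest.approx(poly, rel=0.005)

    def test_plane_through_vertebra_has_no_disc_area(self, segment_mesh):
        areas = region_areas(segment_mesh, 20.0)
        assert all(areas[r] == 0.0 for r in DISC_REGIONS)
        assert areas["cancellous_L4"] > 0

    def test_plane_outside_mesh_rejected(self, segment_mesh):
        with pytest.raises(ValueError, match="outside"):
            region_areas(segment_mesh, 1000.0)


class TestMeshValidity:
    def test_minimal_resolution_positive_jacobians(self, coarse_mesh):
        detJ = jacobians(coarse_mesh.nodes[coarse_mesh.hexes])
        assert detJ.min() > 0

    def test_mirror_symmetry_about_sagittal_plane(self, segment_mesh):
        mirrored = segment_mesh.nodes.copy()
        mirrored[:, 0] *= -1
        d, _ = cKDTree(segment_mesh.nodes).query(mirrored)
        assert d.max() < 1e-9

    def test_all_mandatory_node_sets_present(self, segment_mesh):
        mandatory = ["l4_top_cortical_points", "l4_top_cancellous_points",
                     "l5_bottom", "disc_center"]
        mandatory += [f"cep_upper_{s}" for s in
                      ("anterior_central", "central", "posterior_central",
                       "left_margin", "right_margin")]
        mandatory += [f"cep_lower_{s}" for s in
                      ("anterior_central", "central", "posterior_central",
                       "left_margin", "right_margin")]
        mandatory += [f"posterior_lateral_annulus_layer_{i}" for i in (1, 2, 3)]
        for name in mandatory:
            assert len(segment_mesh.node_set(name)) > 0, name

    def test_forty_load_points_disjoint_on_top_surface(self, segment_mesh):
        cort = segment_mesh.node_set("l4_top_cortical_points")
        canc = segment_mesh.node_set("l4_top_cancellous_points")
        assert len(cort) + len(canc) == 40
        assert len(np.intersect1d(cort, canc)) == 0
        z_top = segment_mesh.nodes[:, 2].max()
        assert np.allclose(segment_mesh.nodes[np.r_[cort, canc], 2], z_top)
        # cortical points sit on the outer boundary, cancellous strictly
        # inside (in normalized elliptical scale)
        a, b = segment_mesh.meta["semi_axes"]

        def scale(ids):
            xy = segment_mesh.nodes[ids, :2]
            return np.hypot(xy[:, 0] / a, xy[:, 1] / b)

        assert scale(canc).max() < scale(cort).min()

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError, match="tile"):
            GeometryParams(np_area_fraction=0.7).validate()
        with pytest.raises(ValueError, match="multiple of 8"):
            GeometryParams(n_circumferential=12).validate()
        with pytest.raises(ValueError, match="> 0"):
            GeometryParams(disc_area=-1.0).validate()

    def test_every_region_tag_is_in_the_closed_enumeration(self, segment_mesh):
        assert segment_mesh.hex_region.max() < len(REGION_NAMES)
        assert segment_mesh.truss_region.max() < len(REGION_NAMES)


class TestFibers:
    @staticmethod
    def _angles(mesh):
        fib = np.array(
            [REGION_NAMES[r].startswith("annulus_fiber") for r in mesh.truss_region]
        )
        d = mesh.nodes[mesh.trusses[fib, 1]] - mesh.nodes[mesh.trusses[fib, 0]]
        return np.degrees(
            np.arctan2(np.abs(d[:, 2]), np.hypot(d[:, 0], d[:, 1]))
        )

    def test_mean_fiber_angle_near_thirty_degrees(self, segment_mesh):
        ang = self._angles(segment_mesh)
        assert 28.0 <= ang.mean() <= 32.0

    def test_every_fiber_within_two_degrees(self, segment_mesh):
        ang = self._angles(segment_mesh)
        assert np.all(np.abs(ang - 30.0) <= 2.0)

    def test_zero_angle_gives_circumferential_fibers(self, default_params):
        from dataclasses import replace

        p = replace(default_params, fiber_angle_deg=0.0)
        mesh = generate_fibers(build_motion_segment(p), p)
        ang = self._angles(mesh)
        assert np.all(ang < 1e-9)

    def test_fiber_families_balanced_and_tension_only(self, segment_mesh):
        # symmetry of construction: +theta and -theta helices mirror each
        # other, so the signed rise along +theta traversal splits evenly
        fib = np.array(
            [REGION_NAMES[r].startswith("annulus_fiber")
             for r in segment_mesh.truss_region]
        )
        assert segment_mesh.truss_tension_only[fib].all()
        for layer in (1, 2, 3):
            assert segment_mesh.fiber_volume_per_layer[
                f"annulus_fiber_layer{layer}"
            ] > 0

    def test_fiber_nodes_are_embedded_consistently(self, segment_mesh):
        m = segment_mesh
        interp = np.einsum(
            "mk,mkj->mj", m.embedded_weights, m.nodes[m.embedded_hosts]
        )
        assert np.abs(m.nodes[m.embedded_nodes] - interp).max() < 1e-9
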