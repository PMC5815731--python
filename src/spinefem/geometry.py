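"""Parametric mesh generator for an L4/5 lumbar motion segment.

The builder is the synthetic stand-in for a patient CT-derived geometry:
two vertebral bodies, a three-layer annulus fibrosus around the nucleus
pulposus (NP), a cartilaginous endplate (CEP) above and below the disc,
seven tension-only ligaments, and criss-cross annulus fiber trusses.

Coordinate convention (documented once, used everywhere): Z points up
(superior), +Y anterior, +X left; compression acts in -Z.  Units are
N / mm / MPa.  The disc mid-plane sits at z = 0.

The vertebral cross-section is an ellipse sized to the printed disc area;
nucleus and annulus-layer boundaries are concentric scaled ellipses whose
polygonal (discretized) areas are corrected so the printed cross-section
areas are met at any circumferential resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .elements import jacobians

__all__ = [
    "GeometryParams",
    "Mesh",
    "LigamentSpec",
    "build_motion_segment",
    "generate_fibers",
    "region_areas",
    "DEFAULT_LIGAMENTS",
]


@dataclass(frozen=True)
class LigamentSpec:
    """One named ligament: attachment azimuths (deg, 90 = anterior, 0 = left),
    vertebral attachment ring offset (stations away from the disc), and total
    cross-sectional area (mm^2, split over the azimuths)."""

    name: str
    azimuths_deg: Tuple[float, ...]
    ring_offset: int
    area_mm2: float


# Simplified posterior/anterior attachment scheme: all seven ligaments run
# between outer-surface nodes of L4 and L5.  Posterior bony elements are not
# meshed; interspinous/supraspinous lever arms are therefore shortened
# (documented limitation).
DEFAULT_LIGAMENTS: Tuple[LigamentSpec, ...] = (
    LigamentSpec("anterior_longitudinal", (90.0,), 1, 63.7),
    LigamentSpec("posterior_longitudinal", (270.0,), 1, 20.0),
    LigamentSpec("flavum", (250.0, 290.0), 1, 40.0),
    LigamentSpec("capsular", (205.0, 335.0), 1, 60.0),
    LigamentSpec("interspinous", (270.0,), 2, 40.0),
    LigamentSpec("supraspinous", (270.0,), 3, 30.0),
    LigamentSpec("intertransverse", (0.0, 180.0), 1, 3.6),
)

LIGAMENT_NAMES = tuple(l.name for l in DEFAULT_LIGAMENTS)

#: closed region enumeration
REGION_NAMES: Tuple[str, ...] = (
    "cortical_L4",
    "cancellous_L4",
    "cortical_L5",
    "cancellous_L5",
    "cep_upper",
    "cep_lower",
    "annulus_layer1",
    "annulus_layer2",
    "annulus_layer3",
    "np",
    "annulus_fiber_layer1",
    "annulus_fiber_layer2",
    "annulus_fiber_layer3",
) + tuple(f"ligament_{n}" for n in LIGAMENT_NAMES)

REGION_ID = {name: i for i, name in enumerate(REGION_NAMES)}

CEP_SITE_NAMES = (
    "anterior_central",
    "central",
    "posterior_central",
    "left_margin",
    "right_margin",
)


@dataclass
class GeometryParams:
    """Geometric truth for the motion segment (printed values as defaults)."""

    disc_height: float = 12.0  # mm, CEP-to-CEP outer span
    disc_area: float = 1300.0  # mm^2 cross-section
    np_area_fraction: float = 0.381  # 495.5 / 1300
    annulus_layer_area_fractions: Tuple[float, float, float] = (0.25, 0.21, 0.165)
    annulus_layer_volume_fractions: Tuple[float, float, float] = (0.21, 0.17, 0.13)
    fiber_angle_deg: float = 30.0  # to the transverse (XY) plane
    cep_thickness: float = 0.6  # mm hyaline cartilage layer
    vertebra_height: float = 28.0  # mm (literature-typical; not printed)
    cortical_shell_thickness: float = 1.0  # mm, nominal
    bony_endplate_thickness: float = 1.0  # mm cortical plate facing each CEP
    ellipse_aspect: float = 0.7  # AP semi-axis / lateral semi-axis
    posterior_lateral_azimuth_deg: float = 315.0  # bulge sampling azimuth
    fiber_volume_fraction: float = 0.15  # of annulus layer volume
    # mesh resolution
    n_circumferential: int = 16  # divisible by 8
    n_radial_np: int = 2
    n_radial_per_annulus_layer: int = 1
    n_axial_disc: int = 4
    n_axial_vertebra: int = 3
    ligament_spec: Tuple[LigamentSpec, ...] = field(default=DEFAULT_LIGAMENTS)

    def validate(self) -> None:
        lengths = {
            "disc_height": self.disc_height,
            "disc_area": self.disc_area,
            "np_area_fraction": self.np_area_fraction,
            "cep_thickness": self.cep_thickness,
            "vertebra_height": self.vertebra_height,
            "cortical_shell_thickness": self.cortical_shell_thickness,
            "ellipse_aspect": self.ellipse_aspect,
            "fiber_volume_fraction": self.fiber_volume_fraction,
        }
        for name, v in lengths.items():
            if not v > 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        if any(f <= 0 for f in self.annulus_layer_area_fractions):
            raise ValueError("annulus layer area fractions must be > 0")
        if not 0.0 < self.fiber_angle_deg < 90.0 and self.fiber_angle_deg != 0.0:
            raise ValueError("fiber_angle_deg must be in [0, 90)")
        tiling = self.np_area_fraction + sum(self.annulus_layer_area_fractions)
        if not 0.95 <= tiling <= 1.05:
            raise ValueError(
                f"NP + annulus area fractions must tile the disc "
                f"(sum in [0.95, 1.05]), got {tiling:.4f}"
            )
        if 2.0 * self.cep_thickness >= self.disc_height:
            raise ValueError("CEP layers thicker than the disc itself")
        n = self.n_circumferential
        if n < 8 or n % 8:
            raise ValueError("n_circumferential must be a multiple of 8, >= 8")
        for nm in (
            "n_radial_np",
            "n_radial_per_annulus_layer",
            "n_axial_disc",
            "n_axial_vertebra",
        ):
            if getattr(self, nm) < 1:
                raise ValueError(f"{nm} must be >= 1")
        for lig in self.ligament_spec:
            if lig.area_mm2 <= 0:
                raise ValueError(f"ligament {lig.name}: area must be > 0")

    def with_resolution(self, factor: int) -> "GeometryParams":
        """Scaled copy with all n_* multiplied by an integer factor."""
        return replace(
            self,
            n_circumferential=self.n_circumferential * factor,
            n_radial_np=self.n_radial_np * factor,
            n_radial_per_annulus_layer=self.n_radial_per_annulus_layer * factor,
            n_axial_disc=self.n_axial_disc * factor,
            n_axial_vertebra=self.n_axial_vertebra * factor,
        )


@dataclass
class Mesh:
    """Hexahedral + truss mesh with region tags and named node sets."""

    nodes: np.ndarray  # (N, 3)
    hexes: np.ndarray  # (H, 8) int, VTK ordering
    hex_region: np.ndarray  # (H,) int into REGION_NAMES
    trusses: np.ndarray  # (T, 2) int
    truss_region: np.ndarray  # (T,) int
    truss_area: np.ndarray  # (T,) float mm^2
    truss_tension_only: np.ndarray  # (T,) bool
    node_sets: Dict[str, np.ndarray]
    # kinematically embedded nodes (fiber chain nodes inside host hexes)
    embedded_nodes: np.ndarray = field(default_factory=lambda: np.zeros(0, int))
    embedded_hosts: np.ndarray = field(default_factory=lambda: np.zeros((0, 8), int))
    embedded_weights: np.ndarray = field(default_factory=lambda: np.zeros((0, 8)))
    fiber_volume_per_layer: Dict[str, float] = field(default_factory=dict)
    meta: dict = field(default_factory=dict, repr=False)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def region_name(self, rid: int) -> str:
        return REGION_NAMES[rid]

    def hexes_in(self, region: str) -> np.ndarray:
        return np.nonzero(self.hex_region == REGION_ID[region])[0]

    def node_set(self, name: str) -> np.ndarray:
        return self.node_sets[name]


# ---------------------------------------------------------------------------
# cross-section construction
# ---------------------------------------------------------------------------


def _cross_section(params: GeometryParams):
    """Build the 2D quad mesh of the cross-section.

    Returns (xy, quads, quad_region2d, rings, core_center) where
    quad_region2d is 0 for NP, 1..3 for annulus layers, and rings is an
    ordered list of (label, node-id array in perimeter order).
    """
    n = params.n_circumferential
    nc = n // 4
    a = np.sqrt(params.disc_area / (np.pi * params.ellipse_aspect))
    b = params.ellipse_aspect * a
    # polygon-area correction: polygon area at radius scale s is
    # s^2 * a * b * (n/2) sin(2 pi / n); corr makes it pi a b s^2.
    corr = np.sqrt(np.pi / ((n / 2.0) * np.sin(2.0 * np.pi / n)))
    cum = np.cumsum(
        [params.np_area_fraction, *params.annulus_layer_area_fractions]
    )
    s_np, s1, s2, s3 = np.sqrt(cum) * corr

    theta = np.pi / 4.0 + 2.0 * np.pi * np.arange(n) / n

    def ring_xy(s: float) -> np.ndarray:
        return np.column_stack([a * s * np.cos(theta), b * s * np.sin(theta)])

    # central core: rectangle with corners on the 45-degree diagonals at
    # half the NP boundary scale
    s_core = 0.5 * s_np
    Ax = a * s_core * np.cos(np.pi / 4.0)
    By = b * s_core * np.sin(np.pi / 4.0)

    xy: List[np.ndarray] = []
    u = np.linspace(1.0, -1.0, nc + 1)  # +x -> -x so perimeter runs CCW from 45 deg
    v = np.linspace(1.0, -1.0, nc + 1)
    core_ids = np.empty((nc + 1, nc + 1), dtype=int)  # [iv, iu]
    for iv in range(nc + 1):
        for iu in range(nc + 1):
            core_ids[iv, iu] = len(xy)
            xy.append(np.array([Ax * u[iu], By * v[iv]]))
    # core perimeter in CCW order starting at corner (+Ax, +By) (theta=45)
    per = []
    per.extend(core_ids[0, :-1])  # top side, +x -> -x
    per.extend(core_ids[:-1, -1][1:])  # hmm placeholder (replaced below)
    # rebuild cleanly:
    per = (
        list(core_ids[0, 0:nc])  # top: (Ax,By) -> (-Ax,By)
        + list(core_ids[0:nc, nc])  # left side going down: (-Ax,By)->(-Ax,-By)
        + list(core_ids[nc, nc:0:-1])  # bottom: (-Ax,-By)->(Ax,-By)
        + list(core_ids[nc:0:-1, 0])  # right side going up
    )
    square_ring = np.array(per, dtype=int)
    assert len(square_ring) == n

    rings: List[Tuple[str, np.ndarray]] = [("core_boundary", square_ring)]

    def add_ring(label: str, pts: np.ndarray) -> np.ndarray:
        ids = np.arange(len(xy), len(xy) + n)
        xy.extend(pts)
        rings.append((label, ids))
        return ids

    # transition rings: blend square boundary -> NP boundary polygon
    sq_xy = np.array([xy[i] for i in square_ring])
    np_xy = ring_xy(s_np)
    for r in range(1, params.n_radial_np + 1):
        t = r / params.n_radial_np
        label = "np_boundary" if r == params.n_radial_np else f"np_transition_{r}"
        add_ring(label, (1.0 - t) * sq_xy + t * np_xy)

    # annulus rings
    s_prev = s_np
    for layer, s_out in enumerate((s1, s2, s3), start=1):
        for r in range(1, params.n_radial_per_annulus_layer + 1):
            t = r / params.n_radial_per_annulus_layer
            s = (1.0 - t) * s_prev + t * s_out
            label = (
                f"annulus_{layer}_outer"
                if r == params.n_radial_per_annulus_layer
                else f"annulus_{layer}_sub{r}"
            )
            add_ring(label, ring_xy(s))
        s_prev = s_out

    xy_arr = np.array(xy)

    # quads: core grid (CCW: u decreases with iu, so order flipped)
    quads: List[Tuple[int, int, int, int]] = []
    region2d: List[int] = []
    for iv in range(nc):
        for iu in range(nc):
            # physical x decreases with iu, y decreases with iv
            q = (
                core_ids[iv + 1, iu + 1],
                core_ids[iv + 1, iu],
                core_ids[iv, iu],
                core_ids[iv, iu + 1],
            )
            quads.append(q)
            region2d.append(0)
    # ring quads between consecutive rings
    ring_layer = {  # which disc region each ring band belongs to
        i: 0 for i in range(1, params.n_radial_np + 1)
    }
    idx = params.n_radial_np
    for layer in range(1, 4):
        for _ in range(params.n_radial_per_annulus_layer):
            idx += 1
            ring_layer[idx] = layer
    for i in range(1, len(rings)):
        inner = rings[i - 1][1]
        outer = rings[i][1]
        for j in range(n):
            jp = (j + 1) % n
            # CCW in xy (viewed from +z): inner_j -> outer_j -> outer_jp -> inner_jp
            quads.append((inner[j], outer[j], outer[jp], inner[jp]))
            region2d.append(ring_layer[i])

    core_center = int(core_ids[nc // 2, nc // 2])
    return (
        xy_arr,
        np.array(quads, dtype=int),
        np.array(region2d, dtype=int),
        rings,
        core_center,
        (a, b),
    )


def _check_quads_ccw(xy: np.ndarray, quads: np.ndarray) -> None:
    p = xy[quads]  # (Q, 4, 2)
    area2 = np.zeros(len(quads))
    for k in range(4):
        q = (k + 1) % 4
        area2 += p[:, k, 0] * p[:, q, 1] - p[:, q, 0] * p[:, k, 1]
    bad = np.nonzero(area2 <= 0)[0]
    if len(bad):
        raise ValueError(f"cross-section quads with non-positive area: {bad[:5]}")


# ---------------------------------------------------------------------------
# main builder
# ---------------------------------------------------------------------------


def build_motion_segment(params: GeometryParams | None = None) -> Mesh:
    """Construct the two-vertebra motion segment mesh at the printed dimensions.

    Raises ``ValueError`` for invalid parameter sets or if the requested
    resolution produces inverted hexahedra.
    """
    params = params or GeometryParams()
    params.validate()

    xy, quads, region2d, rings, core_center, (a, b) = _cross_section(params)
    _check_quads_ccw(xy, quads)
    n2d = len(xy)
    n = params.n_circumferential

    H = params.disc_height
    cep = params.cep_thickness
    Hv = params.vertebra_height
    z_disc_bot, z_disc_top = -0.5 * H, 0.5 * H
    core_bot, core_top = z_disc_bot + cep, z_disc_top - cep

    stations: List[float] = []
    layer_kind: List[str] = []  # kind of the layer *above* station i

    def add_span(z0, z1, nlayers, kind):
        zs = np.linspace(z0, z1, nlayers + 1)
        if not stations:
            stations.append(zs[0])
        for z in zs[1:]:
            stations.append(float(z))
            layer_kind.append(kind)

    # the bony vertebral endplate (cortical) caps each body against the CEP
    t_ep = min(params.bony_endplate_thickness, 0.5 * Hv)
    add_span(z_disc_bot - Hv, z_disc_bot - t_ep, params.n_axial_vertebra, "L5")
    add_span(z_disc_bot - t_ep, z_disc_bot, 1, "L5_ep")
    add_span(z_disc_bot, core_bot, 1, "cep_lower")
    add_span(core_bot, core_top, params.n_axial_disc, "disc")
    add_span(core_top, z_disc_top, 1, "cep_upper")
    add_span(z_disc_top, z_disc_top + t_ep, 1, "L4_ep")
    add_span(z_disc_top + t_ep, z_disc_top + Hv, params.n_axial_vertebra, "L4")

    z_stations = np.array(stations)
    n_st = len(z_stations)

    nodes = np.empty((n_st * n2d, 3))
    for k, z in enumerate(z_stations):
        nodes[k * n2d : (k + 1) * n2d, :2] = xy
        nodes[k * n2d : (k + 1) * n2d, 2] = z

    # outermost ring band of quads acts as the cortical shell in vertebrae
    outer_band = np.arange(len(quads) - n, len(quads))
    is_outer = np.zeros(len(quads), dtype=bool)
    is_outer[outer_band] = True
    disc_region_of = {
        0: REGION_ID["np"],
        1: REGION_ID["annulus_layer1"],
        2: REGION_ID["annulus_layer2"],
        3: REGION_ID["annulus_layer3"],
    }

    hex_list = []
    hex_region = []
    for k, kind in enumerate(layer_kind):
        lo, hi = k * n2d, (k + 1) * n2d
        for q, (q0, q1, q2, q3) in enumerate(quads):
            hex_list.append(
                (lo + q0, lo + q1, lo + q2, lo + q3, hi + q0, hi + q1, hi + q2, hi + q3)
            )
            if kind == "disc":
                rid = disc_region_of[int(region2d[q])]
            elif kind == "cep_lower":
                rid = REGION_ID["cep_lower"]
            elif kind == "cep_upper":
                rid = REGION_ID["cep_upper"]
            elif kind == "L4_ep":
                rid = REGION_ID["cortical_L4"]
            elif kind == "L5_ep":
                rid = REGION_ID["cortical_L5"]
            elif kind == "L4":
                rid = REGION_ID["cortical_L4" if is_outer[q] else "cancellous_L4"]
            else:
                rid = REGION_ID["cortical_L5" if is_outer[q] else "cancellous_L5"]
            hex_region.append(rid)

    hexes = np.array(hex_list, dtype=int)
    hex_region = np.array(hex_region, dtype=int)

    detJ = jacobians(nodes[hexes])
    bad = np.nonzero(detJ.min(axis=1) <= 0)[0]
    if len(bad):
        raise ValueError(
            f"resolution produces inverted hexahedra (first offender: element "
            f"{bad[0]}, region {REGION_NAMES[hex_region[bad[0]]]})"
        )

    # ----- node sets -------------------------------------------------------
    ring_map = dict(rings)
    outer_ring = ring_map["annulus_3_outer"]
    s1_ring = ring_map["annulus_1_outer"]
    s2_ring = ring_map["annulus_2_outer"]
    np_ring = ring_map["np_boundary"]
    sq_ring = ring_map["core_boundary"]

    def at_station(ids2d, k):
        return np.asarray(ids2d, dtype=int) + k * n2d

    top_k = n_st - 1
    node_sets: Dict[str, np.ndarray] = {}
    node_sets["l5_bottom"] = at_station(np.arange(n2d), 0)
    node_sets["l4_top"] = at_station(np.arange(n2d), top_k)

    stride = n // 8
    sub8 = np.arange(0, n, stride)
    node_sets["l4_top_cortical_points"] = at_station(outer_ring[sub8], top_k)
    canc = np.concatenate(
        [sq_ring[sub8], np_ring[sub8], s1_ring[sub8], s2_ring[sub8]]
    )
    node_sets["l4_top_cancellous_points"] = at_station(canc, top_k)

    def nearest_on_ring(ring_ids, azimuth_deg):
        ang = np.degrees(
            np.arctan2(xy[ring_ids, 1] / b, xy[ring_ids, 0] / a)
        ) % 360.0
        d = np.abs((ang - azimuth_deg + 180.0) % 360.0 - 180.0)
        return int(ring_ids[np.argmin(d)])

    # CEP representative sites on the disc-facing surface of each endplate
    k_cep_up = int(np.argmin(np.abs(z_stations - core_top)))
    k_cep_lo = int(np.argmin(np.abs(z_stations - core_bot)))
    site_2d = {
        "anterior_central": nearest_on_ring(s1_ring, 90.0),
        "central": core_center,
        "posterior_central": nearest_on_ring(s1_ring, 270.0),
        "left_margin": nearest_on_ring(outer_ring, 0.0),
        "right_margin": nearest_on_ring(outer_ring, 180.0),
    }
    for site, nid in site_2d.items():
        node_sets[f"cep_upper_{site}"] = at_station([nid], k_cep_up)
        node_sets[f"cep_lower_{site}"] = at_station([nid], k_cep_lo)

    k_mid = int(np.argmin(np.abs(z_stations)))
    az = params.posterior_lateral_azimuth_deg
    for layer, ring in ((1, s1_ring), (2, s2_ring), (3, outer_ring)):
        nid = nearest_on_ring(ring, az)
        node_sets[f"posterior_lateral_annulus_layer_{layer}"] = at_station(
            [nid], k_mid
        )
    node_sets["disc_center"] = at_station([core_center], k_mid)

    # ----- ligaments -------------------------------------------------------
    k_l4_bot = top_k - params.n_axial_vertebra - 1  # station at z = +H/2
    k_l5_top = params.n_axial_vertebra + 1  # station at z = -H/2
    trusses, t_region, t_area = [], [], []
    for lig in params.ligament_spec:
        off = min(lig.ring_offset, params.n_axial_vertebra)
        per_truss = lig.area_mm2 / len(lig.azimuths_deg)
        for azd in lig.azimuths_deg:
            nid2d = nearest_on_ring(outer_ring, azd)
            n_up = int(at_station([nid2d], k_l4_bot + off)[0])
            n_dn = int(at_station([nid2d], k_l5_top - off)[0])
            trusses.append((n_dn, n_up))
            t_region.append(REGION_ID[f"ligament_{lig.name}"])
            t_area.append(per_truss)

    trusses = np.array(trusses, dtype=int).reshape(-1, 2)
    t_region = np.array(t_region, dtype=int)
    t_area = np.array(t_area)
    tension = np.ones(len(trusses), dtype=bool)

    mesh = Mesh(
        nodes=nodes,
        hexes=hexes,
        hex_region=hex_region,
        trusses=trusses,
        truss_region=t_region,
        truss_area=t_area,
        truss_tension_only=tension,
        node_sets=node_sets,
        meta={
            "params": params,
            "n2d": n2d,
            "xy": xy,
            "quads": quads,
            "region2d": region2d,
            "rings": rings,
            "z_stations": z_stations,
            "layer_kind": layer_kind,
            "semi_axes": (a, b),
            "core_bot": core_bot,
            "core_top": core_top,
            "n_quads": len(quads),
        },
    )
    _check_load_points(mesh)
    return mesh


def _check_load_points(mesh: Mesh) -> None:
    c = mesh.node_sets["l4_top_cortical_points"]
    s = mesh.node_sets["l4_top_cancellous_points"]
    if len(np.intersect1d(c, s)) or len(c) + len(s) != 40:
        raise AssertionError("load point sets must be 40 disjoint ids")


# ---------------------------------------------------------------------------
# annulus fibers
# ---------------------------------------------------------------------------


def generate_fibers(mesh: Mesh, params: GeometryParams | None = None) -> Mesh:
    """Add criss-cross +/- fiber_angle_deg truss helices to the annulus layers.

    Fibers get their own node chains on each layer's mid-radial surface and
    are embedded kinematically in their host hexes (trilinear weights), so
    every segment meets the requested angle to the transverse plane exactly,
    independent of element aspect ratio.  Mutates and returns ``mesh``.
    """
    params = params or mesh.meta["params"]
    meta = mesh.meta
    n = params.n_circumferential
    quads = meta["quads"]
    xy = meta["xy"]
    rings = meta["rings"]
    z_st = meta["z_stations"]
    layer_kind = meta["layer_kind"]
    n2d = meta["n2d"]
    nq = meta["n_quads"]
    core_bot, core_top = meta["core_bot"], meta["core_top"]

    disc_layer_idx = [k for k, kind in enumerate(layer_kind) if kind == "disc"]
    if not disc_layer_idx:
        raise ValueError("mesh has no disc core layers to host fibers")
    tan_a = np.tan(np.radians(params.fiber_angle_deg))

    # ring index bookkeeping: rings[0] = core boundary, then n_radial_np
    # transition rings, then annulus sub-rings
    nrnp = params.n_radial_np
    nrpl = params.n_radial_per_annulus_layer

    new_nodes: List[np.ndarray] = []
    emb_hosts: List[np.ndarray] = []
    emb_w: List[np.ndarray] = []
    fib_trusses: List[Tuple[int, int]] = []
    fib_region: List[int] = []
    fib_len_per_layer = {1: 0.0, 2: 0.0, 3: 0.0}
    counts = {(1, +1): 0, (1, -1): 0, (2, +1): 0, (2, -1): 0, (3, +1): 0, (3, -1): 0}

    n_mesh_nodes = mesh.n_nodes

    for layer in (1, 2, 3):
        # radial sub-ring of the layer that contains the mid-surface
        first_ring = nrnp + (layer - 1) * nrpl  # rings[] index of inner boundary
        sub = nrpl // 2  # 0-based sub-ring containing the middle (xi_r set below)
        inner_ids = rings[first_ring + sub][1]
        outer_ids = rings[first_ring + sub + 1][1]
        if nrpl % 2 == 1:
            t_r = 0.5
        else:
            t_r = 0.0  # mid-surface coincides with a ring; use inner edge of sub
            sub = nrpl // 2
            inner_ids = rings[first_ring + sub][1]
            outer_ids = rings[first_ring + sub + 1][1]
        xi_r = 2.0 * t_r - 1.0

        # 2D quad index of the hosting sub-ring band, per angular position j:
        # ring bands were appended after the core grid in ring order
        nc = n // 4
        core_quads = nc * nc
        band = first_ring + sub  # 0-based band index (band i between rings i,i+1)
        quad_of_j = core_quads + band * n + np.arange(n)

        mid_xy = (1.0 - t_r) * xy[inner_ids] + t_r * xy[outer_ids]
        chord = np.linalg.norm(mid_xy[(np.arange(n) + 1) % n] - mid_xy, axis=1)

        vol_layer = 0.0  # filled after total length known

        for family in (+1, -1):
            for j0 in range(n):
                chain = _march_helix(
                    j0, family, mid_xy, chord, tan_a, core_bot, core_top, n
                )
                if len(chain) < 2:
                    continue
                counts[(layer, family)] += 1
                ids = []
                for (theta_t, jj, z) in chain:
                    nid = n_mesh_nodes + len(new_nodes)
                    hosts, w, pos = _embed_point(
                        jj, theta_t, z, xi_r, quad_of_j, quads, xy,
                        z_st, disc_layer_idx, n2d, nq,
                    )
                    new_nodes.append(pos)
                    emb_hosts.append(hosts)
                    emb_w.append(w)
                    ids.append(nid)
                for k in range(len(ids) - 1):
                    fib_trusses.append((ids[k], ids[k + 1]))
                    fib_region.append(REGION_ID[f"annulus_fiber_layer{layer}"])
                    p0 = new_nodes[ids[k] - n_mesh_nodes]
                    p1 = new_nodes[ids[k + 1] - n_mesh_nodes]
                    fib_len_per_layer[layer] += float(np.linalg.norm(p1 - p0))

    for layer in (1, 2, 3):
        if counts[(layer, +1)] != counts[(layer, -1)]:
            raise AssertionError("fiber family counts must match per layer")
        if counts[(layer, +1)] == 0:
            raise ValueError(f"annulus layer {layer} too coarse to host fibers")

    # fiber cross-section area from the target volume fraction
    areas_2d = region_areas(mesh, 0.5 * (core_bot + core_top))
    fib_area = {}
    for layer in (1, 2, 3):
        v_layer = areas_2d[f"annulus_layer{layer}"] * (core_top - core_bot)
        L = fib_len_per_layer[layer]
        fib_area[layer] = params.fiber_volume_fraction * v_layer / L if L else 0.0
        mesh.fiber_volume_per_layer[f"annulus_fiber_layer{layer}"] = (
            fib_area[layer] * L
        )

    fib_trusses = np.array(fib_trusses, dtype=int)
    fib_region_arr = np.array(fib_region, dtype=int)
    fib_areas = np.array(
        [fib_area[int(REGION_NAMES[r].rsplit("layer", 1)[1])] for r in fib_region]
    )

    mesh.nodes = np.vstack([mesh.nodes, np.array(new_nodes)])
    mesh.trusses = np.vstack([mesh.trusses, fib_trusses])
    mesh.truss_region = np.concatenate([mesh.truss_region, fib_region_arr])
    mesh.truss_area = np.concatenate([mesh.truss_area, fib_areas])
    mesh.truss_tension_only = np.concatenate(
        [mesh.truss_tension_only, np.ones(len(fib_trusses), dtype=bool)]
    )
    mesh.embedded_nodes = np.arange(n_mesh_nodes, mesh.n_nodes)
    mesh.embedded_hosts = np.array(emb_hosts, dtype=int)
    mesh.embedded_weights = np.array(emb_w)
    return mesh


def _march_helix(j0, family, mid_xy, chord, tan_a, z_bot, z_top, n):
    """March one fiber helix; returns [(t_in_element, j, z), ...] vertices.

    Each vertex sits at angular position j + t (t in [0,1) within element j
    for the +1 family; for -1 the chain steps to decreasing j).
    """
    chain = [(0.0, j0, z_bot)]
    z = z_bot
    j = j0
    if tan_a < 1e-12:
        # degenerate flat fibers: one full circumferential loop at z_bot
        for _ in range(n):
            j = (j + family) % n
            chain.append((0.0, j, z_bot))
        return chain
    for _ in range(10 * n + 100):
        c = chord[j] if family == +1 else chord[(j - 1) % n]
        dz = c * tan_a
        if z + dz >= z_top - 1e-12:
            frac = (z_top - z) / dz
            if family == +1:
                chain.append((frac, j, z_top))
            else:
                chain.append((1.0 - frac, (j - 1) % n, z_top))
            break
        z += dz
        j = (j + family) % n
        chain.append((0.0, j, z))
    return chain


def _embed_point(j, t, z, xi_r, quad_of_j, quads, xy, z_st, disc_layers, n2d, nq):
    """Trilinear embedding of a fiber vertex at angular element j, fraction t,
    height z, radial natural coordinate xi_r.  Returns (host ids, weights, xyz).
    """
    # axial layer containing z
    kz = None
    for k in disc_layers:
        if z_st[k] - 1e-9 <= z <= z_st[k + 1] + 1e-9:
            kz = k
            if z < z_st[k + 1]:
                break
    z0, z1 = z_st[kz], z_st[kz + 1]
    xi_z = 2.0 * (z - z0) / (z1 - z0) - 1.0
    xi_t = 2.0 * t - 1.0

    q2d = quads[quad_of_j[j]]  # (inner_j, outer_j, outer_jp, inner_jp)
    lo = kz * n2d
    hi = (kz + 1) * n2d
    hosts = np.array([lo + q2d[0], lo + q2d[1], lo + q2d[2], lo + q2d[3],
                      hi + q2d[0], hi + q2d[1], hi + q2d[2], hi + q2d[3]])
    # corner order (inner_j, outer_j, outer_jp, inner_jp): xi_t along j->jp,
    # xi_r from inner (-1) to outer (+1)
    n4 = np.array(
        [
            0.25 * (1 - xi_t) * (1 - xi_r),
            0.25 * (1 - xi_t) * (1 + xi_r),
            0.25 * (1 + xi_t) * (1 + xi_r),
            0.25 * (1 + xi_t) * (1 - xi_r),
        ]
    )
    w = np.concatenate([n4 * 0.5 * (1 - xi_z), n4 * 0.5 * (1 + xi_z)])
    pos2d = n4 @ xy[list(q2d)]
    return hosts, w, np.array([pos2d[0], pos2d[1], z])


# ---------------------------------------------------------------------------
# validation helper
# ---------------------------------------------------------------------------


def region_areas(mesh: Mesh, z: float) -> Dict[str, float]:
    """Cross-sectional area of every hex region cut by the plane at height z.

    Assumes vertically extruded hexes (true for this builder): each cut
    element contributes the shoelace area of its four vertical edges
    interpolated at z.  Regions not intersected report 0.
    """
    nodes, hexes = mesh.nodes, mesh.hexes
    zmin = nodes[hexes, 2].min()
    zmax = nodes[hexes, 2].max()
    if not zmin <= z <= zmax:
        raise ValueError(f"plane z={z} outside mesh z-range [{zmin}, {zmax}]")

    zb = nodes[hexes[:, 0], 2]
    zt = nodes[hexes[:, 4], 2]
    sel = (zb - 1e-9 <= z) & (z < zt - 1e-9)
    if not sel.any():  # z at the very top
        sel = (zb - 1e-9 <= z) & (z <= zt + 1e-9)
    areas = {name: 0.0 for name in REGION_NAMES}
    hsel = np.nonzero(sel)[0]
    frac = (z - zb[hsel]) / (zt[hsel] - zb[hsel])
    p_bot = nodes[hexes[hsel, :4], :2]  # (E, 4, 2)
    p_top = nodes[hexes[hsel, 4:], :2]
    p = p_bot + frac[:, None, None] * (p_top - p_bot)
    a2 = np.zeros(len(hsel))
    for k in range(4):
        q = (k + 1) % 4
        a2 += p[:, k, 0] * p[:, q, 1] - p[:, q, 0] * p[:, k, 1]
    cut_area = 0.5 * np.abs(a2)
    for rid in np.unique(mesh.hex_region[hsel]):
        areas[REGION_NAMES[rid]] = float(
            cut_area[mesh.hex_region[hsel] == rid].sum()
        )
    return areas
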