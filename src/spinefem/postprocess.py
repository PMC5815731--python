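"""Output metrics: endplate site stresses, percent increases, disc bulge,
axial displacement, internal disc stress, and the NP pressure diagnostic.

"Peak" endplate stress is the maximum of the nodal-averaged von Mises
stress over the ten representative sites (five per endplate: central,
anterior-central, posterior-central, left and right margin); the global
endplate maximum is reported alongside for transparency.  Nodal averaging
is restricted to endplate elements so adjacent bone does not contaminate
the cartilage values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from .fem import SolutionField, nodal_von_mises, von_mises
from .geometry import CEP_SITE_NAMES, Mesh

__all__ = [
    "StressReport",
    "cep_site_stresses",
    "percent_increase",
    "bulge_displacement",
    "axial_displacement",
    "disc_center_stress",
    "np_mean_pressure",
    "make_report",
]


@dataclass
class StressReport:
    """All scalar outputs for one (condition, motion state) solve."""

    condition: str
    motion_state: str
    cep_site_stress: Dict[str, float]  # 10 sites -> von Mises MPa
    cep_peak: float  # max over the 10 sites
    cep_global_max: float  # max nodal value anywhere on either endplate
    upper_cep_max: float  # max over the 5 upper sites
    lower_cep_max: float
    bulge_displacement: float  # mm
    axial_displacement: float  # mm (magnitude of mean top-surface uz)
    disc_center_vm: float  # MPa
    disc_center_axial: float  # MPa (sigma_zz, signed)
    np_mean_pressure: float  # MPa, diagnostic
    percent_increase_vs_normal: Optional[float] = None
    iterations: int = 0
    residual: float = 0.0


def cep_site_stresses(solution: SolutionField, mesh: Mesh) -> Dict[str, float]:
    """Nodal-averaged von Mises at the ten representative endplate sites."""
    out: Dict[str, float] = {}
    for side, region in (("upper", "cep_upper"), ("lower", "cep_lower")):
        vm = nodal_von_mises(mesh, solution, regions=(region,))
        for site in CEP_SITE_NAMES:
            name = f"cep_{side}_{site}"
            ids = mesh.node_sets.get(name)
            if ids is None or len(ids) == 0:
                raise KeyError(f"missing endplate site node set '{name}'")
            out[name] = float(vm[ids].mean())
    return out


def percent_increase(condition_peak: float, normal_peak: float) -> float:
    """100 * (condition - normal) / normal, %."""
    if normal_peak <= 0:
        raise ValueError(f"normal peak must be > 0, got {normal_peak}")
    return 100.0 * (condition_peak - normal_peak) / normal_peak


def bulge_displacement(solution: SolutionField, mesh: Mesh) -> float:
    """Mean posterior-directed Y-displacement magnitude (mm) over the three
    posterior-lateral annulus layer points."""
    vals = []
    for layer in (1, 2, 3):
        name = f"posterior_lateral_annulus_layer_{layer}"
        ids = mesh.node_sets.get(name)
        if ids is None or len(ids) == 0:
            raise KeyError(f"missing node set '{name}'")
        # +Y is anterior, so posterior (outward) bulge is -uy at these points
        vals.append(float(np.abs(solution.u[ids, 1]).mean()))
    return float(np.mean(vals))


def axial_displacement(solution: SolutionField, mesh: Mesh) -> float:
    """Magnitude of the mean Z-displacement over the 40 top load points (mm)."""
    ids = np.concatenate(
        [
            mesh.node_set("l4_top_cortical_points"),
            mesh.node_set("l4_top_cancellous_points"),
        ]
    )
    return float(abs(solution.u[ids, 2].mean()))


def disc_center_stress(solution: SolutionField, mesh: Mesh):
    """(von Mises, axial sigma_zz) at the disc-center node, MPa.

    Averaged over the NP elements adjacent to the node; both the equivalent
    stress and the signed axial component are reported because the internal
    disc metric is an axial compressive stress.
    """
    ids = mesh.node_set("disc_center")
    vm = nodal_von_mises(mesh, solution, regions=("np",))
    # nodal-averaged sigma_zz over adjacent active NP elements
    from .geometry import REGION_ID

    sel = np.nonzero(
        solution.hex_active & (mesh.hex_region == REGION_ID["np"])
    )[0]
    szz_sum = np.zeros(mesh.n_nodes)
    wt = np.zeros(mesh.n_nodes)
    for e in sel:
        szz_sum[mesh.hexes[e]] += solution.element_stress[e, 2]
        wt[mesh.hexes[e]] += 1.0
    szz = np.where(wt > 0, szz_sum / np.maximum(wt, 1.0), 0.0)
    return float(vm[ids].mean()), float(szz[ids].mean())


def np_mean_pressure(solution: SolutionField, mesh: Mesh) -> float:
    """Volume-weighted mean hydrostatic pressure -tr(sigma)/3 in the NP (MPa).

    Diagnostic: in the healthy disc this should sit near 1.5x the applied
    axial stress; it is reported and logged, never a hard pass/fail.
    """
    from .elements import jacobians
    from .geometry import REGION_ID

    sel = np.nonzero(
        solution.hex_active & (mesh.hex_region == REGION_ID["np"])
    )[0]
    if len(sel) == 0:
        return 0.0
    vols = jacobians(mesh.nodes[mesh.hexes[sel]]).sum(axis=1)
    p = -solution.element_stress[sel, :3].sum(axis=1) / 3.0
    return float((p * vols).sum() / vols.sum())


def make_report(
    condition: str,
    motion_state: str,
    solution: SolutionField,
    mesh: Mesh,
    normal_peak: Optional[float] = None,
) -> StressReport:
    """Assemble the full scalar report for one solve."""
    sites = cep_site_stresses(solution, mesh)
    upper = max(v for k, v in sites.items() if k.startswith("cep_upper"))
    lower = max(v for k, v in sites.items() if k.startswith("cep_lower"))
    peak = max(upper, lower)
    vm_up = nodal_von_mises(mesh, solution, regions=("cep_upper",))
    vm_lo = nodal_von_mises(mesh, solution, regions=("cep_lower",))
    global_max = float(max(vm_up.max(), vm_lo.max()))
    dc_vm, dc_zz = disc_center_stress(solution, mesh)
    pct = (
        percent_increase(peak, normal_peak) if normal_peak is not None else None
    )
    return StressReport(
        condition=condition,
        motion_state=motion_state,
        cep_site_stress=sites,
        cep_peak=peak,
        cep_global_max=global_max,
        upper_cep_max=upper,
        lower_cep_max=lower,
        bulge_displacement=bulge_displacement(solution, mesh),
        axial_displacement=axial_displacement(solution, mesh),
        disc_center_vm=dc_vm,
        disc_center_axial=dc_zz,
        np_mean_pressure=np_mean_pressure(solution, mesh),
        percent_increase_vs_normal=pct,
        iterations=solution.iterations,
        residual=solution.residual,
    )
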