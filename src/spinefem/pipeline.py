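"""Study orchestration: the 4-condition x 5-motion-state comparison and the
1000-6000 N verification sweep, driven by a single validated config.

One mesh is shared across all conditions (only materials change; nucleus
removal deactivates the NP elements), so site-wise endplate comparisons
are node-identical.  Reports are CSV + JSON; VTK fields and bar-chart
figures are optional outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Dict, List, Literal, Optional, Tuple

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import geometry
from .fem import solve_static
from .geometry import GeometryParams, Mesh, build_motion_segment, generate_fibers
from .loads import MOTION_STATES, load_audit, make_motion_state, make_sweep
from .materials import DiscCondition, MaterialConfig, condition_materials
from .postprocess import StressReport, make_report

log = logging.getLogger(__name__)

__all__ = ["StudyConfig", "run_study", "run_verification", "build_study_mesh"]

RESOLUTION_PRESETS: Dict[str, Dict[str, int]] = {
    "coarse": dict(
        n_circumferential=8, n_radial_np=1, n_radial_per_annulus_layer=1,
        n_axial_disc=2, n_axial_vertebra=2,
    ),
    "default": dict(
        n_circumferential=16, n_radial_np=2, n_radial_per_annulus_layer=1,
        n_axial_disc=4, n_axial_vertebra=3,
    ),
    "fine": dict(
        n_circumferential=32, n_radial_np=4, n_radial_per_annulus_layer=2,
        n_axial_disc=8, n_axial_vertebra=6,
    ),
}


class GeometryBlock(BaseModel):
    """Overrides for the geometric parameters (all optional)."""

    model_config = ConfigDict(extra="forbid")

    disc_height: float = 12.0
    disc_area: float = 1300.0
    np_area_fraction: float = 0.381
    annulus_layer_area_fractions: Tuple[float, float, float] = (0.25, 0.21, 0.165)
    fiber_angle_deg: float = 30.0
    cep_thickness: float = 0.6
    vertebra_height: float = 28.0
    cortical_shell_thickness: float = 1.0
    ellipse_aspect: float = 0.7
    posterior_lateral_azimuth_deg: float = 315.0
    fiber_volume_fraction: float = 0.15


class MaterialBlock(BaseModel):
    """Overrides for bone/CEP/ligament/implant defaults."""

    model_config = ConfigDict(extra="forbid")

    cortical_E: float = 12000.0
    cortical_nu: float = 0.3
    cancellous_E: float = 100.0
    cancellous_nu: float = 0.2
    cep_E: float = 23.8
    cep_nu: float = 0.4
    fiber_E: float = 500.0
    fiber_nu: float = 0.3
    implant_E: float = 1.25
    implant_nu: float = 0.30
    normal_np_nu: float = 0.49  # 0.4999 selectable for the near-incompressible NP
    ligament_E: Optional[Dict[str, float]] = None


class LoadBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    axial_force: float = 500.0  # N
    torque_nm: float = 7.5
    cortical_cancellous_ratio: Tuple[float, float] = (3.0, 1.0)
    sweep_loads: Tuple[float, ...] = (1000.0, 2000.0, 3000.0, 4000.0, 5000.0, 6000.0)
    flip_sagittal_moment: bool = False


class StudyConfig(BaseModel):
    """Validated run configuration; unknown keys are rejected by name."""

    model_config = ConfigDict(extra="forbid")

    geometry: GeometryBlock = Field(default_factory=GeometryBlock)
    materials: MaterialBlock = Field(default_factory=MaterialBlock)
    loads: LoadBlock = Field(default_factory=LoadBlock)
    resolution: Literal["coarse", "default", "fine"] = "default"
    conditions: Tuple[str, ...] = tuple(c.value for c in DiscCondition)
    states: Tuple[str, ...] = MOTION_STATES
    out_dir: str = "spinefem_out"
    seed: int = 0
    mesh_jitter: float = 0.0  # mm, optional random node perturbation
    figures: bool = False
    write_vtk: bool = False
    verbosity: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(self.model_dump_json()), fh, sort_keys=False)

    def geometry_params(self) -> GeometryParams:
        return GeometryParams(
            **self.geometry.model_dump(),
            **RESOLUTION_PRESETS[self.resolution],
        )

    def material_config(self) -> MaterialConfig:
        kw = self.materials.model_dump()
        lig = kw.pop("ligament_E")
        cfg = MaterialConfig(**kw)
        if lig:
            cfg.ligament_E.update(lig)
        return cfg

    def digest(self) -> str:
        return hashlib.sha256(self.model_dump_json().encode()).hexdigest()[:12]


def build_study_mesh(config: StudyConfig) -> Mesh:
    """Build the shared segment mesh (with fibers) for a config."""
    params = config.geometry_params()
    mesh = build_motion_segment(params)
    mesh = generate_fibers(mesh, params)
    if config.mesh_jitter > 0:
        _jitter(mesh, config.mesh_jitter, config.seed)
    return mesh


def _jitter(mesh: Mesh, amplitude: float, seed: int) -> None:
    """Perturb interior nodes for robustness experiments (never default)."""
    rng = np.random.default_rng(seed)
    protected = np.zeros(mesh.n_nodes, dtype=bool)
    for ids in mesh.node_sets.values():
        protected[ids] = True
    protected[mesh.embedded_nodes] = True
    free = ~protected
    mesh.nodes[free] += rng.uniform(-amplitude, amplitude, (free.sum(), 3))


def _report_row(rep: StressReport) -> dict:
    row = {
        "condition": rep.condition,
        "motion_state": rep.motion_state,
        "cep_peak_MPa": rep.cep_peak,
        "cep_global_max_MPa": rep.cep_global_max,
        "upper_cep_max_MPa": rep.upper_cep_max,
        "lower_cep_max_MPa": rep.lower_cep_max,
        "percent_increase_vs_normal": rep.percent_increase_vs_normal,
        "bulge_mm": rep.bulge_displacement,
        "axial_displacement_mm": rep.axial_displacement,
        "disc_center_vm_MPa": rep.disc_center_vm,
        "disc_center_axial_MPa": rep.disc_center_axial,
        "np_mean_pressure_MPa": rep.np_mean_pressure,
        "iterations": rep.iterations,
        "residual": rep.residual,
    }
    row.update({f"site_{k}_MPa": v for k, v in rep.cep_site_stress.items()})
    return row


def run_study(
    config: StudyConfig,
    mesh: Optional[Mesh] = None,
) -> Tuple[pd.DataFrame, Dict[str, StressReport]]:
    """Solve every requested condition x motion state on a shared mesh.

    Returns the report table and the keyed StressReport map; writes
    CSV/JSON (and optional VTK/figures) under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mesh = mesh if mesh is not None else build_study_mesh(config)
    mat_cfg = config.material_config()

    conditions = [DiscCondition(c) for c in config.conditions]
    # the normal condition must be solved for percent increases; solve it first
    ordered = sorted(conditions, key=lambda c: c is not DiscCondition.normal)

    reports: Dict[str, StressReport] = {}
    normal_peaks: Dict[str, float] = {}
    audit_log = []
    for cond in ordered:
        materials = condition_materials(cond, mat_cfg)
        for state in config.states:
            case = make_motion_state(
                mesh,
                state,
                axial=config.loads.axial_force,
                torque_nm=config.loads.torque_nm,
                ratio=config.loads.cortical_cancellous_ratio,
                flip_sagittal_moment=config.loads.flip_sagittal_moment,
            )
            audit_log.append(load_audit(mesh, case))
            try:
                sol = solve_static(mesh, materials, case.system)
            except Exception as exc:
                _dump_partial(out, reports, audit_log, config)
                raise RuntimeError(
                    f"solve failed for condition={cond.value}, state={state}: {exc}"
                ) from exc
            rep = make_report(
                cond.value, state, sol, mesh,
                normal_peak=normal_peaks.get(state),
            )
            if cond is DiscCondition.normal:
                normal_peaks[state] = rep.cep_peak
                rep.percent_increase_vs_normal = 0.0
            reports[f"{cond.value}/{state}"] = rep
            if config.write_vtk:
                from .vtkio import write_vtk_solution

                write_vtk_solution(
                    out / f"field_{cond.value}_{state}.vtk", mesh, sol
                )
            if config.verbosity:
                log.info(
                    "%s/%s: cep_peak=%.4f MPa, bulge=%.4f mm, iters=%d",
                    cond.value, state, rep.cep_peak,
                    rep.bulge_displacement, sol.iterations,
                )

    df = pd.DataFrame([_report_row(r) for r in reports.values()])
    df.to_csv(out / "study_report.csv", index=False)
    summary = {
        "config_digest": config.digest(),
        "material_config": asdict(mat_cfg),
        "load_audit": audit_log,
        "reports": {k: _report_row(r) for k, r in reports.items()},
        "np_pressure_diagnostic": _np_pressure_diagnostic(config, reports),
    }
    (out / "study_report.json").write_text(json.dumps(summary, indent=2))
    if config.figures:
        _figures(out, df)
    return df, reports


def _np_pressure_diagnostic(config, reports) -> dict:
    """Soft check: normal-condition NP pressure vs 1.5x the nominal applied
    axial stress under compression."""
    key = "normal/axial_compression"
    if key not in reports:
        return {}
    expected = 1.5 * config.loads.axial_force / config.geometry.disc_area
    got = reports[key].np_mean_pressure
    ok = bool(abs(got - expected) <= 0.30 * expected)
    msg = (
        f"NP mean pressure {got:.3f} MPa vs 1.5 x axial stress "
        f"{expected:.3f} MPa ({'within' if ok else 'OUTSIDE'} +/-30% band)"
    )
    log.info(msg)
    return {"np_pressure_MPa": got, "expected_MPa": expected,
            "within_30pct": ok, "message": msg}


def _dump_partial(out: Path, reports, audit_log, config) -> None:
    payload = {
        "FAILED": True,
        "config_digest": config.digest(),
        "load_audit": audit_log,
        "reports": {k: _report_row(r) for k, r in reports.items()},
    }
    (out / "study_report_partial.json").write_text(json.dumps(payload, indent=2))


def run_verification(
    config: StudyConfig,
    mesh: Optional[Mesh] = None,
) -> pd.DataFrame:
    """1000-6000 N sweep on the normal model with linearity statistics.

    Writes ``verification.csv`` (load vs axial displacement, posterior-
    lateral bulge, disc-center stress) and ``verification.json`` with
    slope/intercept/R^2 per curve.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mesh = mesh if mesh is not None else build_study_mesh(config)
    materials = condition_materials(DiscCondition.normal, config.material_config())

    rows = []
    for case in make_sweep(
        mesh, config.loads.sweep_loads, config.loads.cortical_cancellous_ratio
    ):
        sol = solve_static(mesh, materials, case.system)
        rep = make_report("normal", "vertical_sweep", sol, mesh)
        rows.append(
            {
                "load_N": case.axial_force,
                "axial_displacement_mm": rep.axial_displacement,
                "bulge_mm": rep.bulge_displacement,
                "disc_center_vm_MPa": rep.disc_center_vm,
                "disc_center_axial_MPa": rep.disc_center_axial,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(out / "verification.csv", index=False)

    stats = {}
    for col in ("axial_displacement_mm", "bulge_mm", "disc_center_vm_MPa"):
        stats[col] = _linfit(df["load_N"].to_numpy(), df[col].to_numpy())
    (out / "verification.json").write_text(json.dumps(stats, indent=2))
    return df


def _linfit(x: np.ndarray, y: np.ndarray) -> dict:
    from scipy.stats import linregress

    res = linregress(x, y)
    return {
        "slope": res.slope,
        "intercept": res.intercept,
        "r_squared": float(res.rvalue**2),
    }


def _figures(out: Path, df: pd.DataFrame) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(11, 4))
    piv = df.pivot(index="motion_state", columns="condition", values="cep_peak_MPa")
    piv.plot.bar(ax=axes[0], rot=30)
    axes[0].set_ylabel("peak endplate von Mises (MPa)")
    piv2 = df.pivot(index="motion_state", columns="condition", values="bulge_mm")
    piv2.plot.bar(ax=axes[1], rot=30)
    axes[1].set_ylabel("posterior-lateral bulge (mm)")
    fig.tight_layout()
    fig.savefig(out / "study_summary.png", dpi=120)
    plt.close(fig)
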