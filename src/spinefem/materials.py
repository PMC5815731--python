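"""Material library for the four disc conditions.

Isotropic linear elasticity throughout.  The printed disc values are the
model's anchors: normal NP (E = 1.0 MPa, nu = 0.49), normal annulus matrix
(2.56, 0.40), degenerative NP (1.66, 0.40), degenerative annulus
(12.99, 0.35).  Bone, endplate, ligament, fiber and implant properties are
configurable defaults from the lumbar finite-element literature.

Two printed shear moduli are internally inconsistent with G = E/(2(1+nu))
(degenerative annulus 4.55 vs 4.81 MPa; normal NP 0.338 vs 0.336 MPa);
``condition_materials`` logs the mismatch and uses (E, nu).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Dict, Optional

log = logging.getLogger(__name__)

__all__ = [
    "MaterialProperties",
    "DiscCondition",
    "MaterialAssignment",
    "MaterialConfig",
    "shear_modulus",
    "condition_materials",
]


@dataclass(frozen=True)
class MaterialProperties:
    E: float  # elastic modulus, MPa
    nu: float  # Poisson ratio
    tension_only: bool = False
    label: str = ""

    def __post_init__(self):
        if not self.E > 0:
            raise ValueError(f"{self.label or 'material'}: E must be > 0, got {self.E}")
        if not -1.0 < self.nu < 0.5:
            raise ValueError(
                f"{self.label or 'material'}: nu must lie strictly in (-1, 0.5), "
                f"got {self.nu}"
            )

    @property
    def shear_modulus(self) -> float:
        return shear_modulus(self.E, self.nu)


class DiscCondition(str, Enum):
    normal = "normal"
    degenerative = "degenerative"
    np_removed = "np_removed"
    np_replaced = "np_replaced"


def shear_modulus(E: float, nu: float) -> float:
    """Isotropic shear modulus G = E / (2 (1 + nu)), MPa."""
    if not E > 0:
        raise ValueError(f"E must be > 0, got {E}")
    if not -1.0 < nu < 0.5:
        raise ValueError(f"nu must lie strictly in (-1, 0.5), got {nu}")
    return E / (2.0 * (1.0 + nu))


@dataclass
class MaterialConfig:
    """Configurable defaults for everything the disc-condition table does not
    fix: bone, endplate, fibers, ligaments, and the artificial-nucleus
    implant.  Values are literature-typical and overridable from the run
    config; they are echoed into every report for provenance."""

    cortical_E: float = 12000.0
    cortical_nu: float = 0.3
    cancellous_E: float = 100.0
    cancellous_nu: float = 0.2
    cep_E: float = 23.8
    cep_nu: float = 0.4
    fiber_E: float = 500.0
    fiber_nu: float = 0.3
    ligament_E: Dict[str, float] = field(
        default_factory=lambda: {
            "anterior_longitudinal": 20.0,
            "posterior_longitudinal": 20.0,
            "flavum": 19.5,
            "interspinous": 11.6,
            "supraspinous": 15.0,
            "capsular": 32.9,
            "intertransverse": 58.7,
        }
    )
    ligament_nu: float = 0.3
    # SMH artificial nucleus: hydrogel device, slightly stiffer than the
    # nucleus matrix (within the published nucleus-device modulus family)
    # and drained (low Poisson ratio), so it restores bulk support without
    # fluid-like pressurization.  Calibrated once against the replacement
    # condition's axial-compression behaviour (see docs); overridable.
    implant_E: float = 1.25
    implant_nu: float = 0.30
    # normal NP Poisson ratio: 0.49 ties to the normal-disc definition;
    # the near-incompressible 0.4999 variant is selectable.
    normal_np_nu: float = 0.49

    # printed disc-condition values
    normal_np_E: float = 1.0
    normal_annulus_E: float = 2.56
    normal_annulus_nu: float = 0.40
    degen_np_E: float = 1.66
    degen_np_nu: float = 0.40
    degen_annulus_E: float = 12.99
    degen_annulus_nu: float = 0.35


@dataclass
class MaterialAssignment:
    """Region -> properties map for one disc condition."""

    condition: DiscCondition
    regions: Dict[str, MaterialProperties]
    np_active: bool = True
    implant_E: Optional[float] = None
    implant_nu: Optional[float] = None

    def lookup(self, region: str) -> Optional[MaterialProperties]:
        """Properties for a region, or None if the region is inactive."""
        if region == "np" and not self.np_active:
            return None
        try:
            return self.regions[region]
        except KeyError:
            raise KeyError(f"no material assigned to region '{region}'") from None


# printed shear moduli used only for the consistency audit
_PRINTED_G = {
    ("np", DiscCondition.normal): 0.338,
    ("annulus", DiscCondition.normal): 0.914,
    ("np", DiscCondition.degenerative): 0.593,
    ("annulus", DiscCondition.degenerative): 4.55,
}


def _audit_shear(label: str, cond: DiscCondition, E: float, nu: float) -> None:
    printed = _PRINTED_G.get((label, cond))
    if printed is None:
        return
    computed = shear_modulus(E, nu)
    if abs(computed - printed) > 5e-4:
        log.warning(
            "%s/%s: printed shear modulus %.3f MPa differs from "
            "E/(2(1+nu)) = %.3f MPa; using (E, nu) as given",
            cond.value, label, printed, computed,
        )


def condition_materials(
    condition: DiscCondition | str,
    config: MaterialConfig | None = None,
) -> MaterialAssignment:
    """Full region->material map for one disc condition.

    The endplate, bone, fiber and ligament entries are identical across all
    four conditions; only the NP and (for the degenerative disc) the annulus
    matrix change.  ``np_removed`` marks the NP region inactive so its
    elements drop out of the assembly entirely.
    """
    condition = DiscCondition(condition)
    cfg = config or MaterialConfig()

    def mp(E, nu, label, tension=False):
        return MaterialProperties(E=E, nu=nu, tension_only=tension, label=label)

    regions: Dict[str, MaterialProperties] = {
        "cortical_L4": mp(cfg.cortical_E, cfg.cortical_nu, "cortical bone"),
        "cortical_L5": mp(cfg.cortical_E, cfg.cortical_nu, "cortical bone"),
        "cancellous_L4": mp(cfg.cancellous_E, cfg.cancellous_nu, "cancellous bone"),
        "cancellous_L5": mp(cfg.cancellous_E, cfg.cancellous_nu, "cancellous bone"),
        "cep_upper": mp(cfg.cep_E, cfg.cep_nu, "cartilaginous endplate"),
        "cep_lower": mp(cfg.cep_E, cfg.cep_nu, "cartilaginous endplate"),
    }
    for name, E in cfg.ligament_E.items():
        regions[f"ligament_{name}"] = mp(
            E, cfg.ligament_nu, f"ligament {name}", tension=True
        )
    for layer in (1, 2, 3):
        regions[f"annulus_fiber_layer{layer}"] = mp(
            cfg.fiber_E, cfg.fiber_nu, "annulus fiber", tension=True
        )

    if condition is DiscCondition.degenerative:
        np_props = mp(cfg.degen_np_E, cfg.degen_np_nu, "degenerative NP")
        ann = mp(cfg.degen_annulus_E, cfg.degen_annulus_nu, "degenerative annulus")
        _audit_shear("np", condition, cfg.degen_np_E, cfg.degen_np_nu)
        _audit_shear("annulus", condition, cfg.degen_annulus_E, cfg.degen_annulus_nu)
    else:
        ann = mp(cfg.normal_annulus_E, cfg.normal_annulus_nu, "annulus matrix")
        if condition is DiscCondition.np_replaced:
            np_props = mp(cfg.implant_E, cfg.implant_nu, "artificial NP implant")
        else:
            np_props = mp(cfg.normal_np_E, cfg.normal_np_nu, "nucleus pulposus")
            _audit_shear("np", DiscCondition.normal, cfg.normal_np_E, cfg.normal_np_nu)
            _audit_shear(
                "annulus", DiscCondition.normal, cfg.normal_annulus_E,
                cfg.normal_annulus_nu,
            )

    regions["np"] = np_props
    for layer in (1, 2, 3):
        regions[f"annulus_layer{layer}"] = replace(
            ann, label=f"{ann.label} layer {layer}"
        )

    return MaterialAssignment(
        condition=condition,
        regions=regions,
        np_active=condition is not DiscCondition.np_removed,
        implant_E=cfg.implant_E if condition is DiscCondition.np_replaced else None,
        implant_nu=cfg.implant_nu if condition is DiscCondition.np_replaced else None,
    )
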