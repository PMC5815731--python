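# spinefem

Parametric finite-element analysis of the L4/5 lumbar motion segment:
how disc degeneration, nucleus pulposus (NP) removal, and artificial NP
replacement change the stress carried by the cartilaginous endplates (CEP)
and the bulging of the intervertebral disc.

## Who this is for

Spine-biomechanics researchers and implant engineers who want a fully
parametric, scriptable stand-in for a patient-specific CT model: every
geometric and material quantity is a config parameter, every solve is
deterministic, and the whole comparative study runs in well under a minute
on a laptop.

## The model

The segment is two vertebral bodies (cancellous core, cortical shell and a
cortical bony endplate facing the disc) joined by a 12 mm disc of
1300 mm² cross-section: a near-incompressible NP (495.5 mm², 38.1 % of
the disc area) surrounded by three annulus fibrosus layers at area
fractions 0.25 / 0.21 / 0.165, capped by 0.6 mm cartilaginous endplates,
tied by seven tension-only ligaments, with criss-cross ±30° tension-only
fiber trusses embedded in the annulus.

Mechanics are small-strain isotropic linear elasticity,

- hexahedral elements with a mean-dilatation (B-bar) formulation, so the
  NP can be driven to ν = 0.4999 without volumetric locking;
- truss elements with an active-set iteration enforcing the tension-only
  behaviour of ligaments and fibers;
- a rigid 6-dof coupling of the L4 top surface to its neutral point, where
  the 7.5 N·m motion-state torque is applied.

The four disc conditions differ only in the disc materials
(E in MPa / Poisson ratio):

| condition    | nucleus            | annulus matrix |
|--------------|--------------------|----------------|
| normal       | 1.0 / 0.49         | 2.56 / 0.40    |
| degenerative | 1.66 / 0.40        | 12.99 / 0.35   |
| NP removed   | elements removed   | 2.56 / 0.40    |
| NP replaced  | implant 1.25 / 0.30| 2.56 / 0.40    |

Derived shear moduli follow G = E / (2(1+ν)), e.g. G = 0.914 MPa for the
normal annulus and 0.593 MPa for the degenerated nucleus.

Each condition is solved in five motion states — axial compression
(500 N over 40 top-surface points, split 3:1 cortical:cancellous),
forward flexion, backward extension, and left/right axial rotation
(500 N + 7.5 N·m) — with the L5 base fully fixed, plus a 1000–6000 N
verification sweep.

## Worked example

```bash
python examples/03_axial_comparison.py
```

prints (default resolution, ~5000 degrees of freedom):

```
condition      peak CEP [MPa]  vs normal  bulge [mm]  NP pressure [MPa]
normal                 0.5585      +0.0%      0.5291             0.3910
degenerative           0.5660      +1.3%      0.0844             0.0950
np_removed             0.8327     +49.1%      0.4506             0.0000
np_replaced            0.6722     +20.4%      0.4415             0.1449
```

Each row is one static solve of the shared mesh: the peak von Mises
stress over the ten representative endplate sites, its increase over the
normal disc, the mean posterior-lateral annulus bulge, and the emergent
mean NP pressure (the healthy disc pressurizes toward 1.5× the nominal
axial stress, 0.577 MPa here; the depressurized degenerated and removed
nuclei do not).  Removing the nucleus forces the entire load through the
annulus and concentrates stress at the endplate margins; the hydrogel
replacement restores part of the central support and lands between the
normal and the removed disc.

Other entry points: `examples/01_build_mesh.py` (geometry + VTK export),
`examples/04_verification_sweep.py` (linearity of the load sweep),
`examples/05_full_study.py` (all 4×5 solves), or the CLI:

```bash
spinefem run --config examples/config_default.yaml --out study_out
spinefem verify --resolution coarse --out sweep_out
```

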