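# Methods

This note documents the model, its numerical realization, the parameters
that matter, and what the synthetic geometry does and does not capture.
Units are N / mm / MPa throughout; the coordinate convention is Z up
(superior), +Y anterior, +X left, with compression acting in −Z.

## The parametric segment as a stand-in for a CT geometry

Patient-specific lumbar FE models start from a CT-derived surface.  This
package replaces that surface with a parametric construction whose only
geometric truths are the printed disc dimensions: disc height 12 mm,
disc cross-section 1300 mm², nucleus cross-section 495.5 mm² (38.1 % of
the disc), three annulus layers at area fractions 0.25 / 0.21 / 0.165 of
the disc area, 0.6 mm cartilaginous endplates, and ±30° annulus fibers.
The vertebral body outline is an ellipse (lateral-to-AP aspect 0.7)
sized to the disc area and mirror-symmetric about the sagittal plane;
vertebra height (28 mm), cortical shell thickness, and a 1 mm cortical
bony endplate facing each disc surface are literature-typical
configurables.  The annulus-layer volume ratios (21 / 17 / 13 %) are
recorded for documentation but not enforced: area fractions and heights
already determine the volumes.

The cross-section is meshed as a butterfly grid (a central quadrilateral
core inside the nucleus, blended rings outward), extruded vertically.
Boundary polygon radii carry a resolution-dependent correction,
sqrt(π / ((n/2)·sin(2π/n))) for n circumferential divisions, so the
polygonal region areas equal the continuum targets at every resolution —
the printed areas are met to well under 1 % even on the coarse preset,
and refinement leaves them unchanged.

Posterior bony elements (pedicles, facets, spinous process) are not
meshed.  The seven ligaments (anterior and posterior longitudinal,
flavum, capsular, interspinous, supraspinous, intertransverse) run as
tension-only trusses between outer-surface nodes of the two vertebrae at
configurable azimuths and heights.  Facet articulation is therefore
carried by the capsular trusses rather than contact mechanics, and the
interspinous/supraspinous lever arms are shorter than anatomical — both
are deliberate simplifications of a geometry the printed data cannot
constrain, and they damp the rotational and extension responses.

## Annulus fibers

Each annulus layer carries two families of helical fiber trusses (+30°
and −30° to the transverse plane) on its mid-radial surface, one helix
starting at every circumferential station per family.  Fiber vertices
are dedicated nodes embedded kinematically in their host hexahedra via
trilinear shape-function weights (the embedded-rebar technique), which
makes every segment meet the requested angle exactly regardless of
element aspect ratio — face-diagonal rebar would wander by several
degrees around an elliptical cross-section.  The fiber cross-section per
layer is set from a fiber volume fraction (default 0.15 of the layer
volume, a typical collagen content) and the realized fiber volume is
recorded per layer.  Fibers and ligaments are tension-only.

## Constitutive model and conditions

All materials are isotropic linear elastic.  The four disc conditions
change only disc materials: normal NP (E = 1.0, ν = 0.49; the
near-incompressible ν = 0.4999 variant is selectable), normal annulus
matrix (2.56 / 0.40), degenerated NP (1.66 / 0.40), degenerated annulus
(12.99 / 0.35).  Nucleus removal deactivates the NP elements entirely
(zero stiffness contribution; interior nodes are pinned).  Replacement
assigns the NP region the implant material.

Two printed shear moduli are inconsistent with G = E/(2(1+ν))
(degenerated annulus: 4.55 printed vs 4.81 derived; normal NP: 0.338 vs
0.336 at ν = 0.49).  The library uses (E, ν) and logs the mismatch
rather than silently correcting either number.

Bone, endplate, fiber, ligament and implant properties are not printed
in the available source and are shipped as overridable defaults from the
lumbar-FE literature: cortical bone 12000 / 0.3, cancellous 100 / 0.2,
CEP 23.8 / 0.4, fiber trusses 500 / 0.3, ligament moduli 11.6–58.7 MPa
per ligament.  The artificial-nucleus implant, whose published
mechanical identity is limited to membership in the hydrogel
nucleus-device family (compressive moduli of roughly 0.05–1.5 MPa), is a
declared calibration parameter: the shipped default (E = 1.25 MPa,
ν = 0.30 — slightly stiffer than the nucleus matrix and drained, i.e.
non-pressurizing) was fixed once so that the replaced disc sits strictly
between the normal and nucleus-removed discs in peak endplate stress
across motion states while bulging less than the removed disc, which is
the implant's defining mechanical role.  It was not re-tuned afterwards.

The NP's hydrostatic behaviour is emergent, not imposed: the
near-incompressible solid pressurizes under load, and the
volume-weighted mean pressure −tr(σ)/3 over the NP is reported as a
diagnostic against 1.5× the nominal axial stress (0.577 MPa at 500 N
over 1300 mm²).  At the default ν = 0.49 the normal disc reaches
0.391 MPa — just below the ±30 % band, logged as such; the ν = 0.4999
variant reaches ≈ 0.46 MPa.  No explicit fluid cavity or
fluid–structure coupling is used.

## Solver

Displacement-based FEM, 8-node hexahedra with 2×2×2 Gauss quadrature and
the mean-dilatation B-bar modification (the volumetric part of the
strain-displacement operator is replaced by its element average).  This
passes the constant-stress patch test exactly and keeps the ν = 0.4999
nucleus locking-free (single-element uniaxial response within 1 % of the
analytic modulus).  Trusses contribute EA/L along their axis.

Constraints are realized through a global master–slave transformation:
rigid coupling of the L4 top surface to a 6-dof master at its centroid
(small-rotation kinematics, exact moment transmission), and the
trilinear embedding of fiber nodes.  The reduced operator stays
symmetric; the fixed L5 base is eliminated; the factorization is a
direct sparse LU with deterministic ordering, so identical configs
reproduce results bit for bit.

Tension-only members use a fixed-point active-set loop: solve with the
current active set, deactivate members whose axial force is below
−10⁻⁸ N, repeat until the set is stable (cap 20 iterations; failure is
an explicit error).  Under pure compression scaling the active set is
load-invariant, which is why the verification sweep is exactly linear.
Stress is recovered at the Gauss points with the same B-bar operator,
averaged per element, and averaged to nodes within a region (endplate
values are never contaminated by adjacent bone).  Solutions report the
relative equilibrium residual (typically 10⁻¹²; anything above 10⁻⁶ is
treated as a singular system) and reaction resultants, which balance the
applied loads to machine precision.

## Loading protocol

Axial loads enter through 40 designated points on the L4 top surface — 8
on the cortical shell ring, 32 on four interior rings — with per-point
weights that realize the 3:1 cortical:cancellous force split exactly.
The four torqued states couple the top surface to its neutral point and
apply 500 N axial force plus a 7.5 N·m moment there: flexion is the
moment about −X (tipping L4 anteriorly), extension +X, left/right axial
rotation ±Z; a config flag flips the sagittal sign convention.  The
verification sweep applies 1000–6000 N in 1000 N steps through the same
40-point distribution.  Every realized case is audited (force and moment
resultants) before solving, and the audit is written to the run log.

## Outputs

Per condition and motion state: von Mises stress at ten representative
endplate sites (central, anterior-central, posterior-central and the two
lateral margins of each endplate, sampled on the disc-facing surface),
the peak over those sites (the headline comparison; the global endplate
maximum is reported alongside), percent increase versus the normal
condition, mean posterior-lateral annulus bulge (|u_y| at the 315°
posterior-lateral point of each layer's mid-height ring, azimuth
configurable), mean axial displacement of the 40 load points, disc-center
von Mises and axial stress, and the NP pressure diagnostic.  Reports are
CSV + JSON; meshes and fields export to legacy-VTK ASCII.

## Problem sizes and presets

The default resolution (16 circumferential divisions, 4 axial disc
layers) yields ≈ 2000 nodes / 6000 dof and solves one motion state in
about a second; the full 4 × 5 study takes ≈ 25 s.  The coarse preset
(8 / 2) runs the study in a few seconds and is used for the
pipeline-level tests; the fine preset (32 / 8, ≈ 30 000 dof) exists for
refinement checks.  Region areas and the study metrics are stable across
presets (areas by construction; peak-stress percent increases shift by
some percent with refinement, as expected of stress-point quantities).

## What the stand-in geometry does and does not show

The parametric model reproduces: the printed cross-section partition and
fiber architecture; exact load resultants; mirror symmetry (left/right
rotation solutions are mirror images to solver precision); linearity of
the verification curves; nucleus pressurization in the healthy disc and
its loss with degeneration and removal; the strong endplate-stress rise
and load redistribution after nucleus removal; and a replacement
condition that restores intermediate behaviour.

Known limitations, all consequences of geometry the source does not
print rather than of the solver:

- **Degeneration severity is understated.**  With an emergent-pressure
  solid nucleus and element-deletion removal, the removed disc must route
  the full load through the annulus (mean axial stress 500 N / 805 mm² ≈
  0.62 MPa), whereas the degenerated disc's stiffer annulus carries at
  most ≈ 0.53 MPa because its nucleus still supports ≈ 70 N.  Peak
  endplate stress therefore ranks removal above degeneration at every
  site, and the degenerative increase over normal is small (≈ +1 % under
  axial compression) — the qualitative degeneration-worst ordering
  reported for CT-based models with an imposed nucleus pressure is not
  reachable in this model class.  For the same reason the degenerated
  disc (stiffer everywhere, no height loss modelled) bulges less than
  the normal one.
- **Upper/lower endplate asymmetry is marginal.**  The segment is nearly
  symmetric under superior–inferior reflection (equal vertebra heights,
  no lordotic angle, no posterior bony column), so flexion/extension and
  rotation produce only ~0.1–1 % differences between the endplate
  maxima, and their sign is dominated by near-field effects of the load
  introduction rather than anatomy.
- Facet contact, poroelasticity, osmotic swelling, strain-dependent
  fiber laws, geometric nonlinearity and muscle forces are out of scope;
  the model is linear, so large-load sweep responses are proportional by
  construction and should be read as linearized stiffness, not as
  physiologic large-strain response.
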