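# Default study configuration for the L4/5 motion-segment pipeline.
# Coordinate convention: Z up (superior), +Y anterior, +X left;
# compression acts in -Z.  Units: N, mm, MPa.
#
# Every key shown here is optional; omitted keys take these defaults.
# Unknown keys are rejected by name.

geometry:
  disc_height: 12.0          # mm, CEP-to-CEP span
  disc_area: 1300.0          # mm^2 cross-section
  np_area_fraction: 0.381    # nucleus area / disc area (495.5 / 1300)
  annulus_layer_area_fractions: [0.25, 0.21, 0.165]
  fiber_angle_deg: 30.0      # annulus fiber angle to the transverse plane
  cep_thickness: 0.6         # mm hyaline cartilage per endplate
  vertebra_height: 28.0      # mm (literature-typical, configurable)
  cortical_shell_thickness: 1.0
  ellipse_aspect: 0.7        # AP / lateral semi-axis of the body outline
  posterior_lateral_azimuth_deg: 315.0  # bulge sampling azimuth
  fiber_volume_fraction: 0.15

materials:
  cortical_E: 12000.0
  cortical_nu: 0.3
  cancellous_E: 100.0
  cancellous_nu: 0.2
  cep_E: 23.8
  cep_nu: 0.4
  fiber_E: 500.0
  fiber_nu: 0.3
  implant_E: 1.25            # artificial nucleus (hydrogel), calibrated default
  implant_nu: 0.30
  normal_np_nu: 0.49         # 0.4999 selects the near-incompressible nucleus

loads:
  axial_force: 500.0         # N
  torque_nm: 7.5             # N*m at the coupled neutral point
  cortical_cancellous_ratio: [3.0, 1.0]
  sweep_loads: [1000.0, 2000.0, 3000.0, 4000.0, 5000.0, 6000.0]
  flip_sagittal_moment: false

resolution: default          # coarse | default | fine
conditions: [normal, degenerative, np_removed, np_replaced]
states: [axial_compression, forward_flexion, backward_extension,
         left_axial_rotation, right_axial_rotation]
out_dir: spinefem_out
seed: 0
figures: false
write_vtk: false
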