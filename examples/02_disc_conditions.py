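"""The four disc conditions and their material assignments.

Prints the elastic modulus, Poisson ratio and derived shear modulus of the
disc tissues for the normal, degenerative, nucleus-removed and
nucleus-replaced models, as assigned to the mesh regions.
"""

from spinefem import condition_materials, shear_modulus

for cond in ("normal", "degenerative", "np_removed", "np_replaced"):
    a = condition_materials(cond)
    print(f"\n{cond}")
    for region in ("np", "annulus_layer1", "cep_upper"):
        props = a.lookup(region)
        if props is None:
            print(f"  {region:16s} inactive (elements removed from assembly)")
            continue
        G = shear_modulus(props.E, props.nu)
        print(f"  {region:16s} E = {props.E:8.2f} MPa  nu = {props.nu:.4f}  "
              f"G = {G:.3f} MPa   ({props.label})")

print("\nsanity: printed shear moduli")
print(f"  annulus matrix (2.56, 0.40) -> G = {shear_modulus(2.56, 0.40):.3f} "
      "MPa (printed 0.914)")
print(f"  degenerated NP (1.66, 0.40) -> G = {shear_modulus(1.66, 0.40):.3f} "
      "MPa (printed 0.593)")
# The shear moduli derive from the isotropic relation; the two printed
# values above are the internally consistent anchors of the material table.
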