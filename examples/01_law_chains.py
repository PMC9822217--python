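"""Built-in HU -> density -> Young's-modulus law chains.

Evaluates each packaged law chain at a few Hounsfield values spanning
marrow (~0 HU), trabecular bone (~400 HU), and dense cortical bone
(~1500 HU), printing the intermediate density and the resulting modulus.
The piecewise chain switches regime with density: a power law for low-
density trabecular bone, a constant 2398 MPa plateau in the middle, and a
stiffer cortical power law above 0.486 g/cm^3 ash density.
"""

import bonemap as bm

for name in bm.builtin_chain_names():
    chain = bm.builtin_chain(name)
    print(f"\n{name}  (modulus law consumes {chain.density_kind})")
    for hu in (0.0, 400.0, 1000.0, 1500.0):
        rho = bm.hu_to_density(chain, hu)
        E = bm.hu_to_modulus(chain, hu)
        print(f"  HU {hu:7.1f} -> rho {rho:8.5f} g/cm^3 -> E {E:10.2f} MPa")

print("\npiecewise plateau: density_to_modulus(0.4 g/cm^3) =",
      bm.density_to_modulus(bm.builtin_chain("piecewise_eq6_10"), 0.4), "MPa")
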