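# bonemap

Patient-specific elastic properties for finite-element bone models from CT.

Subject-specific FE models of bone (femur, pelvis, implant-reconstruction
studies) need spatially varying material properties, because bone stiffness
varies by two orders of magnitude between the trabecular interior and the
cortical shell.  Quantitative CT provides that information: each voxel
carries an attenuation value in Hounsfield units (HU) that maps, through a
scanner calibration line and empirical density–modulus relations, to a local
Young's modulus.  `bonemap` implements that mapping workflow for 4-node
tetrahedral meshes, in the style of the Bonemat family of tools, for
biomechanics researchers who want a scriptable, testable pipeline:

1. **Imaging** — CT volumes (DICOM series, NIfTI-1, or raw + JSON header)
   with a voxel→world affine, evaluated continuously by trilinear
   interpolation.
2. **Element HU averaging** — three strategies: mean over the element's
   nodes, mean over CT voxels inside the element, and numerical integration
   of the HU field over the element volume (the default; robust when element
   and voxel sizes are comparable).
3. **Law chains** — configurable HU → density → modulus conversions.
   Four published chains ship built in:

   | chain | calibration | density relations | modulus law (MPa) |
   |---|---|---|---|
   | `pelvis_uniform_eq1_2` | ρ_ash = 0.00063·HU − 0.0067 | — | E = 10500·ρ_ash^2.29 |
   | `cortical_apparent_eq3_5` | (config) | ρ_ash = 0.877·ρ_CT + 0.079; ρ_app = ρ_ash/0.6 | E = 6850·ρ_app^1.49 |
   | `piecewise_eq6_10` | ρ_CT = 0.0008·HU | ρ_ash = 0.877·1.15·ρ_CT + 0.08 | E = 33900·ρ_ash^2.2 (ρ_ash ≤ 0.3); 2398 (0.3 < ρ_ash ≤ 0.486); 10200·ρ_ash^2.01 (ρ_ash > 0.486) |
   | `bonemat_test_eq11_13` | ρ_CT = 0.00079·HU − 0.0039 | ρ_ash = 0.877·ρ_CT + 0.079 | E = 14664·ρ_ash^1.49 |

   User chains load from YAML/JSON with interval coverage validated.
4. **Binning** — elements grouped into equal-width material sets (modulus or
   HU space) with per-set representative modulus and volume fraction, so a
   solver receives a manageable number of material cards.
5. **Export** — Abaqus `.inp` with `*ELSET`/`*MATERIAL`/`*SOLID SECTION`
   per set, legacy VTK with per-cell HU/ρ/E fields, CSV element tables.
6. **Verification** — analytic phantoms (constant, affine-ramp, cortical
   shell, checkerboard) and a small linear-elastic tet4 solver for patch
   tests, laminate bounds, and load-path checks — no patient data required
   anywhere in the test suite.

## Worked example

Map a bone-like shell phantom (cortical 1500 HU around trabecular 300 HU)
onto a structured tet mesh and print the material-set distribution
(`examples/02_map_phantom.py`):

```text
mapped 3072 elements with volume_integration
element HU range: 300.0 .. 1500.0
element E range:  2240.8 .. 17242.1 MPa

material-set distribution (fractions sum to 1.000000000000):
 bin  E_repr_MPa  volume_fraction  n_elements
   0   2338.0074           0.7188        2208
   1   5106.0521           0.0391         120
   ...
   7  16955.1580           0.1172         360
```

Each row is one material set: its volume-weighted mean modulus and the
fraction of the model volume it occupies.  The soft trabecular interior
dominates by volume (bin 0) while the stiff cortical shell appears as the
high-modulus tail — exactly the bimodal structure a shelled bone should
show.  The same pipeline is available from the shell:

```bash
bonemap phantom shell.yaml --volume-out shell.json \
        --mesh-out mesh.inp --extent 12 12 12 --divisions 12 12 12
bonemap map --volume shell.json --mesh mesh.inp \
        --chain bonemat_test_eq11_13 --out-prefix mapped
bonemap verify mapped.inp --bc bc.yaml --out solution.vtk
```

`examples/` contains one short script per capability (law chains, mapping,
strategy comparison, verification solves).

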