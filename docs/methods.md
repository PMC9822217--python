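# Methods

## Problem and model

Bone is modelled as a locally isotropic, linear-elastic continuum whose
Young's modulus varies in space.  A quantitative CT scan supplies the
spatial information: the voxel value in Hounsfield units (HU) is converted
to a mineral-equivalent density by the scanner's linear calibration, then to
a Young's modulus by an empirical power law.  The pipeline assigns each
4-node tetrahedral element of an FE mesh a single modulus and then groups
elements into discrete material sets for export, which is the form
commercial solvers consume.

The element modulus is computed in "HU-average" order by default: the
element's representative HU is computed first and converted once through
the law chain.  The alternative "modulus-average" order (convert every
sample, then average) is exposed as `conversion_order="modulus_average"`
because the two differ on nonlinear laws — by Jensen's inequality the
modulus-average is never smaller under a convex power law — and the
literature on HU integration distinguishes them.  Neither order is silently
preferred elsewhere in the package.

## Coordinate conventions and interpolation

Voxel indices are 0-based, the voxel value sits at the voxel center, and
`world = origin + orientation · (spacing ∘ index)` with everything in mm.
The HU field between voxel centers is evaluated by trilinear interpolation,
the convention of the Bonemat lineage.  Trilinear interpolation is exact
for fields affine in world coordinates, which the affine phantom exploits
as a machine-precision oracle, and never overshoots the 8-voxel stencil
range.  Outside the voxel-center hull the default policy is to clamp to
the hull boundary and count the event (meshes routinely overhang a scanned
volume by fractions of a voxel); a strict error mode is available, and
elements falling entirely outside the hull are listed in the run report
because silently extrapolating bone properties is unsafe.

## Element averaging strategies

* `node_average` — mean of the four nodal interpolations.  Exact for affine
  fields (the nodal mean is the centroid value) but biased when elements are
  much larger than a voxel.
* `voxel_average` — mean HU over voxel centers inside the element
  (membership by barycentric coordinates, boundary-inclusive with tolerance
  1e-9).  Fails when an element contains no voxel center; such elements
  fall back to volume integration (logged per element) or raise, per
  configuration.
* `volume_integration` (default) — (1/V)·∫HU dV approximated by red
  (8-way) subdivision of the tetrahedron applied `refinement` times,
  sampling the field at each of the 8^refinement equal-volume sub-tet
  centroids with equal weights.  Because the sample set's first moment is
  the element centroid, the rule is exact for affine fields at every
  refinement.  A fixed-order polynomial quadrature would have no advantage
  here: the interpolated field is only piecewise-trilinear, with derivative
  kinks at voxel boundaries.  The default refinement of 2 (64 samples per
  element) is validated by a convergence test against a refinement-6
  reference.

A note on voxel-average convergence: the error of averaging an affine
field over the voxel centers inside a tet is a lattice-discrepancy
quantity.  It decays as the grid is refined but fluctuates level-to-level,
and axis-aligned meshes whose element pitch is commensurate with the voxel
pitch can lock all elements to the same lattice phase (including
superconvergent exact cancellation).  The convergence test therefore poses
the mesh at a generic rigid rotation — as real meshes are posed relative
to a scanner grid — and asserts the average decay rate over a three-level
spacing halving rather than each individual ratio.

## Law chains

A chain is calibration line → ordered affine density conversions → piecewise
modulus law, with units fixed to g/cm³ and MPa throughout.  Modulus
segments are half-open intervals `(lo, hi]`, taken literally from the
printed regime inequalities of the source laws (so ρ_ash = 0.486 belongs to
the constant 2398 MPa plateau and ρ_ash = 0.3 to the low-density power
law), and must cover `(rho_floor, ∞)` without gap or overlap — enforced at
load time, naming the offending interval.

Floors: `rho_floor` defaults to 1e-3 g/cm³ and `e_floor` to 0.01 MPa.  The
pelvis calibration line goes negative for low HU (air, marrow), and a
non-positive modulus would break any downstream solve; both floors are
configurable and every flooring event is counted in the run report.

Two documented ambiguities in the source coefficients:

* The piecewise chain's calibration is printed in a typographically
  ambiguous form; it is implemented as slope 8·10⁻⁴ g/cm³ per HU with zero
  intercept, the only physically sensible reading, and flagged here rather
  than silently resolved.
* The cortical/apparent-density chain is published without its scanner
  calibration.  The package defaults it to the QCT test calibration
  (0.00079, −0.0039) used by the `bonemat_test` chain; calibration
  coefficients are scanner-specific config inputs in any real study and
  should be overridden.

## Binning

Equal-width intervals between the observed minimum and maximum (modulus
space by default; HU space provided as the classical alternative), half-open
`(lo, hi]` with the minimum absorbed into the first bin.  Empty bins are
dropped with indices preserved.  The default of 50 bins is a configurable
package choice — enough sets to resolve a distribution curve while keeping
the exported material table manageable.  The representative modulus
defaults to the volume-weighted mean of member moduli, which preserves the
mesh's volume-averaged stiffness better than the interval midpoint (also
available).  Invariants asserted on every run: bins partition the element
ids exactly, and volume fractions sum to 1 within 1e-12.

## Verification solver

A constant-strain tet4 implementation of small-strain isotropic
elasticity with a direct sparse solve, intended for verification-scale
meshes (≲50k elements), not production contact analyses.  The Poisson
ratio is a single global value defaulting to 0.3 — the conventional choice
for bone FE, not a CT-derived quantity — and is echoed in every solution
and run report.  Dirichlet values support per-component NaN (free), so
symmetry and uniaxial conditions are expressible; Neumann tractions are
uniform per triangular face with the consistent area/3 nodal lumping.
Singular systems are detected by residual check and reported with an
estimated count of free modes.  Verified against the affine-displacement
patch test (exact to machine precision for E from 0.01 to 20000 MPa), the
two-layer series-compliance (Reuss) laminate oracle, exact 1/k displacement
scaling under k-scaled stiffness, and a qualitative cortical load-path
check on the mapped shell phantom.

## Synthetic phantoms

Each phantom kind has a closed-form HU field in world coordinates, so every
pipeline stage is tested against exact oracles: constant, affine ramp,
cortical shell (high-HU shell around a low-HU interior, with spherical
`l2` and cubic `linf` variants), and a voxel-parity checkerboard.  Defaults
represent realistic bone contrast: cortical ≈ 1500 HU, trabecular ≈ 300 HU,
sub-millimetre voxels (0.5 mm).  Gaussian noise is available but off by
default and requires an explicit seed; all volumes are bitwise reproducible
for a fixed spec.

The `linf` (cubic) shell exists because a strict element-wise contrast
property — *every* shell-centroid element stiffer than *every* interior
element — cannot hold for a curved interface crossed by a non-conforming
box mesh: elements straddling the interface on either side receive
arbitrarily close (for symmetric configurations, exactly equal) averages.
With the cubic shell the interfaces are axis-aligned planes placed on
element faces, the mesh conforms, and the strict property is meaningful;
the spherical variant is checked with a one-element-diameter margin around
the interfaces instead.

Box meshes use the Kuhn 6-tet subdivision of each grid cube (all elements
congruent up to reflection, summed volume exactly the box volume), which
makes volume-fraction hand checks trivial.

What the phantoms do *not* emulate: anatomical geometry, partial-volume
blur beyond trilinear sampling, beam-hardening or metal artefacts, noise
correlation, and scanner-specific calibration drift.  Passing tests
demonstrate the correctness of the mapping machinery, not the clinical
accuracy of any particular law chain on real scans.

## Determinism and I/O

The pipeline contains no randomness; repeated runs are bitwise identical,
asserted at the byte level on all CLI artifacts.  CLI outputs are staged to
temporary files and atomically renamed, so failed runs leave nothing
behind.  The Abaqus dialect is the comma-separated `.inp` subset with
`C3D4`-family elements only — quadratic tets are rejected loudly, since
averaging rules and the verification solver are written for the linear
element — and unknown keyword blocks pass through verbatim so a mapped
file remains usable downstream.

## Problem sizes

Tests and examples run on phantoms up to 41³–169³ voxels and meshes up to
~10⁴ elements, sizes at which every check completes in seconds while still
exercising multi-element, multi-bin, multi-regime behaviour.
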