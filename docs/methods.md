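# Methods note

## Scope and model

`spinefe` estimates vertebral compressive strength from calibrated CT by a
voxel-based finite-element (FE) pipeline:

1. **HU-to-density calibration.** A scan-specific affine line
   `density [mg/cm³ K₂HPO₄] = slope · HU + intercept` is fit by ordinary
   least squares from either internal reference tissues (phantomless route:
   fat, blood, muscle, bone at assumed densities −80, 20, 40, 300 mg/cm³) or
   the five rods of an in-scan calibration phantom. Region statistics are
   taken after eroding each region with a 5-voxel ball (2 voxels for phantom
   rods) to suppress partial-volume voxels; erosion is implemented as a
   Euclidean-distance-transform threshold, which is exact for ball
   structuring elements. Background air is thresholded in [−1050, −950] HU
   (largest 6-connected component) and used as a quality check, not as a fit
   point, because air does not lie on the soft-tissue/bone line.
2. **Meshing.** The calibrated volume and the vertebral-body mask are
   resampled to 1.0 mm isotropic voxels (trilinear for densities,
   nearest-neighbour for labels); every voxel of the largest face-connected
   mask component becomes one 8-node hexahedral element. Densities at or
   below zero (possible after affine calibration) are floored at
   0.005 g/cm³. Flat endplate surfaces are detected on the one-voxel
   boundary shell with an anisotropic 5×1×1 (z–y–x) criterion: a surface
   voxel column belongs to an endplate if its column extremum lies on the
   extreme plane and the body occupies a full 5-voxel in-column run behind
   it, which removes thin oblique ledges while keeping one-voxel-thick flat
   plates. Three-voxel PMMA cap layers (E = 2500 MPa, σy = 70 MPa, ν = 0.3)
   are extruded on both endplate footprints to distribute the load.
3. **Materials.** Bone elements receive isotropic properties from the
   calibrated apparent density ρ (g/cm³) through
   `E = 2980·ρ^1.05 MPa` and `σy = 37.4·ρ^1.39 MPa`, with ν = 0.3
   everywhere. Continuous density is discretized into 256 equal-width bins
   evaluated at bin midpoints.
4. **FE solves.** Uniaxial compression with the inferior cap surface fully
   fixed and the superior cap surface driven axially (lateral motion free).
   The linear model is solved at 0.2 % apparent strain of the total capped
   height; the nonlinear model ramps to 2 % in 20 equal displacement
   increments with von Mises elastic–perfectly-plastic radial-return
   updates. Convergence is declared at a maximum relative displacement
   update of 1e-6 (at most 30 000 linear / 10 000 plastic iterations).
5. **Strength estimators.** `rforce_linear` (reaction of the linear solve),
   `fload_stiffness = 0.0068 · K_FE · H` (model stiffness in kN/mm times
   vertebral body height in mm), and `fload_nonlinear` (force at 2 %
   apparent strain). The displacement threshold of the linear surrogate can
   be recalibrated from sample vertebrae by relative least squares; the
   optimum has the closed form `u* = Σaᵢ / Σaᵢ²` with `aᵢ = KᵢHᵢ/Fᵢ`.
6. **Level normalization.** An adjacent-level ratio graph averages
   within-subject strength ratios of nonfractured adjacent vertebrae and
   accumulates them along the chain to L1; a population normalization
   compares level means to the cohort L1 mean. Strata (sex, fracture
   status) are analyzed separately, with one-sided Mann–Whitney U tests for
   fractured-vs-control comparisons (exact for tie-free groups of ≤ 8,
   asymptotic otherwise; fully tied data return p = 0.5 with a warning).

Units are mm, MPa and N internally (1 MPa·mm² = 1 N); reported forces are
kN with compression positive.

## Numerical choices

- All elements are identical cubes, so a single unit-modulus 24×24
  stiffness template (2×2×2 Gauss) is scaled by each element's modulus;
  the template has exactly six rigid-body zero-energy modes.
- The linear solver uses Jacobi-preconditioned conjugate gradients
  (relative residual ≤ 1e-6 by default); a sparse direct factorization is
  available as an independent cross-check.
- The nonlinear solver applies an incremental elastic predictor per
  displacement increment and iterates with a factorized tangent
  (modified Newton). A bare initial-elastic-stiffness iteration diverges
  at the first yielding increment — the prescribed-displacement jump
  creates a transient strain concentration at the driven face — so the
  algorithmically consistent elastoplastic tangent is reassembled and
  refactorized whenever the iteration contracts slower than a ratio of
  0.85, diverges, or stalls for 100 iterations; the factorization persists
  across increments because the plastic zone only grows under monotonic
  loading. These are efficiency devices only: converged forces are
  identical (verified to 4+ decimals) across reform schedules, the
  homogeneous-column plateau matches σy·A to ~1e-6, and with σy = ∞ the
  nonlinear solution reproduces the linear one at every increment.
- The perfect-plasticity consistent tangent is stabilized with a small
  (1e-8 · 2μ) multiple of the deviatoric identity to remove the rank
  deficiency along the flow direction.

## Synthetic data and generator fidelity

No patient data ship with the package. All studies run on synthetic
phantoms with known ground truth:

- **Reference-tissue scans**: disjoint 14³-voxel tissue boxes whose HU
  invert the truth calibration line exactly (plus optional Gaussian HU
  noise); air is written near −1000 HU. An embeddable 5-rod phantom spans
  ≈ −52…376 mg/cm³.
- **Vertebrae**: elliptic cylinders with flat endplates, a dense cortical
  shell, a smoothly heterogeneous trabecular interior (Gaussian random
  field, σ = 1.5 voxel correlation), and an optional weakened mid-body
  band emulating fracture. Cohorts scale the cross-sectional area per
  level (default 1.06 per level caudally) so the true adjacent-level
  strength ratio of homogeneous columns equals the area ratio.

These phantoms are deliberately reduced-scale (default body 34×28×27 mm;
the stochastic end-to-end study uses 14×11×12 mm bodies with a one-voxel
shell at 0.8 g/cm³, consistent with the heavily partial-volumed apparent
density of the thin vertebral cortex at 1 mm voxels) so the full pipeline
runs on one CPU in minutes. They capture the load-bearing structure
(shell + heterogeneous trabecular core + endplates) but not real vertebral
shape, posterior elements, marrow-fat inhomogeneity or scanner artifacts;
absolute strengths are therefore not comparable to clinical values, while
the relative and analytic properties the test suite asserts are.

## Limitations

- Small-strain kinematics; no geometric nonlinearity or contact. The 2 %
  "failure" load is a plateau force, not a post-peak collapse load.
- Elastic–perfectly-plastic bone with a symmetric von Mises surface; no
  tension–compression asymmetry or damage.
- Voxel meshes have stair-stepped surfaces; no smoothing is applied.
- The phantomless route depends on assumed tissue densities; systematic
  tissue-composition differences shift the line (the air QC flag, fit
  diagnostics r², and the phantom cross-check are provided for this
  reason).
- Mann–Whitney p-values for very small strata are coarse; strata under
  3 subjects are flagged.
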