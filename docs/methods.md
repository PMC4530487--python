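# Methods

## Scope and model

`bonefe` implements the computational chain used in preclinical studies
that ask whether a focal intervention changes the mechanics of a long bone:
micro-CT-based voxel micro-FE simulation of a three-point bending test,
analysis of the destructive bending experiment, tissue-modulus
back-calculation from the experiment/FE stiffness ratio, and paired
treated-vs-control statistics. No animal data ship with the package; every
stage is exercised on synthetic phantoms whose ground truth is known, so
each claim the test suite makes is a statement about algorithmic
correctness, not about any particular animal cohort.

Axis convention everywhere: axis 0 is the bone shaft / roller-span
direction, axis 2 the vertical loading direction. Coordinates are 0-based
with half-open intervals; voxel *i* has its center at (i + 0.5)·spacing.
Units: lengths mm (µm at the image interface), forces N, stiffness N/mm,
moduli GPa at the API (converted to N/mm² internally).

## Preprocessing

The chain is fixed as reorient → downsample → threshold → crop → largest
component.

* **Reorientation** — axis permutations/flips are lossless; arbitrary-angle
  rotations use trilinear interpolation. Rotation for real scans is
  user-supplied; there is no automatic principal-axis alignment, because
  the correct orientation is defined by the physical test rig, which the
  software cannot infer from the image.
* **Downsampling** (default 25 → 50 µm) is the arithmetic mean over each
  source block, which conserves integrated density. The target spacing must
  be an integer multiple of the source spacing; trailing voxels that do not
  fill a block are discarded.
* **Thresholding** keeps a voxel iff intensity ≥ permille/1000 · reference,
  with the *maximum possible value of the storage format* as the default
  reference (32767 for int16, 65535 for uint16, 1.0 for float). Reading
  "maximum possible value" as the data-range maximum rather than the
  observed image maximum keeps the segmentation independent of image noise;
  `threshold_reference: observed` is available as a config switch.
* **Cropping** keeps [min(roller) − margin, max(roller) + margin) along the
  shaft axis (margin default 0.5 mm). With 50 µm voxels and rollers at
  1.0/11.0 mm this is exactly the index range [10, 230).
* **Component cleanup** retains the largest 6-connected component (floating
  islands would make the stiffness matrix singular); ties go to the
  component containing the lexicographically smallest voxel.

A partial-volume caveat measured on the phantoms: downsampling a 25 µm
scan of a thin cortical wall to 50 µm and thresholding at 500 ‰ erodes the
wall by up to half a voxel per surface (≈4 % cross-section area on a
0.3 mm wall). This bias is inherent to the mean-then-threshold protocol,
not to the implementation; validation meshes therefore render the phantom
directly at the working resolution, where voxel-center membership is
unbiased.

## Voxel micro-FE

Each bone voxel becomes a cubic 8-node trilinear hexahedron with identical
isotropic material (default E = 10 GPa, ν = 0.3), so a single 24×24 element
matrix — full 2×2×2 Gauss quadrature, exact for this element — serves the
whole mesh. The element is verified to have exactly six zero-energy
(rigid-body) modes and to reproduce constant-strain states through the
mesh-level patch test to 10⁻¹⁰ relative error.

**Boundary conditions.** For each bottom roller, the support set contains
the bottom-most bone-surface node of every (axis0, axis1) column within
±`contact_halfwidth_vox` voxels of the roller plane; these nodes are fixed
vertically only (rolling pins, not clamps). Rigid-body motion is removed by
additionally fixing axis 0 on support set *a* and axis 1 on one node of
set *a*. Load nodes are the top-surface analogue at the load position
(default mid-span) and receive a prescribed vertical displacement
(δ = −0.01 mm by default; the reported stiffness is independent of δ by
linearity). Prescribed displacements are imposed by constraint elimination,
so reactions are exact; global equilibrium (support reactions balancing
load-node reactions) holds to solver tolerance.

**Support-band width is the dominant modeling artifact.** Fixing the
vertical freedom across the full width over a band of 2·hw + 1 node planes
resists support rotation and acts like a shortened span. Measured on the
solid square beam (edge 1.2 mm, span 9.6 mm), FE/Timoshenko is 1.90 at
200 µm, 1.28 at 100 µm and 1.07 at 50 µm with the default hw = 1 — monotone
convergence, because the band footprint shrinks with the voxels — while
knife-edge supports (hw = 0) give 0.99–1.01 at all resolutions. Comparisons
against simply-supported beam theory on the thin-walled cylinder therefore
use hw = 0; the default hw = 1 is kept for real, noisy masks where a
single-plane contact may miss the surface. Changing hw is *not* a small
perturbation (tens of percent on short spans) and is surfaced as such in
the tests.

**Solver.** K u = f is solved with Jacobi-preconditioned conjugate
gradients to a relative residual of 10⁻⁶ (configurable), on an assembled
scipy CSR matrix by default; an element-by-element matrix-free operator
(identical arithmetic, no global matrix) and a dense direct path for small
systems are provided and cross-checked to 10⁻⁸ relative stiffness
agreement on randomized porous meshes. Everything is serial and
deterministic: reruns are bit-identical.

## Bending-curve analysis

* **Elastic stiffness** — among contiguous sample windows whose forces lie
  in [10 %, 60 %] of the ultimate load (pre-peak) and that span at least
  15 % of all samples, the least-squares fit with maximal R² wins; ties go
  to the longest, then the earliest window. If no window reaches R² ≥ 0.9
  the best available slope is still reported with a `low_quality` flag,
  never silently. The band upper edge assumes the yield force lies above
  60 % of the ultimate force, which holds for whole-bone bending records;
  all band parameters are configurable.
* **Ultimate load** — the force maximum (the synthetic generator includes
  the apex point in the sample sequence, as test machines log the peak).
* **Yield load** — whole-bone tests have no gauge strain, so a 0.2 %-offset
  rule is unavailable. Instead, the elastic line is extrapolated beyond the
  fit window; the first pre-peak sample falling below the line by more than
  5 % (relative, configurable) marks departure, and yield is reported at
  the last earlier sample still on or above the line (tolerance 10⁻⁹ so
  exact noiseless samples count as on-line). On noiseless bilinear curves
  this recovers the true yield to one sample spacing and is insensitive to
  the threshold choice; a perfectly linear record yields
  yield = ultimate with an explicit flag.

## Tissue-modulus calibration

E_tissue = (k_exp / k_FE) · E_ref exactly, no fitting; scale-equivariant by
construction. The closed-loop check manufactures an "experiment" by solving
the same phantom at a known true modulus and converting that stiffness into
a noise-free synthetic curve: recovery at E_true ∈ {6, 10, 14} GPa is exact
to ~10⁻¹¹ relative, limited only by solver tolerance and curve sampling.

## Statistics

* **Wilcoxon signed-rank (paired)** — zero differences dropped, average
  ranks for ties; T is the smaller signed-rank sum. Default is the normal
  approximation without continuity correction and with tie-corrected
  variance; this convention is anchored by the n = 3 values
  p = 0.109, 0.285, 0.593 for T = 0, 1, 2 (printing as 0.11/0.29/0.59),
  which is how mainstream statistics packages report small-n signed-rank
  tests. An exact mode enumerates the 2ⁿ sign distribution by convolution;
  at n = 3 its smallest attainable two-sided p is 0.25, so no α = 0.05
  rejection is possible — the asymptotic default mirrors common practice,
  the exact mode tells the honest small-n story.
* **t tests** — across-timepoint comparisons of treated/control ratios use
  the pooled-variance two-sided t test by default (Welch by flag); paired
  mode operates on differences; zero-variance inputs raise.
* No multiplicity correction is applied.

## Synthetic data

* **Femur phantom** — the mid-shaft is a hollow circular cylinder (defaults:
  length 12 mm, outer radius 2 mm, cortical thickness 0.6 mm, typical
  rat-femur literature values, config-overridable), optionally with an
  endosteal woven-bone shell and periosteal thickening as geometric
  stand-ins for post-intervention bone modeling. Bone/background gray
  levels are 0.75/0.05 of the data range, so the noiseless phantom survives
  the 500 ‰ threshold voxel-for-voxel (voxel-center membership). Gaussian
  partial-volume blur is applied before additive Gaussian noise; the result
  is clipped to the data range. Every generator is a pure function of its
  spec including the seed.
* **Bending curve** — bilinear with prescribed stiffness, yield and
  ultimate load (post-yield slope 20 % of elastic by default), then a drop
  to 50 % of ultimate; sampled at the displacement step implied by the
  0.1 mm/min cross-head speed and the sampling interval, plus additive
  force noise.
* **Paired cohort** — control values i.i.d. lognormal; treated = control ×
  (1 + effect) × exp(noise). The default of three pairs matches a study arm
  in which three bone pairs per timepoint reach mechanical testing.

What the phantoms do **not** emulate: beam-hardening and scanner artifacts,
trabecular architecture, spatially varying mineralization (the FE assumes
one tissue modulus), anatomical curvature and condyles, machine compliance
and toe regions in the curves. Passing tests therefore demonstrate that the
pipeline recovers known answers under its own model assumptions — they do
not certify accuracy on real scans, where segmentation and support
placement dominate the error budget.

## Verification problem sizes

Closed-form comparisons use slender geometries, since Timoshenko theory is
itself only trustworthy for beam-like aspect ratios (at span/diameter 2.4 —
a realistic rat-femur test — the shear term is ~47 % of the compliance and
the "theory" is no longer an oracle). The standard cases are: solid square
beam, edge 1.2 mm, span 9.6 mm, at 50 µm (≈122 k elements, within 10 % of
theory at the protocol band width); a half-scale beam (edge 0.6 mm, span
4.8 mm, same slenderness) for the 100/50/25 µm convergence series, keeping
the finest mesh at ≈134 k elements; and a hollow cylinder with outer radius
0.75 mm, wall 0.3 mm, span 9 mm at 50 µm (≈83 k elements, 0.3 % agreement
under knife-edge supports). The demo cohort runs a scaled-down shaft
(length 4.4 mm, outer radius 0.5 mm) so a full paired two-timepoint cohort
solves in about a minute.

## Known limitations

* Linear elasticity only: the FE predicts elastic stiffness, not yield or
  failure; plasticity lives exclusively in the experimental curve.
* The support/load node-selection rule ("bottom-most node per column across
  the full width") touches the lateral walls of a curved section at
  mid-height; together with the band-width effect this is the leading
  source of FE-vs-experiment stiffness discrepancy, and real rigs are
  somewhere between knife-edge and finite-band contact.
* Jacobi-PCG iteration counts grow roughly linearly with mesh refinement
  (≈500/1050/2050 iterations across the beam series); meshes in the
  million-element range are the practical ceiling in this implementation.
* The exact Wilcoxon mode assumes exchangeability of signs under the null,
  as usual; with n = 3 pairs no design can reach α = 0.05.
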