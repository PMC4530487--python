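# bonefe

Image-based whole-bone biomechanics on micro-CT: voxel micro-finite-element
(micro-FE) simulation of a three-point bending test, destructive
load-displacement curve analysis, back-calculation of the bone tissue
Young's modulus, and paired treated-vs-control statistics — exercised
end-to-end on synthetic femur phantoms with known ground truth.

The package is aimed at preclinical bone researchers who combine a micro-CT
scan of a long bone (e.g. a rat femur after a focal intervention such as
thermal ablation) with a destructive three-point bending test of the same
bone, and want to answer two questions:

1. **Whole-bone level** — did the intervention change the bone's elastic
   stiffness, yield load or ultimate load relative to the contralateral
   control?
2. **Tissue level** — did the mineralized tissue itself change, once
   geometry (new woven bone, cortical thickening) is factored out?

## Method

**Micro-FE.** The scan is reoriented into the bending frame, reduced to a
50 µm working resolution by block averaging, segmented with a single global
threshold at 500 ‰ of the maximum possible intensity, and cropped to the
region between the bottom rollers plus 0.5 mm per side. Every bone voxel
becomes an 8-node hexahedral element (trilinear, full 2×2×2 Gauss
integration) with isotropic linear-elastic tissue properties
(E<sub>ref</sub> = 10 GPa, ν = 0.3). Bottom-surface nodes at the two roller
planes are supported vertically (rolling-pin idealization plus minimal
rigid-body stabilizers) and a vertical displacement δ is prescribed at the
top-surface nodes under the loading roller. The FE bending stiffness is

&nbsp;&nbsp;&nbsp;&nbsp;k<sub>FE</sub> = |Σ R<sub>z</sub>(load nodes)| / |δ|,

solved by Jacobi-preconditioned conjugate gradients (assembled-sparse by
default, matrix-free element-by-element available).

**Bending test analysis.** The elastic stiffness k<sub>exp</sub> is the
least-squares slope of the best (maximum-R²) contiguous window inside the
10–60 % force band of the ultimate load; the ultimate load is the force
maximum; the yield load is the force at the changing point between the
elastic and plastic ranges, detected as the departure from the extrapolated
elastic line.

**Tissue-modulus calibration.** Because the FE model is linear in E,

&nbsp;&nbsp;&nbsp;&nbsp;E<sub>tissue</sub> = (k<sub>exp</sub> / k<sub>FE</sub>) · E<sub>ref</sub>.

**Statistics.** Paired treated/control comparisons use the two-sided
Wilcoxon signed-rank test (normal approximation without continuity
correction, tie-corrected variance; exact 2ⁿ enumeration available);
changes of the treated/control ratio across timepoints use the two-sided
pooled-variance t test (Welch optional).

**Verification.** The solver is validated against the closed-form
Timoshenko three-point-bending stiffness k = [L³/(48EI) + L/(4κGA)]⁻¹ on a
voxelized solid square beam and on a hollow-cylinder cortical phantom, the
element against the constant-strain patch test, and the PCG path against
dense direct solves.

## Worked example

The numbered scripts under `analysis/` run the full study chain on
phantoms. `analysis/01_verify_fe_against_beam_theory.py` prints:

```
solid square beam, full-size section (edge 1.2 mm, span 9.6 mm), protocol support band (one-voxel halfwidth):
  50 um: FE 95.9 N/mm vs theory 89.4 N/mm -> ratio 1.073
half-scale beam (edge 0.6 mm, span 4.8 mm), voxel-size series:
  100 um: ratio 1.909 (2088 elements, 499 CG iterations)
   50 um: ratio 1.284 (16704 elements, 1050 CG iterations)
   25 um: ratio 1.073 (133632 elements, 2053 CG iterations)
hollow cylinder (r_o 0.75 mm, wall 0.3 mm, span 9 mm), knife-edge supports:
  50 um: FE 126.8 N/mm vs theory 126.4 N/mm -> ratio 1.003
```

i.e. the voxel model approaches beam theory monotonically from above as the
discrete support band shrinks with the voxel size, and agrees to 0.3 % with
the annulus closed form under knife-edge supports.
`analysis/02_tissue_modulus_recovery.py` closes the calibration loop:

```
E_true   6.0 GPa -> recovered 6.0000 GPa (relative error +2.68e-11)
E_true  10.0 GPa -> recovered 10.0000 GPa (relative error +4.22e-15)
E_true  14.0 GPa -> recovered 14.0000 GPa (relative error -2.86e-11)
```

`analysis/04_phantom_cohort_pipeline.py` runs a paired cohort in which the
treated femurs carry endosteal woven bone, periosteal thickening and a −5 %
tissue-modulus effect. Whole-bone stiffness comes out *higher* on the
treated side (the new bone adds section), while the tissue-modulus
calibration isolates the material effect:

```
  7d elastic_stiffness_n_per_mm: +50.1 ± 0.0 %  (Wilcoxon T=0, p=0.180)
  7d tissue_modulus_gpa:          -4.9 ± 0.0 %  (Wilcoxon T=0, p=0.180)
```

The same chain is scriptable from the shell:

```sh
bonefe phantom --seed 1 -o vol.mha
bonefe preprocess --in vol.mha --rollers 1.0 11.0 --margin 0.5 --target-um 50 -o mask.mha
bonefe solve --mask mask.mha --rollers 1.0 11.0 --E 10 --nu 0.3 -o fe.json
bonefe bend-analyze --in curves/ -o summaries.csv
bonefe stats --pairs cohort.csv -o report.json
bonefe demo --full --seed 7 -o out/      # end-to-end phantom cohort
```

## Layout

- `src/bonefe/` — library: `phantoms` (synthetic data), `imageproc`
  (volume I/O + preprocessing), `microfe` (element, mesh, solver),
  `mechtest` (curve analysis), `calib_stats` (calibration + statistics),
  `beamtheory` (closed-form oracles), `validation`, `pipeline`, `config`,
  `cli`.
- `analysis/` — numbered narrative drivers writing tables to `results/`.
- `docs/methods.md` — modeling assumptions, parameter choices, numerical
  details and limitations.
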