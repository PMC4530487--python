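"""Verification experiments: voxel FE against closed-form beam theory,
tissue-modulus recovery, and curve-analysis recovery.

These runners define the package's standard verification problems:

* a voxelized solid square beam and a hollow-cylinder (cortical-shaft)
  phantom, both compared against the Timoshenko three-point-bending
  stiffness;
* end-to-end tissue-modulus recovery, where a synthetic "experiment" is
  manufactured at a known true modulus and the calibration chain must give
  it back;
* Monte-Carlo stiffness/yield/ultimate recovery from noisy bending curves.

Beam-theory comparisons use knife-edge supports (contact halfwidth 0) where
the oracle assumes simple supports; the voxel-band convergence study keeps
the band at its default one-voxel halfwidth so the discrete model tends to
the knife-edge limit as the voxels shrink.
"""

from __future__ import annotations

import numpy as np

from .beamtheory import annulus_section, rect_section, three_point_bending_stiffness
from .imageproc import BoneMask, SpanCrop, crop_to_span, largest_component, local_span_crop, threshold_permille
from .mechtest import analyze_curve
from .microfe import Material, build_model, solve
from .phantoms import CurveSpec, PhantomSpec, generate_femur_phantom, generate_load_curve

__all__ = [
    "solid_beam_mask",
    "annulus_mask",
    "beam_vs_timoshenko",
    "annulus_vs_timoshenko",
    "modulus_recovery",
    "curve_recovery_mc",
]


def solid_beam_mask(vox_um: float, edge_mm: float, span_mm: float,
                    margin_mm: float = 0.5) -> tuple[BoneMask, SpanCrop]:
    """Fully meshed square-section beam with rollers ``margin_mm`` from the
    ends."""
    s = vox_um / 1000.0
    n_edge = int(round(edge_mm / s))
    n_len = int(round((span_mm + 2 * margin_mm) / s))
    mask = BoneMask(np.ones((n_len, n_edge, n_edge), dtype=bool), vox_um)
    return mask, SpanCrop((margin_mm, margin_mm + span_mm), margin_mm=0.0)


def annulus_mask(vox_um: float, r_outer_mm: float, thickness_mm: float,
                 span_mm: float, margin_mm: float = 0.5) -> tuple[BoneMask, SpanCrop]:
    """Segmented hollow-cylinder phantom rendered at the working resolution
    (voxel-center membership, so the mask is the exact discrete annulus)."""
    spec = PhantomSpec(
        length_mm=span_mm + 2 * margin_mm,
        outer_radius_mm=r_outer_mm,
        cortical_thickness_mm=thickness_mm,
        voxel_size_um=vox_um,
    )
    mask = threshold_permille(generate_femur_phantom(spec))
    crop = SpanCrop((margin_mm, margin_mm + span_mm), margin_mm=0.0)
    mask = largest_component(crop_to_span(mask, crop))
    return mask, local_span_crop(mask, crop)


def _run(mask, crop, material, hw, tol):
    model = build_model(mask, material, crop, contact_halfwidth_vox=hw)
    sol = solve(model, tol=tol)
    return model, sol


def beam_vs_timoshenko(vox_um: float, edge_mm: float = 1.2, span_mm: float = 9.6,
                       contact_halfwidth_vox: int = 1, tol: float = 1e-6) -> dict:
    """FE bending stiffness of the solid square beam vs the Timoshenko
    closed form (kappa = 5/6)."""
    material = Material()
    mask, crop = solid_beam_mask(vox_um, edge_mm, span_mm)
    model, sol = _run(mask, crop, material, contact_halfwidth_vox, tol)
    A, I, kap = rect_section(edge_mm, edge_mm)
    k_theory = three_point_bending_stiffness(span_mm, material, A, I, kap)
    return {
        "voxel_um": vox_um,
        "k_fe_n_per_mm": sol.fe_stiffness_n_per_mm,
        "k_theory_n_per_mm": k_theory,
        "ratio": sol.fe_stiffness_n_per_mm / k_theory,
        "n_elements": model.n_elements,
        "iterations": sol.solver_iterations,
    }


def annulus_vs_timoshenko(vox_um: float = 50.0, r_outer_mm: float = 0.75,
                          thickness_mm: float = 0.3, span_mm: float = 9.0,
                          contact_halfwidth_vox: int = 0, tol: float = 1e-6) -> dict:
    """FE stiffness of the hollow-cylinder phantom vs the annulus Timoshenko
    value (Cowper's kappa). Knife-edge supports by default: the closed form
    assumes simple supports, and a finite support band acts as a span
    change."""
    material = Material()
    mask, crop = annulus_mask(vox_um, r_outer_mm, thickness_mm, span_mm)
    model, sol = _run(mask, crop, material, contact_halfwidth_vox, tol)
    A, I, kap = annulus_section(r_outer_mm, r_outer_mm - thickness_mm,
                                material.poisson_ratio)
    k_theory = three_point_bending_stiffness(span_mm, material, A, I, kap)
    return {
        "voxel_um": vox_um,
        "k_fe_n_per_mm": sol.fe_stiffness_n_per_mm,
        "k_theory_n_per_mm": k_theory,
        "ratio": sol.fe_stiffness_n_per_mm / k_theory,
        "n_elements": model.n_elements,
        "iterations": sol.solver_iterations,
    }


def modulus_recovery(e_true_gpa: float, e_ref_gpa: float = 10.0,
                     vox_um: float = 50.0, r_outer_mm: float = 0.75,
                     thickness_mm: float = 0.3, span_mm: float = 4.8,
                     tol: float = 1e-6) -> dict:
    """Back-calculate the tissue modulus of a phantom whose "experimental"
    stiffness is manufactured at a known true modulus.

    The experiment is emulated in two steps: the FE model solved at
    ``e_true`` gives the bone's true bending stiffness, and a noise-free
    synthetic bending curve with that stiffness is analyzed like a real
    record. The calibration FE run uses ``e_ref``; recovery error is limited
    by solver tolerance and curve sampling only.
    """
    from .calib_stats import back_calculate_tissue_modulus

    mask, crop = annulus_mask(vox_um, r_outer_mm, thickness_mm, span_mm)
    _, sol_true = _run(mask, crop, Material(e_true_gpa), 1, tol)
    k_true = sol_true.fe_stiffness_n_per_mm
    curve = generate_load_curve(
        CurveSpec(
            stiffness_n_per_mm=k_true,
            yield_load_n=0.08 * k_true,
            ultimate_load_n=0.12 * k_true,
        )
    )
    k_exp = analyze_curve(curve).elastic_stiffness_n_per_mm
    _, sol_ref = _run(mask, crop, Material(e_ref_gpa), 1, tol)
    res = back_calculate_tissue_modulus(k_exp, sol_ref.fe_stiffness_n_per_mm, e_ref_gpa)
    return {
        "e_true_gpa": e_true_gpa,
        "e_recovered_gpa": res.e_tissue_gpa,
        "relative_error": res.e_tissue_gpa / e_true_gpa - 1.0,
        "k_exp_n_per_mm": k_exp,
        "k_fe_n_per_mm": sol_ref.fe_stiffness_n_per_mm,
        "n_elements": mask.n_voxels,
    }


def curve_recovery_mc(n_seeds: int = 200, stiffness: float = 120.0,
                      yield_load: float = 40.0, ultimate_load: float = 60.0,
                      noise_sd_n: float = 0.5, seed0: int = 0) -> dict:
    """Monte-Carlo recovery of the elastic stiffness from noisy curves."""
    recovered = np.empty(n_seeds)
    for i in range(n_seeds):
        spec = CurveSpec(
            stiffness_n_per_mm=stiffness,
            yield_load_n=yield_load,
            ultimate_load_n=ultimate_load,
            noise_sd_n=noise_sd_n,
            seed=seed0 + i,
        )
        recovered[i] = analyze_curve(
            generate_load_curve(spec)
        ).elastic_stiffness_n_per_mm
    return {
        "n_seeds": n_seeds,
        "true_stiffness": stiffness,
        "mean_recovered": float(recovered.mean()),
        "mean_bias_relative": float(recovered.mean() / stiffness - 1.0),
        "sd_recovered": float(recovered.std(ddof=1)),
    }
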