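"""End-to-end orchestration: preprocess -> micro-FE -> bending analysis ->
tissue-modulus calibration -> paired statistics.

Two entry points share the same downstream chain:

* :func:`run_pipeline` on explicit specimens (volumes + curves, real or
  synthetic);
* :func:`run_demo` which synthesizes a paired treated/control phantom cohort
  with known ground truth and pushes it through the full chain.

All outputs are deterministic functions of the configuration (including its
seed): a rerun with the same config writes bit-identical reports. Timings go
to the log, never into result files.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calib_stats import back_calculate_tissue_modulus, cohort_report
from .config import PipelineConfig
from .imageproc import (
    SpanCrop,
    VoxelImage,
    downsample_to,
    crop_to_span,
    largest_component,
    local_span_crop,
    read_volume,
    threshold_permille,
)
from .mechtest import LoadDisplCurve, WindowRule, analyze_curve, read_curve, write_curve
from .microfe import Material, build_model, solve
from .phantoms import CurveSpec, PhantomSpec, generate_femur_phantom, generate_load_curve

log = logging.getLogger("bonefe.pipeline")

__all__ = ["run_pipeline", "run_demo", "Specimen"]


class Specimen:
    """One bone entering the pipeline: a volume and its bending curve."""

    def __init__(self, animal: str, timepoint: str, side: str, volume, curve,
                 rollers_mm=None, load_position_mm=None):
        if side not in ("treated", "control"):
            raise ValueError("side must be 'treated' or 'control'")
        self.animal, self.timepoint, self.side = animal, timepoint, side
        self.volume = volume          # VoxelImage | path
        self.curve = curve            # LoadDisplCurve | path
        self.rollers_mm = rollers_mm  # optional per-specimen override
        self.load_position_mm = load_position_mm
        self._fe_cache = None         # (mask, solution), set by run_demo

    @property
    def uid(self) -> str:
        return f"{self.animal}_{self.timepoint}_{self.side}"


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
            log.info("stage %-12s done in %.2f s", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


@_stage("preprocess")
def _preprocess(volume, cfg: PipelineConfig, crop: SpanCrop):
    img = volume if isinstance(volume, VoxelImage) else read_volume(volume)
    img = downsample_to(img, cfg.preprocessing.target_um)
    mask = threshold_permille(
        img, cfg.preprocessing.permille, reference=cfg.preprocessing.threshold_reference
    )
    mask = crop_to_span(mask, crop)
    return largest_component(mask), local_span_crop(mask, crop)


@_stage("solve")
def _solve_fe(mask, lcrop, cfg: PipelineConfig):
    material = Material(cfg.fe.youngs_modulus_gpa, cfg.fe.poisson_ratio)
    model = build_model(
        mask, material, lcrop,
        contact_halfwidth_vox=cfg.fe.contact_halfwidth_vox,
        prescribed_displacement_mm=cfg.fe.prescribed_displacement_mm,
    )
    return solve(model, tol=cfg.fe.tol, max_iter=cfg.fe.max_iter)


@_stage("bend-analyze")
def _analyze(curve, cfg: PipelineConfig):
    if not isinstance(curve, LoadDisplCurve):
        curve = read_curve(curve)
    rule = WindowRule(
        cfg.mechtest.band_lo, cfg.mechtest.band_hi,
        cfg.mechtest.min_fraction, cfg.mechtest.r2_floor,
    )
    return analyze_curve(curve, rule, cfg.mechtest.yield_deviation_fraction)


def run_pipeline(
    config: PipelineConfig, specimens: list[Specimen], outdir: str | Path | None = None
) -> dict:
    """Run the full chain on a list of specimens and write the report bundle
    (summaries.csv, fe_results.csv, moduli.csv, report.json, manifest.json)."""
    outdir = Path(outdir if outdir is not None else config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows, fe_rows, mod_rows = [], [], []
    for sp in specimens:
        log.info("specimen %s", sp.uid)
        rollers = sp.rollers_mm or config.preprocessing.rollers_mm
        crop = SpanCrop(
            tuple(rollers),
            margin_mm=config.preprocessing.margin_mm,
            load_position_mm=sp.load_position_mm
            if sp.load_position_mm is not None
            else config.preprocessing.load_position_mm,
        )
        if sp._fe_cache is not None:
            mask, sol = sp._fe_cache
        else:
            mask, lcrop = _preprocess(sp.volume, config, crop)
            sol = _solve_fe(mask, lcrop, config)
        summary = _analyze(sp.curve, config)
        calib = back_calculate_tissue_modulus(
            summary.elastic_stiffness_n_per_mm,
            sol.fe_stiffness_n_per_mm,
            config.fe.youngs_modulus_gpa,
        )
        base = {"animal": sp.animal, "timepoint": sp.timepoint, "side": sp.side}
        rows.append(base | {
            "elastic_stiffness_n_per_mm": summary.elastic_stiffness_n_per_mm,
            "yield_load_n": summary.yield_load_n,
            "ultimate_load_n": summary.ultimate_load_n,
            "fit_r2": summary.fit_r2,
            "low_quality": summary.low_quality,
        })
        fe_rows.append(base | {
            "fe_stiffness_n_per_mm": sol.fe_stiffness_n_per_mm,
            "n_elements": mask.n_voxels,
            "solver_iterations": sol.solver_iterations,
            "residual": sol.residual,
        })
        mod_rows.append(base | {
            "k_exp_n_per_mm": calib.k_exp_n_per_mm,
            "k_fe_n_per_mm": calib.k_fe_n_per_mm,
            "e_ref_gpa": calib.e_ref_gpa,
            "e_tissue_gpa": calib.e_tissue_gpa,
        })

    summaries = pd.DataFrame(rows)
    fe_results = pd.DataFrame(fe_rows)
    moduli = pd.DataFrame(mod_rows)
    report = cohort_report(
        summaries,
        fe_results,
        e_ref_gpa=config.fe.youngs_modulus_gpa,
        wilcoxon_mode=config.stats.wilcoxon_mode,
        alpha=config.stats.alpha,
    )
    manifest = {
        "bonefe_version": __version__,
        "seed": config.seed,
        "parameter_hash": config.parameter_hash(),
        "config": config.to_dict(),
        "specimens": [sp.uid for sp in specimens],
    }
    summaries.to_csv(outdir / "summaries.csv", index=False)
    fe_results.to_csv(outdir / "fe_results.csv", index=False)
    moduli.to_csv(outdir / "moduli.csv", index=False)
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {
        "summaries": summaries,
        "fe_results": fe_results,
        "moduli": moduli,
        "report": report,
        "manifest": manifest,
    }


# ---------------------------------------------------------------------------
# Demo cohort


def _child_seed(base: int, *key: int) -> int:
    ss = np.random.SeedSequence([int(base), *map(int, key)])
    return int(ss.generate_state(1)[0] % 2**31)


def run_demo(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Synthesize the demo cohort and run the full pipeline on it.

    The "experimental" curve of each bone is generated from the ground-truth
    stiffness k_true = k_FE(E_ref) * E_true / E_ref, so tissue-modulus
    calibration has a known answer; curve noise and phantom noise come from
    seeds derived from ``config.seed``.
    """
    c = config.cohort
    inset = 0.4
    rollers = (inset, c.length_mm - inset)
    e_ref = config.fe.youngs_modulus_gpa
    specimens: list[Specimen] = []
    truth_rows = []
    for it, tp in enumerate(c.timepoints):
        for pair in range(c.n_pairs):
            seed = _child_seed(config.seed, it, pair)
            rng = np.random.default_rng(seed)
            sigma = np.sqrt(np.log1p(c.modulus_cv**2))
            e_control = c.control_modulus_gpa * np.exp(rng.normal(-sigma**2 / 2, sigma))
            # animal-level anatomy scatter, shared by the two sides of a pair
            geo = float(np.clip(1.0 + c.geometry_cv * rng.standard_normal(),
                                1.0 - 3 * c.geometry_cv, 1.0 + 3 * c.geometry_cv))
            for k_side, side in enumerate(("control", "treated")):
                e_true = (
                    e_control
                    if side == "control"
                    else e_control * (1.0 + c.treatment_modulus_effect)
                )
                pspec = PhantomSpec(
                    length_mm=c.length_mm,
                    outer_radius_mm=c.outer_radius_mm * geo,
                    cortical_thickness_mm=c.cortical_thickness_mm * geo,
                    woven_bone_mm=c.woven_bone_mm if side == "treated" else 0.0,
                    periosteal_thickening_mm=(
                        c.periosteal_thickening_mm if side == "treated" else 0.0
                    ),
                    voxel_size_um=c.voxel_size_um,
                    blur_sigma_um=c.blur_sigma_um,
                    noise_sd=c.noise_sd,
                    seed=_child_seed(seed, 1, k_side),
                )
                volume = generate_femur_phantom(pspec)
                crop = SpanCrop(rollers, margin_mm=config.preprocessing.margin_mm)
                mask, lcrop = _preprocess(volume, config, crop)
                sol = _solve_fe(mask, lcrop, config)
                k_true = sol.fe_stiffness_n_per_mm * e_true / e_ref
                yield_load = k_true * c.yield_over_stiffness_mm
                cspec = CurveSpec(
                    stiffness_n_per_mm=k_true,
                    yield_load_n=yield_load,
                    ultimate_load_n=yield_load * c.ultimate_over_yield,
                    noise_sd_n=c.curve_noise_sd_n,
                    seed=_child_seed(seed, 2, k_side),
                )
                curve = generate_load_curve(cspec)
                animal = f"rat{it * c.n_pairs + pair + 1:02d}"
                sp = Specimen(animal, tp, side, volume, curve, rollers_mm=rollers)
                sp._fe_cache = (mask, sol)
                specimens.append(sp)
                truth_rows.append(
                    {
                        "animal": animal,
                        "timepoint": tp,
                        "side": side,
                        "e_true_gpa": e_true,
                        "k_true_n_per_mm": k_true,
                    }
                )
    result = run_pipeline(config, specimens, outdir)
    truth = pd.DataFrame(truth_rows)
    outdir = Path(outdir if outdir is not None else config.output_dir)
    truth.to_csv(outdir / "ground_truth.csv", index=False)
    result["ground_truth"] = truth
    return result
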