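"""Synthetic femur phantoms, bending curves, and paired cohorts.

Real scans and destructive tests from the ablation study are not available,
so every downstream stage is exercised on synthetic data with known ground
truth:

* a rat-femur mid-shaft emulated as a hollow cortical cylinder in a grayscale
  volume, optionally with an endosteal woven-bone shell and periosteal
  thickening (the geometric signatures of post-ablation bone modeling),
  degraded by partial-volume blur and additive noise;
* bilinear load-displacement curves with prescribed stiffness, yield load and
  ultimate load;
* paired treated/control cohorts with a known multiplicative effect.

The hollow cylinder is deliberately simple: it admits a closed-form
Timoshenko three-point-bending stiffness, which serves as the independent
oracle for the voxel FE solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .imageproc import VoxelImage

__all__ = [
    "PhantomSpec",
    "CurveSpec",
    "PairedCohortSpec",
    "generate_femur_phantom",
    "generate_load_curve",
    "generate_paired_cohort",
    "annulus_cross_section_area_mm2",
]


@dataclass
class PhantomSpec:
    """Geometry and imaging parameters of the femur mid-shaft phantom.

    The shaft runs along axis 0, centered in the cross-section. Gray levels
    are fractions of the data-range maximum; with ``bone_gray_level > 0.5``
    and no blur/noise the phantom's bone voxels survive the 500 per-mille
    threshold exactly.
    """

    length_mm: float = 12.0
    outer_radius_mm: float = 2.0
    cortical_thickness_mm: float = 0.6
    woven_bone_mm: float = 0.0        # endosteal shell (treated bones)
    periosteal_thickening_mm: float = 0.0
    voxel_size_um: float = 25.0
    bone_gray_level: float = 0.75
    background_gray_level: float = 0.05
    blur_sigma_um: float = 0.0
    noise_sd: float = 0.0             # fraction of the data range
    padding_mm: float = 0.5           # air margin around the bone on axes 1, 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("length_mm", "outer_radius_mm", "cortical_thickness_mm",
                     "voxel_size_um"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if not self.cortical_thickness_mm < self.outer_radius_mm:
            raise ValueError("cortical_thickness_mm must be < outer_radius_mm")
        for name in ("woven_bone_mm", "periosteal_thickening_mm", "blur_sigma_um",
                     "noise_sd", "padding_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("bone_gray_level", "background_gray_level"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        inner = self.outer_radius_mm - self.cortical_thickness_mm
        if self.woven_bone_mm > inner:
            raise ValueError(
                "woven_bone_mm exceeds the medullary radius "
                f"({inner:.3f} mm): shell would overfill the canal"
            )

    @property
    def total_outer_radius_mm(self) -> float:
        return self.outer_radius_mm + self.periosteal_thickening_mm

    @property
    def inner_radius_mm(self) -> float:
        return self.outer_radius_mm - self.cortical_thickness_mm


def annulus_cross_section_area_mm2(spec: PhantomSpec) -> float:
    """Closed-form mineralized cross-section area of the ideal phantom."""
    r_out = spec.total_outer_radius_mm
    r_in = spec.inner_radius_mm
    area = np.pi * (r_out**2 - r_in**2)
    if spec.woven_bone_mm > 0:
        area += np.pi * (r_in**2 - (r_in - spec.woven_bone_mm) ** 2)
    return float(area)


def generate_femur_phantom(spec: PhantomSpec) -> VoxelImage:
    """Render the phantom into a grayscale volume (bone where the voxel
    *center* lies inside the mineralized annulus), then blur, then add noise.

    Deterministic: the same spec (including seed) yields a bit-identical
    volume.
    """
    s = spec.voxel_size_um / 1000.0  # mm
    r_out = spec.total_outer_radius_mm
    half = r_out + spec.padding_mm
    n_ax = int(round(spec.length_mm / s))
    n_tr = int(np.ceil(2 * half / s))
    if n_ax < 1:
        raise ValueError("length_mm smaller than one voxel along the shaft axis")
    if n_tr < 3:
        raise ValueError(
            f"transverse extent {2 * half:.3f} mm too small for voxel size "
            f"{spec.voxel_size_um} um"
        )

    # voxel-center coordinates in the cross-section, bone axis at the center
    c = n_tr * s / 2.0
    yy = (np.arange(n_tr) + 0.5) * s - c
    r2 = yy[:, None] ** 2 + yy[None, :] ** 2

    r_in = spec.inner_radius_mm
    bone2d = (r2 <= r_out**2) & (r2 > r_in**2)
    if spec.woven_bone_mm > 0:
        woven_in = r_in - spec.woven_bone_mm
        bone2d |= (r2 <= r_in**2) & (r2 > woven_in**2)

    grid = np.full((n_ax, n_tr, n_tr), spec.background_gray_level, dtype=np.float64)
    grid[:, bone2d] = spec.bone_gray_level

    if spec.blur_sigma_um > 0:
        grid = ndimage.gaussian_filter(grid, sigma=spec.blur_sigma_um / spec.voxel_size_um)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        grid = grid + rng.normal(0.0, spec.noise_sd, size=grid.shape)
    np.clip(grid, 0.0, 1.0, out=grid)
    return VoxelImage(grid, spec.voxel_size_um, data_range_max=1.0)


# ---------------------------------------------------------------------------
# Load-displacement curves


@dataclass
class CurveSpec:
    """Bilinear-plus-failure model of a destructive bending curve.

    Linear at ``stiffness_n_per_mm`` up to the yield point, then a reduced
    post-yield slope up to the ultimate load, then a sharp drop to
    ``failure_drop_fraction`` of the ultimate load. Sampling follows the
    cross-head speed (0.1 mm/min in the emulated protocol) at the given
    interval; Gaussian force noise is added on top.
    """

    stiffness_n_per_mm: float = 300.0
    yield_load_n: float = 40.0
    ultimate_load_n: float = 60.0
    post_yield_stiffness_fraction: float = 0.2
    failure_drop_fraction: float = 0.5
    displacement_rate_mm_per_min: float = 0.1
    sample_interval_s: float = 0.5
    noise_sd_n: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.stiffness_n_per_mm > 0:
            raise ValueError("stiffness_n_per_mm must be > 0")
        if not 0 < self.yield_load_n < self.ultimate_load_n:
            raise ValueError("need 0 < yield_load_n < ultimate_load_n")
        if not 0 <= self.post_yield_stiffness_fraction < 1:
            raise ValueError("post_yield_stiffness_fraction must be in [0, 1)")
        if not 0 <= self.failure_drop_fraction < 1:
            raise ValueError("failure_drop_fraction must be in [0, 1)")
        if self.noise_sd_n < 0:
            raise ValueError("noise_sd_n must be >= 0")
        if not self.displacement_rate_mm_per_min > 0 or not self.sample_interval_s > 0:
            raise ValueError("rate and sample interval must be > 0")
        if self.post_yield_stiffness_fraction == 0:
            raise ValueError(
                "flat post-yield segment never reaches the ultimate load; "
                "use post_yield_stiffness_fraction > 0"
            )

    @property
    def yield_displacement_mm(self) -> float:
        return self.yield_load_n / self.stiffness_n_per_mm

    @property
    def ultimate_displacement_mm(self) -> float:
        k2 = self.post_yield_stiffness_fraction * self.stiffness_n_per_mm
        return self.yield_displacement_mm + (self.ultimate_load_n - self.yield_load_n) / k2


def ideal_force(spec: CurveSpec, d: np.ndarray) -> np.ndarray:
    """Noise-free force at displacement ``d`` under the bilinear model."""
    d = np.asarray(d, dtype=np.float64)
    k = spec.stiffness_n_per_mm
    k2 = spec.post_yield_stiffness_fraction * k
    d_y, d_u = spec.yield_displacement_mm, spec.ultimate_displacement_mm
    f = np.where(d <= d_y, k * d, spec.yield_load_n + k2 * (d - d_y))
    # tolerant comparison: a sampling point one ulp past the apex still
    # belongs to the rising branch
    past = d > d_u * (1.0 + 1e-12) + 1e-15
    f = np.where(past, spec.failure_drop_fraction * spec.ultimate_load_n, f)
    return f


def generate_load_curve(spec: CurveSpec, metadata: dict | None = None):
    """Sample the bilinear curve at rate-implied displacement steps.

    Returns a :class:`bonefe.mechtest.LoadDisplCurve`. The record extends a
    short distance past the ultimate point so the failure drop is visible.
    """
    from .mechtest import LoadDisplCurve  # local import: avoid cycle

    step = spec.displacement_rate_mm_per_min / 60.0 * spec.sample_interval_s
    d_end = spec.ultimate_displacement_mm * 1.05 + step
    n = max(int(np.ceil(d_end / step)) + 1, 21)
    d = np.arange(n) * step
    # the apex (d_u, F_u) is part of the record: the testing machine logs the
    # peak even when it falls between regular sampling instants
    d_u = spec.ultimate_displacement_mm
    if np.abs(d - d_u).min() > 1e-12:
        d = np.insert(d, np.searchsorted(d, d_u), d_u)
    f = ideal_force(spec, d)
    if spec.noise_sd_n > 0:
        rng = np.random.default_rng(spec.seed)
        f = f + rng.normal(0.0, spec.noise_sd_n, size=n)
        f[0] = 0.0
    return LoadDisplCurve(d, f, metadata=dict(metadata or {}))


# ---------------------------------------------------------------------------
# Paired cohorts


@dataclass
class PairedCohortSpec:
    """Paired treated/control mechanical-property cohort.

    Control values are i.i.d. lognormal with the given mean and coefficient
    of variation; treated = control * (1 + effect) * exp(pair noise). The
    default of three pairs matches a study arm in which three bone pairs per
    timepoint reach mechanical testing.
    """

    n_pairs: int = 3
    control_mean: float = 300.0
    control_cv: float = 0.15
    treatment_effect: float = 0.0     # e.g. -0.16 for 16 % less
    pair_noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if not self.control_mean > 0:
            raise ValueError("control_mean must be > 0")
        if self.control_cv < 0 or self.pair_noise_cv < 0:
            raise ValueError("coefficients of variation must be >= 0")
        if self.treatment_effect <= -1:
            raise ValueError("treatment_effect must be > -1 (values stay positive)")


def generate_paired_cohort(spec: PairedCohortSpec) -> list[tuple[float, float]]:
    """Draw ``n_pairs`` (control, treated) value pairs; seeded and pure."""
    rng = np.random.default_rng(spec.seed)
    # lognormal with exact mean and cv
    sigma2 = np.log1p(spec.control_cv**2)
    mu = np.log(spec.control_mean) - sigma2 / 2.0
    control = np.exp(rng.normal(mu, np.sqrt(sigma2), size=spec.n_pairs))
    noise_sigma = np.sqrt(np.log1p(spec.pair_noise_cv**2))
    noise = rng.normal(0.0, noise_sigma, size=spec.n_pairs) if noise_sigma > 0 else np.zeros(spec.n_pairs)
    treated = control * (1.0 + spec.treatment_effect) * np.exp(noise)
    return list(zip(control.tolist(), treated.tolist()))
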