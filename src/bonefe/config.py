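"""Pipeline configuration: YAML-backed, schema-validated.

Every protocol parameter of the emulated study (50 um working resolution,
500 per-mille threshold, 0.5 mm crop margin, 10 GPa reference modulus,
Poisson 0.3, 0.1 mm/min cross-head speed) lives here as a default rather
than a constant in code. Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field, fields

import yaml

__all__ = [
    "PreprocessingConfig",
    "FEConfig",
    "MechTestConfig",
    "StatsConfig",
    "CohortConfig",
    "PipelineConfig",
    "load_config",
]


def _from_dict(cls, data: dict, path: str = ""):
    if not isinstance(data, dict):
        raise ValueError(f"config section {path or cls.__name__} must be a mapping")
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(
            f"unknown config key(s) {sorted(unknown)} in section "
            f"'{path or cls.__name__}'"
        )
    kwargs = {}
    for name, f in known.items():
        if name not in data:
            continue
        sub = f.metadata.get("section")
        if sub is not None:
            kwargs[name] = _from_dict(sub, data[name], f"{path}.{name}".lstrip("."))
        else:
            kwargs[name] = data[name]
    return cls(**kwargs)


@dataclass
class PreprocessingConfig:
    target_um: float = 50.0
    permille: float = 500.0
    threshold_reference: str = "range"
    rollers_mm: tuple[float, float] = (1.0, 11.0)
    margin_mm: float = 0.5
    load_position_mm: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.permille <= 1000:
            raise ValueError("permille must be in (0, 1000]")
        if self.threshold_reference not in ("range", "observed"):
            raise ValueError("threshold_reference must be 'range' or 'observed'")
        if not self.target_um > 0:
            raise ValueError("target_um must be positive")
        self.rollers_mm = tuple(float(x) for x in self.rollers_mm)
        if len(self.rollers_mm) != 2:
            raise ValueError("rollers_mm needs exactly two positions")


@dataclass
class FEConfig:
    youngs_modulus_gpa: float = 10.0
    poisson_ratio: float = 0.3
    tol: float = 1e-6
    contact_halfwidth_vox: int = 1
    prescribed_displacement_mm: float = -0.01
    max_iter: int | None = None

    def __post_init__(self) -> None:
        if not self.youngs_modulus_gpa > 0:
            raise ValueError("youngs_modulus_gpa must be positive")
        if not -1.0 < self.poisson_ratio < 0.5:
            raise ValueError("poisson_ratio must lie in (-1, 0.5)")
        if not 0 < self.tol < 1:
            raise ValueError("tol must be in (0, 1)")
        if self.contact_halfwidth_vox < 0:
            raise ValueError("contact_halfwidth_vox must be >= 0")
        if self.prescribed_displacement_mm == 0:
            raise ValueError("prescribed displacement must be nonzero")


@dataclass
class MechTestConfig:
    band_lo: float = 0.10
    band_hi: float = 0.60
    min_fraction: float = 0.15
    r2_floor: float = 0.90
    yield_deviation_fraction: float = 0.05

    def __post_init__(self) -> None:
        if not 0 <= self.band_lo < self.band_hi <= 1:
            raise ValueError("need 0 <= band_lo < band_hi <= 1")
        if not 0 < self.yield_deviation_fraction < 1:
            raise ValueError("yield_deviation_fraction must be in (0, 1)")


@dataclass
class StatsConfig:
    wilcoxon_mode: str = "asymptotic"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.wilcoxon_mode not in ("asymptotic", "exact"):
            raise ValueError("wilcoxon_mode must be 'asymptotic' or 'exact'")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class CohortConfig:
    """Synthetic paired cohort for the demo pipeline.

    Each animal contributes a treated and a control femur phantom; treated
    bones get an endosteal woven-bone shell, periosteal thickening and a
    multiplicative tissue-modulus effect. The phantom geometry here is a
    scaled-down mid-shaft segment so a demo run stays interactive.
    """

    n_pairs: int = 2
    timepoints: tuple[str, ...] = ("7d", "1m")
    length_mm: float = 4.4
    outer_radius_mm: float = 0.5
    cortical_thickness_mm: float = 0.2
    voxel_size_um: float = 25.0
    blur_sigma_um: float = 15.0
    noise_sd: float = 0.02
    control_modulus_gpa: float = 12.0
    modulus_cv: float = 0.08
    geometry_cv: float = 0.03        # per-animal scatter of radius/thickness
    treatment_modulus_effect: float = -0.05
    woven_bone_mm: float = 0.06
    periosteal_thickening_mm: float = 0.04
    curve_noise_sd_n: float = 0.2
    yield_over_stiffness_mm: float = 0.12   # yield displacement scale
    ultimate_over_yield: float = 1.5

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        self.timepoints = tuple(self.timepoints)


@dataclass
class PipelineConfig:
    preprocessing: PreprocessingConfig = field(
        default_factory=PreprocessingConfig, metadata={"section": PreprocessingConfig}
    )
    fe: FEConfig = field(default_factory=FEConfig, metadata={"section": FEConfig})
    mechtest: MechTestConfig = field(
        default_factory=MechTestConfig, metadata={"section": MechTestConfig}
    )
    stats: StatsConfig = field(
        default_factory=StatsConfig, metadata={"section": StatsConfig}
    )
    cohort: CohortConfig = field(
        default_factory=CohortConfig, metadata={"section": CohortConfig}
    )
    seed: int = 0
    output_dir: str = "bonefe_out"

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        return _from_dict(cls, data)

    def to_dict(self) -> dict:
        def conv(obj):
            if dataclasses.is_dataclass(obj):
                return {f.name: conv(getattr(obj, f.name)) for f in fields(obj)}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return conv(self)

    def parameter_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | os.PathLike | None) -> PipelineConfig:
    """Load a YAML config file; a missing path yields all defaults."""
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)
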