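"""Closed-form Timoshenko three-point-bending stiffness.

Independent oracle for validating the voxel FE solver: a simply supported
beam with a central point load deflects by

    delta = F L^3 / (48 E I) + F L / (4 kappa G A)

so the midspan stiffness is k = [L^3/(48 E I) + L/(4 kappa G A)]^{-1}, with
shear modulus G = E / (2 (1 + nu)) and section-dependent shear correction
factor kappa.
"""

from __future__ import annotations

import numpy as np

from .microfe import Material

__all__ = [
    "three_point_bending_stiffness",
    "rect_section",
    "annulus_section",
    "kappa_rectangle",
    "kappa_annulus",
]


def kappa_rectangle() -> float:
    """Classical shear correction factor for a rectangular section."""
    return 5.0 / 6.0


def kappa_annulus(r_outer: float, r_inner: float, nu: float) -> float:
    """Cowper's shear correction factor for a hollow circular section."""
    m2 = (r_inner / r_outer) ** 2
    return (
        6.0 * (1.0 + nu) * (1.0 + m2) ** 2
        / ((7.0 + 6.0 * nu) * (1.0 + m2) ** 2 + (20.0 + 12.0 * nu) * m2)
    )


def rect_section(width_mm: float, height_mm: float) -> tuple[float, float, float]:
    """(area mm^2, bending inertia mm^4, kappa) for a b x h rectangle bent
    about the horizontal axis."""
    A = width_mm * height_mm
    I = width_mm * height_mm**3 / 12.0
    return A, I, kappa_rectangle()


def annulus_section(
    r_outer_mm: float, r_inner_mm: float, nu: float = 0.3
) -> tuple[float, float, float]:
    """(area, inertia, kappa) for a hollow circular section."""
    if not 0 <= r_inner_mm < r_outer_mm:
        raise ValueError("need 0 <= r_inner < r_outer")
    A = np.pi * (r_outer_mm**2 - r_inner_mm**2)
    I = np.pi * (r_outer_mm**4 - r_inner_mm**4) / 4.0
    return float(A), float(I), kappa_annulus(r_outer_mm, r_inner_mm, nu)


def three_point_bending_stiffness(
    span_mm: float,
    material: Material,
    area_mm2: float,
    inertia_mm4: float,
    kappa: float,
) -> float:
    """Midspan stiffness in N/mm of a centrally loaded simply supported
    Timoshenko beam."""
    E = material.youngs_modulus_gpa * 1000.0  # N/mm^2
    G = material.shear_modulus_gpa * 1000.0
    L = span_mm
    compliance = L**3 / (48.0 * E * inertia_mm4) + L / (4.0 * kappa * G * area_mm2)
    return 1.0 / compliance
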