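"""Volume I/O and the micro-CT preprocessing chain.

The pipeline mirrors the standard whole-bone micro-FE workflow: reorient the
scan so the shaft lies along the bending axis, reduce resolution (25 -> 50 um
by block averaging), segment mineralized bone with a single global threshold
expressed in per mille of the maximum possible intensity, crop to the bending
span (region between the bottom rollers plus a margin), and keep the largest
connected component so the stiffness matrix is non-singular.

Axis convention throughout: axis 0 = bone shaft / roller-span direction,
axis 2 = vertical loading direction. Coordinates are 0-based with half-open
intervals; the center of voxel i sits at (i + 0.5) * spacing.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import SimpleITK as sitk
import tifffile
from scipy import ndimage

__all__ = [
    "VoxelImage",
    "BoneMask",
    "SpanCrop",
    "read_volume",
    "write_volume",
    "reorient",
    "downsample_to",
    "threshold_permille",
    "crop_to_span",
    "largest_component",
    "preprocess",
]

# maximum representable intensity per storage dtype ("maximum possible value")
_DTYPE_RANGE_MAX = {
    np.dtype(np.uint8): 255.0,
    np.dtype(np.int16): 32767.0,
    np.dtype(np.uint16): 65535.0,
    np.dtype(np.int32): 2147483647.0,
    np.dtype(np.float32): 1.0,
    np.dtype(np.float64): 1.0,
}


def _range_max_for(dtype: np.dtype) -> float:
    try:
        return _DTYPE_RANGE_MAX[np.dtype(dtype)]
    except KeyError:
        raise ValueError(f"unsupported volume dtype {dtype!r}")


@dataclass
class VoxelImage:
    """3D grayscale grid with isotropic physical voxel size.

    Parameters
    ----------
    grid :
        3D scalar intensity array; axis 0 is the shaft direction, axis 2 the
        vertical load direction.
    voxel_size_um :
        Isotropic voxel spacing in micrometres.
    data_range_max :
        Maximum representable intensity of the storage format (e.g. 32767 for
        int16, 1.0 for a float image). The per-mille threshold refers to this.
    """

    grid: np.ndarray
    voxel_size_um: float
    data_range_max: float = 1.0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3 or self.grid.size == 0:
            raise ValueError("grid must be a non-empty 3D array")
        if not self.voxel_size_um > 0:
            raise ValueError("voxel_size_um must be positive")
        if not self.data_range_max > 0:
            raise ValueError("data_range_max must be positive")
        lo, hi = float(self.grid.min()), float(self.grid.max())
        if lo < 0 or hi > self.data_range_max * (1 + 1e-9):
            raise ValueError(
                f"intensities [{lo}, {hi}] outside [0, {self.data_range_max}]"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    @property
    def voxel_size_mm(self) -> float:
        return self.voxel_size_um / 1000.0


@dataclass
class BoneMask:
    """Binary 3D grid of mineralized-bone voxels (same axis convention)."""

    grid: np.ndarray
    voxel_size_um: float

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 3 or self.grid.size == 0:
            raise ValueError("mask grid must be a non-empty 3D array")
        if not self.voxel_size_um > 0:
            raise ValueError("voxel_size_um must be positive")

    @property
    def voxel_size_mm(self) -> float:
        return self.voxel_size_um / 1000.0

    @property
    def n_voxels(self) -> int:
        return int(self.grid.sum())


@dataclass
class SpanCrop:
    """Bending-span crop window along the shaft axis.

    ``roller_positions_mm`` are the two bottom-support coordinates along
    axis 0; the kept region is [min - margin, max + margin). The top-roller
    ``load_position_mm`` defaults to the midpoint of the supports.
    """

    roller_positions_mm: tuple[float, float]
    margin_mm: float = 0.5
    load_position_mm: float | None = None

    def __post_init__(self) -> None:
        a, b = self.roller_positions_mm
        if not (np.isfinite(a) and np.isfinite(b)) or a == b:
            raise ValueError("roller positions must be two distinct coordinates")
        if self.margin_mm < 0:
            raise ValueError("margin_mm must be >= 0")
        if self.load_position_mm is None:
            self.load_position_mm = 0.5 * (a + b)
        lo, hi = min(a, b), max(a, b)
        if not (lo < self.load_position_mm < hi):
            raise ValueError("load position must lie strictly between the supports")

    @property
    def span_mm(self) -> float:
        a, b = self.roller_positions_mm
        return abs(b - a)


# ---------------------------------------------------------------------------
# I/O


def read_volume(path: str | os.PathLike, *, spacing_um: float | None = None) -> VoxelImage:
    """Read a MetaImage (.mha/.mhd), NIfTI (.nii/.nii.gz) or TIFF-stack volume.

    TIFF stacks carry no reliable physical spacing, so ``spacing_um`` is
    required for them; for the other formats spacing comes from the header and
    must be isotropic.
    """
    path = os.fspath(path)
    lower = path.lower()
    if lower.endswith((".tif", ".tiff")):
        if spacing_um is None:
            raise ValueError(
                "TIFF stack carries no spacing metadata: pass spacing_um explicitly"
            )
        grid = np.asarray(tifffile.imread(path))
        return VoxelImage(grid, spacing_um, data_range_max=_range_max_for(grid.dtype))
    img = sitk.ReadImage(path)
    spacing = np.asarray(img.GetSpacing(), dtype=float)  # mm, (x, y, z)
    if not np.allclose(spacing, spacing[0], rtol=1e-6):
        raise ValueError(
            f"anisotropic spacing {tuple(spacing)} mm: pipeline assumes isotropic "
            "voxels; resample first"
        )
    # SimpleITK arrays come back (z, y, x); our axis 0 is the shaft axis which
    # we store as the image x axis, so transpose back to (x, y, z).
    grid = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return VoxelImage(
        grid, float(spacing[0]) * 1000.0, data_range_max=_range_max_for(grid.dtype)
    )


def write_volume(img: VoxelImage | BoneMask, path: str | os.PathLike) -> None:
    """Write a volume or mask as MetaImage/NIfTI (masks as 8-bit)."""
    path = os.fspath(path)
    grid = img.grid
    if grid.dtype == bool:
        grid = grid.astype(np.uint8)
    itk = sitk.GetImageFromArray(np.ascontiguousarray(grid.transpose(2, 1, 0)))
    s = img.voxel_size_um / 1000.0
    itk.SetSpacing((s, s, s))
    sitk.WriteImage(itk, path)


# ---------------------------------------------------------------------------
# Preprocessing operations


_ROT90_PLANES = {"xy": (0, 1), "xz": (0, 2), "yz": (1, 2)}


def reorient(
    img: VoxelImage,
    rotation: tuple[tuple[int, int, int], tuple[bool, bool, bool]] | tuple[float, float, float] | None = None,
    *,
    angles_deg: tuple[float, float, float] | None = None,
) -> VoxelImage:
    """Rotate a scan into the three-point-bending frame.

    Two forms are supported:

    * axis permutation + flips ``((p0, p1, p2), (f0, f1, f2))`` — lossless;
    * ``angles_deg=(a_xy, a_xz, a_yz)`` — successive in-plane rotations by
      arbitrary angles, resampled with trilinear interpolation.
    """
    if rotation is None and angles_deg is None:
        return VoxelImage(img.grid.copy(), img.voxel_size_um, img.data_range_max)
    if angles_deg is not None:
        grid = img.grid.astype(np.float64)
        for plane, ang in zip(("xy", "xz", "yz"), angles_deg):
            if ang:
                grid = ndimage.rotate(
                    grid, ang, axes=_ROT90_PLANES[plane], reshape=False,
                    order=1, mode="constant", cval=float(grid.min()),
                )
        grid = np.clip(grid, 0.0, img.data_range_max)
        return VoxelImage(grid, img.voxel_size_um, img.data_range_max)
    perm, flips = rotation
    if sorted(perm) != [0, 1, 2]:
        raise ValueError(f"{perm!r} is not a permutation of (0, 1, 2)")
    grid = np.transpose(img.grid, perm)
    for ax, f in enumerate(flips):
        if f:
            grid = np.flip(grid, axis=ax)
    return VoxelImage(grid.copy(), img.voxel_size_um, img.data_range_max)


def downsample_to(img: VoxelImage, target_um: float = 50.0) -> VoxelImage:
    """Reduce resolution by block averaging to ``target_um`` spacing.

    The target must be an integer multiple of the source spacing (25 -> 50 um
    is factor 2); each output voxel is the arithmetic mean of its source
    block, which conserves integrated density. Trailing voxels that do not
    fill a complete block are discarded.
    """
    factor = target_um / img.voxel_size_um
    f = int(round(factor))
    if abs(factor - f) > 1e-6 or f < 1:
        raise ValueError(
            f"target spacing {target_um} um is not an integer multiple of "
            f"{img.voxel_size_um} um; reorient/resample to a compatible grid first"
        )
    if f == 1:
        return VoxelImage(img.grid.copy(), img.voxel_size_um, img.data_range_max)
    nx, ny, nz = (s // f for s in img.grid.shape)
    if min(nx, ny, nz) == 0:
        raise ValueError("volume smaller than one output voxel")
    g = img.grid[: nx * f, : ny * f, : nz * f].astype(np.float64)
    g = g.reshape(nx, f, ny, f, nz, f).mean(axis=(1, 3, 5))
    return VoxelImage(g, target_um, img.data_range_max)


def threshold_permille(
    img: VoxelImage, permille: float = 500.0, *, reference: str = "range"
) -> BoneMask:
    """Segment bone with a single global threshold in per mille.

    A voxel is bone iff intensity >= permille/1000 * reference maximum, where
    the reference is the maximum *possible* value of the storage format
    (``reference="range"``, default) or the observed image maximum
    (``reference="observed"``).
    """
    if not 0 < permille <= 1000:
        raise ValueError("permille must be in (0, 1000]")
    if reference == "range":
        ref = img.data_range_max
    elif reference == "observed":
        ref = float(img.grid.max())
    else:
        raise ValueError("reference must be 'range' or 'observed'")
    cut = permille / 1000.0 * ref
    return BoneMask(img.grid >= cut, img.voxel_size_um)


def crop_to_span(mask: BoneMask, crop: SpanCrop) -> BoneMask:
    """Crop to the region between the bottom rollers plus the margin.

    The kept axis-0 index range is the half-open [floor(lo/s), ceil(hi/s))
    with lo = min(roller) - margin and hi = max(roller) + margin; the other
    axes keep their full extent.
    """
    s = mask.voxel_size_mm
    a, b = crop.roller_positions_mm
    lo = min(a, b) - crop.margin_mm
    hi = max(a, b) + crop.margin_mm
    i0 = max(int(np.floor(lo / s + 1e-9)), 0)
    i1 = min(int(np.ceil(hi / s - 1e-9)), mask.grid.shape[0])
    if i1 <= i0:
        raise ValueError(
            f"crop window [{lo}, {hi}] mm does not intersect the volume "
            f"(axis 0 extent {mask.grid.shape[0] * s} mm)"
        )
    out = mask.grid[i0:i1].copy()
    if not out.any():
        raise ValueError("crop produced an empty mask: no bone in the bending span")
    return BoneMask(out, mask.voxel_size_um)


_FACE_STRUCTURE = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def largest_component(mask: BoneMask) -> BoneMask:
    """Keep only the largest 6-connected component.

    Ties are broken in favour of the component containing the
    lexicographically smallest voxel index (the first one encountered in
    scan order, which is how ``ndimage.label`` numbers them).
    """
    if not mask.grid.any():
        raise ValueError("empty mask")
    labels, n = ndimage.label(mask.grid, structure=_FACE_STRUCTURE)
    if n == 1:
        return BoneMask(mask.grid.copy(), mask.voxel_size_um)
    sizes = np.bincount(labels.ravel())[1:]
    keep = int(np.argmax(sizes)) + 1  # argmax -> first max -> lexicographic tie rule
    return BoneMask(labels == keep, mask.voxel_size_um)


def local_span_crop(mask: BoneMask, crop: SpanCrop) -> SpanCrop:
    """Re-express a crop window in the coordinate frame of the cropped mask.

    After :func:`crop_to_span` the volume origin moves to the crop start;
    roller and load positions must shift accordingly before building the FE
    model on the cropped mask.
    """
    s = mask.voxel_size_mm
    a, b = crop.roller_positions_mm
    offset = max(int(np.floor((min(a, b) - crop.margin_mm) / s + 1e-9)), 0) * s
    return SpanCrop(
        (a - offset, b - offset),
        margin_mm=crop.margin_mm,
        load_position_mm=crop.load_position_mm - offset,
    )


def preprocess(
    img: VoxelImage,
    crop: SpanCrop,
    *,
    rotation=None,
    angles_deg=None,
    target_um: float = 50.0,
    permille: float = 500.0,
    threshold_reference: str = "range",
) -> BoneMask:
    """Full chain in the fixed order reorient -> downsample -> threshold ->
    crop -> largest component."""
    img = reorient(img, rotation, angles_deg=angles_deg)
    img = downsample_to(img, target_um)
    mask = threshold_permille(img, permille, reference=threshold_reference)
    mask = crop_to_span(mask, crop)
    return largest_component(mask)
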