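"""Voxel grids, scalar maps, VOI mask algebra, file I/O and resampling.

Conventions
-----------
* A :class:`VoxelGrid` describes a 3-D rectilinear grid in physical (mm)
  space: ``shape`` (voxels along x, y, z in image index order), ``spacing``
  (mm), ``origin`` (mm) and a row-major 3x3 ``direction`` cosine matrix.
* Array values are stored with shape ``grid.shape`` in (x, y, z) index
  order; conversion to/from SimpleITK transposes to its (z, y, x) layout.
* Count, activity and dose volumes are physically non-negative; negative
  voxels (reconstruction ringing) are clamped to zero at load time.
* Masks are binarised by thresholding at 0.5, matching how binary segments
  survive a nearest-neighbour round trip through float volumes.

Both simulation and therapy inputs are assumed rigidly co-registered
upstream; this module only resamples everything onto a common reference
grid (the simulation attenuation-correction CT grid in the intended
workflow).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import SimpleITK as sitk

logger = logging.getLogger("sirtdose")

#: Default liver tissue density, g/cm^3 (== g/ml).
LIVER_DENSITY_G_ML = 1.05

#: Lesions smaller than this voxel-counted volume are excluded from the
#: analysis (a ~2-cm-diameter sphere); the threshold is strict: exactly
#: 4 ml is retained.
MIN_LESION_ML = 4.0

MAP_KINDS = ("counts", "activity_Bq", "dose_Gy")

_IDENTITY_DIRECTION = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0)


@dataclass(frozen=True)
class VoxelGrid:
    """Geometry of a 3-D rectilinear image grid."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[float, ...] = _IDENTITY_DIRECTION

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(s) for s in self.origin))
        object.__setattr__(self, "direction", tuple(float(d) for d in self.direction))
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError(f"shape must be a positive integer triple, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive mm values, got {self.spacing}")
        if len(self.direction) != 9:
            raise ValueError("direction must be a row-major 3x3 cosine matrix")

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in ml (spacing is in mm; 1 ml = 1000 mm^3)."""
        return float(np.prod(self.spacing)) / 1000.0

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def physical_corners(self) -> np.ndarray:
        """The 8 physical-space corner coordinates of the grid extent, mm."""
        d = np.asarray(self.direction, dtype=float).reshape(3, 3)
        sp = np.asarray(self.spacing)
        out = []
        for ix in (-0.5, self.shape[0] - 0.5):
            for iy in (-0.5, self.shape[1] - 0.5):
                for iz in (-0.5, self.shape[2] - 0.5):
                    idx = np.array([ix, iy, iz])
                    out.append(np.asarray(self.origin) + d @ (idx * sp))
        return np.array(out)


def grid_from_sitk(img: sitk.Image) -> VoxelGrid:
    return VoxelGrid(
        shape=tuple(img.GetSize()),
        spacing=tuple(img.GetSpacing()),
        origin=tuple(img.GetOrigin()),
        direction=tuple(img.GetDirection()),
    )


def _to_sitk(values: np.ndarray, grid: VoxelGrid, dtype=None) -> sitk.Image:
    arr = np.asarray(values)
    if dtype is not None:
        arr = arr.astype(dtype)
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr.T))
    img.SetSpacing(grid.spacing)
    img.SetOrigin(grid.origin)
    img.SetDirection(grid.direction)
    return img


@dataclass
class ScalarMap:
    """A per-voxel scalar volume (counts, activity in Bq, or dose in Gy)."""

    grid: VoxelGrid
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in MAP_KINDS:
            raise ValueError(f"kind must be one of {MAP_KINDS}, got {self.kind!r}")
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("scalar map contains non-finite values")

    def total(self) -> float:
        return float(self.values.sum())

    def copy(self) -> "ScalarMap":
        return ScalarMap(self.grid, self.values.copy(), self.kind)


@dataclass
class VOISet:
    """Labelled binary masks sharing one grid.

    After :func:`derive_vois` the label set includes the source structures
    (``liver``, ``lobe``, each retained lesion) and the derived targets:
    ``TL`` (union of retained lesions), ``NTLw`` (liver minus TL) and
    ``NTLt`` (liver-within-lobe minus TL).
    """

    grid: VoxelGrid
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, m in self.masks.items():
            m = np.asarray(m, dtype=bool)
            if m.shape != self.grid.shape:
                raise ValueError(f"mask {label!r} shape {m.shape} != grid {self.grid.shape}")
            self.masks[label] = m

    def __getitem__(self, label: str) -> np.ndarray:
        return self.masks[label]

    def __contains__(self, label: str) -> bool:
        return label in self.masks

    def labels(self) -> list[str]:
        return list(self.masks)

    def volume_ml(self, label: str) -> float:
        return voi_volume_ml(self.masks[label], self.grid)


# ---------------------------------------------------------------------------
# File I/O (NIfTI / NRRD via SimpleITK)
# ---------------------------------------------------------------------------

def load_map(path: str | Path, kind: str) -> ScalarMap:
    """Read a 3-D volume and return it as a non-negative :class:`ScalarMap`.

    Negative voxels are clamped to zero (counts/activity/dose are
    physically non-negative; small negatives arise from reconstruction
    ringing). Non-finite voxels are an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3:
        raise ValueError(f"{path} is {img.GetDimension()}-D; a 3-D volume is required")
    values = sitk.GetArrayFromImage(img).T.astype(np.float64)
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{path} contains non-finite voxel values")
    n_neg = int((values < 0).sum())
    if n_neg:
        logger.info("clamped %d negative voxels to 0 in %s", n_neg, path.name)
        values = np.clip(values, 0.0, None)
    return ScalarMap(grid_from_sitk(img), values, kind)


def load_mask(path: str | Path) -> tuple[np.ndarray, VoxelGrid]:
    """Read a binary mask volume; values are thresholded at 0.5."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3:
        raise ValueError(f"{path} is {img.GetDimension()}-D; a 3-D volume is required")
    values = sitk.GetArrayFromImage(img).T
    if not np.all(np.isfinite(values.astype(np.float64))):
        raise ValueError(f"{path} contains non-finite voxel values")
    return values > 0.5, grid_from_sitk(img)


def save_map(m: ScalarMap, path: str | Path) -> None:
    """Write a scalar map as NIfTI or NRRD (chosen by file extension)."""
    sitk.WriteImage(_to_sitk(m.values, m.grid), str(path))


def save_mask(mask: np.ndarray, grid: VoxelGrid, path: str | Path) -> None:
    sitk.WriteImage(_to_sitk(np.asarray(mask, dtype=np.uint8), grid), str(path))


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def _check_overlap(grid: VoxelGrid, ref: VoxelGrid) -> None:
    a = grid.physical_corners()
    b = ref.physical_corners()
    lo = np.maximum(a.min(axis=0), b.min(axis=0))
    hi = np.minimum(a.max(axis=0), b.max(axis=0))
    if np.any(lo >= hi):
        raise ValueError("input grid and reference grid do not overlap spatially")


def _reference_image(ref: VoxelGrid) -> sitk.Image:
    img = sitk.Image(list(ref.shape), sitk.sitkFloat64)
    img.SetSpacing(ref.spacing)
    img.SetOrigin(ref.origin)
    img.SetDirection(ref.direction)
    return img


def resample_to_reference(m: ScalarMap, ref_grid: VoxelGrid, mode: str = "trilinear") -> ScalarMap:
    """Resample a scalar map onto a reference grid.

    ``mode='trilinear'`` for continuous maps, ``'nearest'`` for label-like
    data. Voxels outside the input extent become 0.
    """
    if mode not in ("nearest", "trilinear"):
        raise ValueError(f"mode must be 'nearest' or 'trilinear', got {mode!r}")
    if ref_grid == m.grid:
        return m.copy()
    _check_overlap(m.grid, ref_grid)
    interp = sitk.sitkNearestNeighbor if mode == "nearest" else sitk.sitkLinear
    out = sitk.Resample(
        _to_sitk(m.values, m.grid), _reference_image(ref_grid),
        sitk.Transform(), interp, 0.0, sitk.sitkFloat64,
    )
    values = sitk.GetArrayFromImage(out).T
    # interpolation between non-negative samples stays non-negative up to
    # round-off; enforce exactly
    return ScalarMap(ref_grid, np.clip(values, 0.0, None), m.kind)


def resample_mask_to_reference(mask: np.ndarray, grid: VoxelGrid, ref_grid: VoxelGrid) -> np.ndarray:
    """Nearest-neighbour mask resampling (preserves binarity)."""
    if ref_grid == grid:
        return np.asarray(mask, dtype=bool).copy()
    _check_overlap(grid, ref_grid)
    img = _to_sitk(np.asarray(mask, dtype=np.uint8), grid)
    out = sitk.Resample(
        img, _reference_image(ref_grid), sitk.Transform(),
        sitk.sitkNearestNeighbor, 0.0, sitk.sitkUInt8,
    )
    return sitk.GetArrayFromImage(out).T > 0


# ---------------------------------------------------------------------------
# VOI algebra
# ---------------------------------------------------------------------------

def voi_volume_ml(mask: np.ndarray, grid: VoxelGrid) -> float:
    """Voxel-counted volume in ml."""
    return float(np.count_nonzero(mask)) * grid.voxel_volume_ml


def voi_mass_kg(mask: np.ndarray, grid: VoxelGrid, density_g_ml: float = LIVER_DENSITY_G_ML) -> float:
    """Mass in kg at constant tissue density (g/ml)."""
    return voi_volume_ml(mask, grid) * density_g_ml / 1000.0


def exclude_small_lesions(
    lesion_masks: Mapping[str, np.ndarray],
    grid: VoxelGrid,
    min_ml: float = MIN_LESION_ML,
) -> tuple[dict[str, np.ndarray], dict[str, float]]:
    """Drop lesions with voxel-counted volume strictly under ``min_ml``.

    Returns ``(retained, excluded_volumes_ml)``; exclusions are logged.
    A lesion of exactly ``min_ml`` is retained.
    """
    retained: dict[str, np.ndarray] = {}
    excluded: dict[str, float] = {}
    for label, mask in lesion_masks.items():
        vol = voi_volume_ml(mask, grid)
        if vol < min_ml:
            excluded[label] = vol
            logger.info("excluding lesion %s: %.2f ml < %.1f ml", label, vol, min_ml)
        else:
            retained[label] = np.asarray(mask, dtype=bool)
    return retained, excluded


def derive_vois(
    liver: np.ndarray,
    lobe: np.ndarray,
    retained_lesions: Mapping[str, np.ndarray] | Sequence[np.ndarray],
    grid: VoxelGrid,
) -> VOISet:
    """Build the dosimetry targets from source contours.

    TL is the union of the retained lesions ("sum of all contoured
    lesions", as a set union so overlaps are not double counted); NTLw is
    the healthy whole liver (liver minus TL); NTLt is the healthy tissue of
    the targeted lobe, where the lobe contour is first intersected with the
    liver because lobe contours drawn on CT may slightly exceed the liver.
    """
    liver = np.asarray(liver, dtype=bool)
    lobe = np.asarray(lobe, dtype=bool)
    if not liver.any():
        raise ValueError("liver mask is empty")
    if isinstance(retained_lesions, Mapping):
        lesion_items = list(retained_lesions.items())
    else:
        lesion_items = [(f"lesion_{i + 1:02d}", m) for i, m in enumerate(retained_lesions)]
    tl = np.zeros(grid.shape, dtype=bool)
    for _, m in lesion_items:
        tl |= np.asarray(m, dtype=bool)
    masks = {"liver": liver, "lobe": lobe}
    masks.update({label: np.asarray(m, dtype=bool) for label, m in lesion_items})
    masks["TL"] = tl
    masks["NTLw"] = liver & ~tl
    masks["NTLt"] = (lobe & liver) & ~tl
    return VOISet(grid, masks)
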