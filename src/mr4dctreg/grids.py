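"""Grid-aware image containers and NIfTI I/O.

Every object in the pipeline lives on a :class:`Grid`: a regular, axis-aligned
3D lattice with voxel spacing in millimetres.  A voxel's physical position is
the position of its *center*; the grid's physical extent is the box covering
all voxel centers plus half a spacing on each side.  Only axis-aligned NIfTI
affines are supported — the pipeline resamples everything onto the CT
reference grid up front, so oblique headers are rejected rather than silently
reoriented.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import nibabel as nib
import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "Grid",
    "Volume",
    "LabelMap",
    "BinaryMask",
    "OrganInfo",
    "read_volume",
    "write_volume",
    "read_labelmap",
    "resample_to_grid",
    "support_mask",
    "normalize_intensity",
]

Interp = Literal["trilinear", "nearest"]

#: Respiratory phases of the 4D-CT, percent of the cycle; 50% (end expiration)
#: is the reference phase.
PHASES = (0, 16, 33, 50, 66, 83)


@dataclass(frozen=True)
class Grid:
    """Regular axis-aligned 3D lattice.

    Parameters
    ----------
    shape : tuple of int
        Number of voxels along each axis; all entries >= 1.
    spacing : tuple of float
        Voxel spacing in mm along each axis; all entries > 0.
    origin : tuple of float
        Physical position (mm) of the center of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(s) for s in self.origin))
        if len(self.shape) != 3:
            raise ValueError(f"grid must be 3D, got shape {self.shape}")
        if any(s < 1 for s in self.shape):
            raise ValueError(f"all shape entries must be >= 1, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"all spacings must be > 0, got {self.spacing}")

    @property
    def affine(self) -> np.ndarray:
        """4x4 axis-aligned affine mapping voxel index to mm."""
        a = np.eye(4)
        a[:3, :3] = np.diag(self.spacing)
        a[:3, 3] = self.origin
        return a

    @property
    def extent(self) -> tuple[np.ndarray, np.ndarray]:
        """(lo, hi) corners in mm of the physical box (centers +- half spacing)."""
        sp = np.asarray(self.spacing)
        lo = np.asarray(self.origin) - 0.5 * sp
        hi = np.asarray(self.origin) + (np.asarray(self.shape) - 0.5) * sp
        return lo, hi

    def world_coordinates(self) -> np.ndarray:
        """Physical (mm) coordinates of all voxel centers, shape (3, X, Y, Z)."""
        axes = [
            self.origin[d] + self.spacing[d] * np.arange(self.shape[d])
            for d in range(3)
        ]
        return np.stack(np.meshgrid(*axes, indexing="ij"), axis=0)

    def world_to_index(self, coords: np.ndarray) -> np.ndarray:
        """Convert physical mm coordinates (3, ...) to fractional voxel indices."""
        sp = np.asarray(self.spacing).reshape((3,) + (1,) * (coords.ndim - 1))
        og = np.asarray(self.origin).reshape((3,) + (1,) * (coords.ndim - 1))
        return (coords - og) / sp


def _check_finite(data: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{what} contains non-finite voxels")


@dataclass
class Volume:
    """Scalar 3D image on a :class:`Grid` with a modality tag."""

    grid: Grid
    data: np.ndarray
    modality: Literal["CT", "MR"] = "CT"
    phase: int | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.shape != self.grid.shape:
            raise ValueError(
                f"data shape {self.data.shape} != grid shape {self.grid.shape}"
            )
        _check_finite(self.data, "Volume")


@dataclass(frozen=True)
class OrganInfo:
    """Registry entry for one organ label."""

    name: str
    supervised: bool = False
    fully_in_fov: bool = True


@dataclass
class LabelMap:
    """Integer organ segmentation (0 = background) with an organ registry."""

    grid: Grid
    data: np.ndarray
    registry: Mapping[int, OrganInfo] = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            if not np.allclose(self.data, np.round(self.data)):
                raise ValueError("LabelMap data must be integer-valued")
            self.data = self.data.astype(np.int32)
        if self.data.shape != self.grid.shape:
            raise ValueError(
                f"data shape {self.data.shape} != grid shape {self.grid.shape}"
            )
        if self.data.min() < 0:
            raise ValueError("label values must be non-negative")
        present = set(np.unique(self.data)) - {0}
        missing = present - set(self.registry)
        if self.registry and missing:
            raise ValueError(f"labels {sorted(missing)} not in the organ registry")

    @property
    def supervised_ids(self) -> list[int]:
        return [k for k, v in self.registry.items() if v.supervised]

    def organ_mask(self, organ_id: int) -> "BinaryMask":
        return BinaryMask(self.grid, self.data == organ_id)


@dataclass
class BinaryMask:
    """Boolean voxel mask on a :class:`Grid`."""

    grid: Grid
    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.shape != self.grid.shape:
            raise ValueError(
                f"mask shape {self.data.shape} != grid shape {self.grid.shape}"
            )

    @property
    def true_fraction(self) -> float:
        return float(self.data.mean())


# ---------------------------------------------------------------------------
# NIfTI I/O


def _grid_from_affine(affine: np.ndarray, shape: tuple[int, ...]) -> Grid:
    lin = affine[:3, :3]
    diag = np.diag(lin)
    off = lin - np.diag(diag)
    if np.max(np.abs(off)) > 1e-3 * max(np.max(np.abs(diag)), 1e-9):
        raise ValueError(
            "oblique NIfTI affine (rotation/shear) not supported; "
            "resample the input to an axis-aligned grid first"
        )
    if np.any(diag <= 0):
        raise ValueError("NIfTI affine must have positive axis scales")
    return Grid(tuple(shape), tuple(diag), tuple(affine[:3, 3]))


def read_volume(path: str | Path, modality: str = "CT",
                phase: int | None = None) -> Volume:
    """Read a 3D scalar NIfTI file into a :class:`Volume`.

    Grid spacing and origin are taken from the (axis-aligned) affine.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such NIfTI file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3D data, got {data.ndim}D in {path}")
    grid = _grid_from_affine(img.affine, data.shape)
    return Volume(grid, np.asarray(data, dtype=np.float64), modality=modality,
                  phase=phase)


def write_volume(v: Volume | LabelMap | BinaryMask, path: str | Path) -> None:
    """Write a volume / label map / mask as NIfTI-1 with an axis-aligned affine.

    Label maps and masks are stored with integer dtypes so they round-trip
    exactly; scalar volumes are stored as float64.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(v, LabelMap):
        data = v.data.astype(np.int32)
    elif isinstance(v, BinaryMask):
        data = v.data.astype(np.uint8)
    else:
        data = v.data.astype(np.float64)
    img = nib.Nifti1Image(data, v.grid.affine)
    nib.save(img, str(path))


def read_labelmap(path: str | Path,
                  registry: Mapping[int, OrganInfo] | None = None) -> LabelMap:
    """Read an integer NIfTI label map; optionally attach an organ registry."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such NIfTI file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3D data, got {data.ndim}D in {path}")
    grid = _grid_from_affine(img.affine, data.shape)
    return LabelMap(grid, np.round(np.asarray(data)).astype(np.int32),
                    registry=registry or {})


# ---------------------------------------------------------------------------
# Resampling / masks / normalization


def resample_to_grid(v: Volume | LabelMap, target: Grid,
                     interpolation: Interp = "trilinear"):
    """Resample an image onto ``target``, zero-filling uncovered regions.

    Physical positions are preserved through both grids' spacing/origin; this
    implements the resample-and-zero-pad preprocessing that puts the MR onto
    the CT reference grid.  Label maps require nearest-neighbour interpolation.
    """
    is_labels = isinstance(v, LabelMap)
    if is_labels and interpolation != "nearest":
        raise ValueError("label maps must be resampled with nearest interpolation")
    idx = v.grid.world_to_index(target.world_coordinates())
    order = 0 if interpolation == "nearest" else 1
    out = map_coordinates(v.data.astype(np.float64), idx, order=order,
                          mode="grid-constant", cval=0.0)
    if is_labels:
        return LabelMap(target, np.round(out).astype(np.int32),
                        registry=v.registry)
    return Volume(target, out, modality=v.modality, phase=v.phase)


def support_mask(v: Volume | LabelMap, target: Grid) -> BinaryMask:
    """Mask of target voxels whose centers fall inside ``v``'s physical extent."""
    lo, hi = v.grid.extent
    coords = target.world_coordinates()
    eps = 1e-9
    inside = np.ones(target.shape, dtype=bool)
    for d in range(3):
        inside &= (coords[d] >= lo[d] - eps) & (coords[d] <= hi[d] + eps)
    return BinaryMask(target, inside)


def normalize_intensity(v: Volume) -> Volume:
    """Rescale intensities to [0, 1] for loss/network consumption.

    CT: clamp to [-1000, 1000] HU and rescale linearly.  MR (arbitrary units):
    rescale by the 1st-99th intensity percentiles, then clamp.
    """
    d = v.data
    if v.modality == "CT":
        out = (np.clip(d, -1000.0, 1000.0) + 1000.0) / 2000.0
    else:
        lo, hi = np.percentile(d, [1.0, 99.0])
        if hi - lo < 1e-9:
            out = np.zeros_like(d)
        else:
            out = np.clip((d - lo) / (hi - lo), 0.0, 1.0)
    return Volume(v.grid, out, modality=v.modality, phase=v.phase)


def crop_grid_z(grid: Grid, keep_fraction: float, center_z: float | None = None) -> Grid:
    """Sub-grid keeping ``keep_fraction`` of the z extent around ``center_z`` (index)."""
    if not 0.0 < keep_fraction <= 1.0:
        raise ValueError("keep_fraction must be in (0, 1]")
    nz = grid.shape[2]
    keep = max(1, int(round(nz * keep_fraction)))
    cz = (nz - 1) / 2.0 if center_z is None else center_z
    z0 = int(round(cz - keep / 2.0 + 0.5))
    z0 = min(max(z0, 0), nz - keep)
    origin = list(grid.origin)
    origin[2] += z0 * grid.spacing[2]
    return Grid((grid.shape[0], grid.shape[1], keep), grid.spacing, tuple(origin))
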