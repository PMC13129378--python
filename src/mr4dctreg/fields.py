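"""Deformation-field machinery.

Displacements are stored in *voxel units* of their own grid (the networks
operate on fixed low-resolution grids, so voxel units keep scaling-and-
squaring grid-local); they are converted to mm only at NIfTI export.  A
displacement field ``u`` defines the map ``phi(x) = x + u(x)``: warping a
moving image with ``u`` samples it at ``x + u(x)``.

Stationary velocity fields (SVFs) are integrated to displacement fields by
scaling and squaring: the velocity is scaled by ``2**-steps`` and the
resulting small displacement is self-composed ``steps`` times, a standard
approximation of the exponential map that yields near-diffeomorphic warps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import nibabel as nib
import numpy as np
from scipy.ndimage import map_coordinates

from .grids import BinaryMask, Grid, LabelMap, Volume, _grid_from_affine

__all__ = [
    "VelocityField",
    "DisplacementField",
    "JacobianReport",
    "integrate_svf",
    "integrate_svf_euler",
    "warp",
    "compose",
    "upsample_field",
    "jacobian_report",
    "read_field",
    "write_field",
]

Provenance = Literal[
    "integrated", "composed", "rigid", "upsampled", "ground-truth", "euler"
]


def _check_vec(u: np.ndarray, grid: Grid, what: str) -> np.ndarray:
    u = np.asarray(u, dtype=np.float64)
    if u.shape != (3,) + grid.shape:
        raise ValueError(f"{what} must have shape (3,)+grid.shape, got {u.shape}")
    if not np.all(np.isfinite(u)):
        raise ValueError(f"{what} contains non-finite values")
    return u


@dataclass
class VelocityField:
    """Stationary velocity, one 3-vector per voxel, in voxel units."""

    grid: Grid
    u: np.ndarray

    def __post_init__(self):
        self.u = _check_vec(self.u, self.grid, "VelocityField")


@dataclass
class DisplacementField:
    """Dense displacement field (voxel units) defining phi(x) = x + u(x)."""

    grid: Grid
    u: np.ndarray
    provenance: Provenance = "integrated"

    def __post_init__(self):
        self.u = _check_vec(self.u, self.grid, "DisplacementField")

    def magnitude_mm(self) -> np.ndarray:
        sp = np.asarray(self.grid.spacing).reshape(3, 1, 1, 1)
        return np.sqrt(((self.u * sp) ** 2).sum(axis=0))


@dataclass
class JacobianReport:
    """Per-voxel Jacobian determinants with folding / log-Jacobian summaries."""

    det: np.ndarray
    foldings_fraction: float
    std_log_jacobian: float
    foldings_fraction_masked: float | None = None
    std_log_jacobian_masked: float | None = None


_EPS_LOGDET = 1e-6


def _identity_coords(shape: tuple[int, int, int]) -> np.ndarray:
    return np.stack(
        np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape], indexing="ij"),
        axis=0,
    )


def _sample_field(u: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Trilinearly sample each component of ``u`` at ``coords`` (border clamp)."""
    return np.stack(
        [map_coordinates(u[c], coords, order=1, mode="nearest") for c in range(3)],
        axis=0,
    )


def integrate_svf(v: VelocityField, steps: int = 7) -> DisplacementField:
    """Integrate an SVF by scaling and squaring over ``steps`` steps."""
    if steps < 1:
        raise ValueError("steps must be >= 1")
    u = v.u / (2.0 ** steps)
    base = _identity_coords(v.grid.shape)
    for _ in range(steps):
        u = u + _sample_field(u, base + u)
    return DisplacementField(v.grid, u, provenance="integrated")


def integrate_svf_euler(v: VelocityField, steps: int = 256) -> DisplacementField:
    """Forward-Euler flow integration; slow reference for validating
    scaling-and-squaring."""
    dt = 1.0 / steps
    base = _identity_coords(v.grid.shape)
    u = np.zeros_like(v.u)
    for _ in range(steps):
        u = u + dt * _sample_field(v.u, base + u)
    return DisplacementField(v.grid, u, provenance="euler")


def warp(v: Volume | LabelMap | BinaryMask, phi: DisplacementField,
         interpolation: str = "trilinear"):
    """Warp an image by a displacement field (spatial-transformer resampling).

    ``out(x) = in(x + u(x))``; samples outside the input grid return 0 /
    background.  Label maps and masks require nearest-neighbour interpolation.
    """
    if phi.grid.shape != v.grid.shape:
        raise ValueError(
            f"field grid {phi.grid.shape} does not match image grid {v.grid.shape}"
        )
    is_labels = isinstance(v, (LabelMap, BinaryMask))
    if is_labels and interpolation != "nearest":
        raise ValueError("label maps / masks must be warped with nearest interpolation")
    coords = _identity_coords(v.grid.shape) + phi.u
    order = 0 if interpolation == "nearest" else 1
    out = map_coordinates(v.data.astype(np.float64), coords, order=order,
                          mode="grid-constant", cval=0.0)
    if isinstance(v, LabelMap):
        return LabelMap(v.grid, np.round(out).astype(np.int32), registry=v.registry)
    if isinstance(v, BinaryMask):
        return BinaryMask(v.grid, out > 0.5)
    return Volume(v.grid, out, modality=v.modality, phase=v.phase)


def compose(phi_then: DisplacementField, phi_after: DisplacementField
            ) -> DisplacementField:
    """Compose two displacement fields.

    ``phi_then`` is the map applied *first* to the moving image, ``phi_after``
    second; warping once with the composition approximates warping
    sequentially: ``u(x) = u2(x) + u1(x + u2(x))``.
    """
    if phi_then.grid.shape != phi_after.grid.shape:
        raise ValueError("fields must live on the same grid to compose")
    base = _identity_coords(phi_after.grid.shape)
    u1_at = _sample_field(phi_then.u, base + phi_after.u)
    return DisplacementField(phi_after.grid, phi_after.u + u1_at,
                             provenance="composed")


def upsample_field(phi: DisplacementField, target: Grid) -> DisplacementField:
    """Trilinearly interpolate a field onto a finer grid of the same extent.

    Displacements are rescaled to target voxel units so the *physical*
    displacement is preserved (fields are predicted at low resolution and
    upsampled to the native image size before warping contours).
    """
    lo_c, hi_c = phi.grid.extent
    lo_t, hi_t = target.extent
    half = 0.5 * max(phi.grid.spacing)
    if np.max(np.abs(lo_c - lo_t)) > half or np.max(np.abs(hi_c - hi_t)) > half:
        raise ValueError(
            "target grid physical extent differs from the field's by more than "
            "half a coarse voxel"
        )
    idx = phi.grid.world_to_index(target.world_coordinates())
    comps = [map_coordinates(phi.u[c], idx, order=1, mode="nearest")
             for c in range(3)]
    scale = np.asarray(phi.grid.spacing) / np.asarray(target.spacing)
    u = np.stack([comps[c] * scale[c] for c in range(3)], axis=0)
    return DisplacementField(target, u, provenance="upsampled")


def _jacobian_det(u: np.ndarray) -> np.ndarray:
    """Determinant of the Jacobian of phi(x) = x + u(x), central differences
    in the interior and one-sided at the faces."""
    J = np.empty((3, 3) + u.shape[1:], dtype=np.float64)
    for i in range(3):
        for j in range(3):
            J[i, j] = np.gradient(u[i], axis=j)
            if i == j:
                J[i, j] += 1.0
    det = (
        J[0, 0] * (J[1, 1] * J[2, 2] - J[1, 2] * J[2, 1])
        - J[0, 1] * (J[1, 0] * J[2, 2] - J[1, 2] * J[2, 0])
        + J[0, 2] * (J[1, 0] * J[2, 1] - J[1, 1] * J[2, 0])
    )
    return det


def jacobian_report(phi: DisplacementField,
                    mask: BinaryMask | None = None) -> JacobianReport:
    """Folding fraction and log-Jacobian spread of a deformation.

    Foldings counts voxels with det <= 0 (det = 0 is degenerate, so it is
    counted as folded); the log-Jacobian standard deviation is taken over
    voxels with det > 1e-6 where the log is well defined.
    """
    det = _jacobian_det(phi.u)

    def _stats(d: np.ndarray) -> tuple[float, float]:
        folded = float(np.mean(d <= 0.0))
        pos = d[d > _EPS_LOGDET]
        stdlj = float(np.std(np.log(pos))) if pos.size else 0.0
        return folded, stdlj

    fold, stdlj = _stats(det.ravel())
    fold_m = stdlj_m = None
    if mask is not None:
        if mask.grid.shape != phi.grid.shape:
            raise ValueError("mask grid does not match field grid")
        sel = det[mask.data]
        if sel.size:
            fold_m, stdlj_m = _stats(sel)
        else:
            fold_m, stdlj_m = 0.0, 0.0
    return JacobianReport(det, fold, stdlj, fold_m, stdlj_m)


# ---------------------------------------------------------------------------
# Field I/O: 4D NIfTI (last dim = 3, displacement in mm) + JSON sidecar


def write_field(phi: DisplacementField, path: str | Path) -> None:
    """Write a field as 4D NIfTI (last axis = xyz displacement in mm)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sp = np.asarray(phi.grid.spacing).reshape(3, 1, 1, 1)
    mm = np.moveaxis(phi.u * sp, 0, -1)
    nib.save(nib.Nifti1Image(mm.astype(np.float64), phi.grid.affine), str(path))
    sidecar = path.with_suffix("").with_suffix("")  # strip .nii.gz / .nii
    meta = {"provenance": phi.provenance, "units": "mm", "component_order": "xyz"}
    Path(str(sidecar) + ".json").write_text(json.dumps(meta))


def read_field(path: str | Path) -> DisplacementField:
    path = Path(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValueError(f"expected 4D field with last dim 3, got {data.shape}")
    grid = _grid_from_affine(img.affine, data.shape[:3])
    sp = np.asarray(grid.spacing).reshape(3, 1, 1, 1)
    u = np.moveaxis(data.astype(np.float64), -1, 0) / sp
    prov = "integrated"
    sidecar = Path(str(path.with_suffix("").with_suffix("")) + ".json")
    if sidecar.exists():
        prov = json.loads(sidecar.read_text()).get("provenance", prov)
    return DisplacementField(grid, u, provenance=prov)
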