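"""Rigid MR-to-CT pre-registration and overlap-mask construction.

The multi-modal branch starts from a coarse 6-DOF rigid alignment of the
(resampled, zero-padded) MR to the expiration-phase CT.  Parameters are
optimized by a seeded, multi-resolution derivative-free search (Powell) over
a mutual-information objective; the result is returned both as parameters
and as an equivalent dense displacement field so rigid and deformable maps
compose uniformly.  The rigidly transported MR support mask defines the
overlap region within which multi-modal similarity and partial-organ
metrics are computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.ndimage import affine_transform, gaussian_filter

from .fields import DisplacementField, warp
from .grids import BinaryMask, Grid, Volume, normalize_intensity

__all__ = ["RigidParams", "rigid_align", "rigid_to_field", "rotation_matrix"]

_MI_BINS = 64


@dataclass(frozen=True)
class RigidParams:
    """6-DOF rigid transform: translation (mm) and per-axis rotations (rad),
    applied about the volume's physical center."""

    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    converged: bool = True

    def __post_init__(self):
        t = np.asarray(self.translation, dtype=float)
        r = np.asarray(self.rotation, dtype=float)
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(r))):
            raise ValueError("rigid parameters must be finite")
        if np.any(r <= -np.pi) or np.any(r > np.pi):
            raise ValueError("rotations must lie in (-pi, pi]")
        object.__setattr__(self, "translation", tuple(float(x) for x in t))
        object.__setattr__(self, "rotation", tuple(float(x) for x in r))


def rotation_matrix(rotation: tuple[float, float, float]) -> np.ndarray:
    """Rz @ Ry @ Rx for per-axis angles (rx, ry, rz)."""
    rx, ry, rz = rotation
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def _physical_center(grid: Grid) -> np.ndarray:
    return np.asarray(grid.origin) + 0.5 * (np.asarray(grid.shape) - 1) \
        * np.asarray(grid.spacing)


def rigid_to_field(p: RigidParams, grid: Grid) -> DisplacementField:
    """Dense displacement field (voxel units) of T(x) = R(x - c) + c + t."""
    R = rotation_matrix(p.rotation)
    c = _physical_center(grid)
    t = np.asarray(p.translation)
    xw = grid.world_coordinates()  # (3, X, Y, Z) in mm
    flat = xw.reshape(3, -1)
    mapped = R @ (flat - c[:, None]) + c[:, None] + t[:, None]
    u_mm = (mapped - flat).reshape(xw.shape)
    sp = np.asarray(grid.spacing).reshape(3, 1, 1, 1)
    return DisplacementField(grid, u_mm / sp, provenance="rigid")


def transform_array_rigid(data: np.ndarray, grid: Grid, R: np.ndarray,
                          t: np.ndarray, order: int = 1) -> np.ndarray:
    """Resample ``data`` at T(x) = R(x - c) + c + t (physical mm) on its own grid."""
    sp = np.asarray(grid.spacing)
    og = np.asarray(grid.origin)
    c = _physical_center(grid)
    # source index = (R (W i + o - c) + c + t - o) / sp for target index i
    A = (R * sp[None, :]) / sp[:, None]
    b = (R @ (og - c) + c + t - og) / sp
    return affine_transform(data, A, offset=b, order=order,
                            mode="grid-constant", cval=0.0)


def _mi_histogram(a: np.ndarray, b: np.ndarray, bins: int = _MI_BINS) -> float:
    h, _, _ = np.histogram2d(a, b, bins=bins, range=[[0, 1], [0, 1]])
    p = h / max(h.sum(), 1.0)
    pa = p.sum(axis=1, keepdims=True)
    pb = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (pa @ pb)[nz])))


def _downsample(data: np.ndarray, grid: Grid, factor: int) -> tuple[np.ndarray, Grid]:
    if factor == 1:
        return data, grid
    sm = gaussian_filter(data, sigma=factor / 2.0)
    out = sm[::factor, ::factor, ::factor]
    g = Grid(out.shape, tuple(np.asarray(grid.spacing) * factor), grid.origin)
    return out, g


def rigid_align(mr: Volume, ct50: Volume, seed: int = 0,
                support: BinaryMask | None = None,
                max_translation_mm: float = 40.0,
                max_rotation_rad: float = 0.35,
                n_restarts: int = 2,
                ) -> tuple[RigidParams, DisplacementField, BinaryMask]:
    """Rigidly align MR (already resampled onto the CT grid) to CT-50.

    Maximizes histogram MI over 6 DOF with a 3-level multi-resolution Powell
    search started from the identity, plus seeded random restarts at the
    coarsest level.  Returns the parameters, the equivalent dense field on
    the CT grid, and the overlap mask (the MR support transported by the
    recovered rigid map).
    """
    if mr.grid.shape != ct50.grid.shape:
        raise ValueError("MR must be resampled to the CT-50 grid before rigid_align")
    grid = ct50.grid
    mr_n = normalize_intensity(mr).data
    ct_n = normalize_intensity(ct50).data
    sup = support.data if support is not None else np.ones(grid.shape, bool)

    levels = [4, 2, 1]
    pyramids = []
    for f in levels:
        mr_d, g_d = _downsample(mr_n, grid, f)
        ct_d, _ = _downsample(ct_n, grid, f)
        sup_d = sup[::f, ::f, ::f] if f > 1 else sup
        pyramids.append((mr_d, ct_d, sup_d, g_d))

    def neg_mi(x: np.ndarray, level: int) -> float:
        mr_d, ct_d, sup_d, g_d = pyramids[level]
        R = rotation_matrix(tuple(x[3:]))
        moved = transform_array_rigid(mr_d, g_d, R, x[:3], order=1)
        moved_sup = transform_array_rigid(sup_d.astype(float), g_d, R, x[:3],
                                          order=0) > 0.5
        sel = moved_sup
        if sel.sum() < 32:
            return 0.0
        return -_mi_histogram(ct_d[sel], moved[sel])

    rng = np.random.default_rng(seed)
    lb = [-max_translation_mm] * 3 + [-max_rotation_rad] * 3
    ub = [max_translation_mm] * 3 + [max_rotation_rad] * 3
    bounds = list(zip(lb, ub))

    starts = [np.zeros(6)]
    for _ in range(n_restarts):
        pert = np.concatenate([rng.uniform(-8, 8, 3), rng.uniform(-0.08, 0.08, 3)])
        starts.append(pert)

    # coarsest level: pick the best restart
    best_x, best_f = None, np.inf
    for x0 in starts:
        res = optimize.minimize(
            neg_mi, x0, args=(0,), method="Powell", bounds=bounds,
            options={"xtol": 1e-3, "ftol": 1e-5, "maxfev": 600})
        if res.fun < best_f:
            best_x, best_f = res.x, res.fun
    # refine through finer levels
    for level in (1, 2):
        res = optimize.minimize(
            neg_mi, best_x, args=(level,), method="Powell", bounds=bounds,
            options={"xtol": 1e-4, "ftol": 1e-6, "maxfev": 400})
        best_x, best_f = res.x, res.fun

    identity_f = neg_mi(np.zeros(6), 2)
    final_f = neg_mi(best_x, 2)
    converged = final_f <= identity_f + 1e-12
    if not converged:
        best_x = np.zeros(6)

    params = RigidParams(tuple(best_x[:3]), tuple(best_x[3:]), converged=converged)
    fld = rigid_to_field(params, grid)
    omega = warp(BinaryMask(grid, sup), fld, interpolation="nearest")
    return params, fld, omega
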