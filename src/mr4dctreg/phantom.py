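"""Synthetic 4D dual-modality abdominal phantom with known ground truth.

Stands in for a clinical MR + 4D-CT cohort: seeded studies with

* superellipsoid organs at plausible relative positions inside a body
  contour, with HU-like CT contrast and Gaussian texture;
* analytic, diffeomorphic respiratory motion prescribed as a stationary
  velocity field per phase — zero at the 50% (end-expiration) reference
  phase, maximal superior-inferior diaphragm excursion at 0%;
* an MR-like volume with per-organ contrast that genuinely differs from CT
  (a permuted contrast table), a smooth multiplicative bias field, a known
  rigid misalignment, and a reduced z field of view;
* optional 4D-CT binning artifacts (duplicated axial slabs).

Because the motion lives in the same SVF parametrization the networks
predict, every experiment on phantoms is a parameter-recovery experiment
with exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield
from typing import Mapping

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.stats import spearmanr

from .fields import DisplacementField, VelocityField, integrate_svf, warp
from .grids import (PHASES, BinaryMask, Grid, LabelMap, OrganInfo, Volume,
                    crop_grid_z, resample_to_grid, support_mask)
from .propagation import REFERENCE_PHASE, StudyRecord
from .rigid import RigidParams, rotation_matrix, transform_array_rigid

__all__ = ["PhantomConfig", "PhantomStudy", "make_anatomy", "make_motion",
           "make_mr", "make_study", "phase_fraction"]

# (name, center fraction, semi-axes fraction of grid extent, HU, supervised)
# Later entries take precedence where organs overlap.
_ORGAN_TABLE = [
    ("body",      (0.50, 0.50, 0.50), (0.46, 0.42, 0.62), 40.0, False),
    ("lung_R",    (0.32, 0.45, 0.84), (0.13, 0.15, 0.20), -800.0, False),
    ("lung_L",    (0.68, 0.45, 0.84), (0.13, 0.15, 0.20), -780.0, False),
    ("heart",     (0.50, 0.42, 0.82), (0.11, 0.11, 0.14), 45.0, False),
    ("stomach",   (0.68, 0.42, 0.60), (0.10, 0.09, 0.12), 25.0, False),
    ("liver",     (0.35, 0.50, 0.55), (0.26, 0.22, 0.22), 65.0, True),
    ("spleen",    (0.74, 0.58, 0.56), (0.10, 0.09, 0.13), 55.0, True),
    ("kidney_L",  (0.63, 0.66, 0.36), (0.08, 0.08, 0.14), 35.0, True),
    ("kidney_R",  (0.37, 0.66, 0.36), (0.08, 0.08, 0.14), 34.0, True),
    ("vertebrae", (0.50, 0.74, 0.50), (0.07, 0.06, 0.62), 300.0, False),
]

_BACKGROUND_HU = -1000.0


@dataclass(frozen=True)
class PhantomConfig:
    """Study-generation conditions."""

    grid: Grid = Grid((48, 48, 32), (2.0, 2.0, 2.0))
    amplitude_mm: float = 15.0
    phases: tuple[int, ...] = PHASES
    mr_fov_crop: float = 0.75
    mr_misalignment: RigidParams = dfield(
        default_factory=lambda: RigidParams((6.0, -4.0, 8.0), (0.0, 0.0, 0.02)))
    artifact_rate: float = 0.0
    noise_sd: float = 20.0
    seed: int = 0

    def __post_init__(self):
        if self.amplitude_mm < 0:
            raise ValueError("motion amplitude must be >= 0")
        if not 0.0 < self.mr_fov_crop <= 1.0:
            raise ValueError("mr_fov_crop must be in (0, 1]")
        if REFERENCE_PHASE not in self.phases:
            raise ValueError("phases must include the 50% reference phase")


@dataclass
class PhantomStudy:
    """A StudyRecord plus the generating ground truth."""

    record: StudyRecord
    gt_fields: Mapping[int, DisplacementField]
    gt_svfs: Mapping[int, VelocityField]
    true_rigid: RigidParams
    mr_support: BinaryMask
    diaphragm_apex: tuple[int, int, int]
    config: PhantomConfig = None


def phase_fraction(phase: int) -> float:
    """Map a phase label in {0,16,33,50,66,83} to its cycle fraction i/6."""
    if phase not in PHASES:
        raise ValueError(f"unknown phase label {phase}")
    return PHASES.index(phase) / 6.0


def _amplitude_factor(phase: int) -> float:
    """a(phase): 1 at 0% (peak excursion), 0 at the 50% reference phase."""
    f = phase_fraction(phase)
    return (np.cos(2.0 * np.pi * f) + 1.0) / 2.0


def make_anatomy(cfg: PhantomConfig) -> tuple[Volume, LabelMap]:
    """Reference-phase (CT-50) anatomy and its exact label map."""
    rng = np.random.default_rng(cfg.seed)
    grid = cfg.grid
    shape = np.asarray(grid.shape, dtype=float)
    idx = np.stack(np.meshgrid(*[np.arange(s) for s in grid.shape],
                               indexing="ij"), axis=0).astype(float)
    frac = idx / (shape.reshape(3, 1, 1, 1) - 1.0)

    labels = np.zeros(grid.shape, dtype=np.int32)
    hu = np.full(grid.shape, _BACKGROUND_HU)
    registry: dict[int, OrganInfo] = {}
    for oid, (name, center, semi, organ_hu, supervised) in enumerate(
            _ORGAN_TABLE, start=1):
        c = np.asarray(center) + rng.uniform(-0.02, 0.02, 3)
        s = np.asarray(semi) * rng.uniform(0.92, 1.08, 3)
        r2 = sum(((frac[d] - c[d]) / s[d]) ** 2 for d in range(3))
        inside = r2 <= 1.0
        labels[inside] = oid
        hu[inside] = organ_hu
        registry[oid] = OrganInfo(name, supervised=supervised)
    hu += rng.normal(0.0, cfg.noise_sd, grid.shape)
    hu = np.clip(hu, -1000.0, 1000.0)
    for oid, info in registry.items():
        if not np.any(labels == oid):
            raise RuntimeError(f"organ {info.name} vanished during placement")
    ct = Volume(grid, hu, modality="CT", phase=REFERENCE_PHASE)
    return ct, LabelMap(grid, labels, registry=registry)


def _diaphragm_apex(labels: LabelMap) -> tuple[int, int, int]:
    """Topmost liver voxel (ties broken toward the liver center of mass)."""
    liver_id = next(k for k, v in labels.registry.items() if v.name == "liver")
    pts = np.argwhere(labels.data == liver_id)
    ztop = pts[:, 2].max()
    top = pts[pts[:, 2] == ztop]
    com = top.mean(axis=0)
    best = top[np.argmin(((top - com) ** 2).sum(axis=1))]
    return tuple(int(x) for x in best)


def make_motion(cfg: PhantomConfig, phase: int,
                labels: LabelMap | None = None) -> VelocityField:
    """Ground-truth respiratory SVF for one phase (voxel units).

    Superior-inferior velocity ``-a(phase) * A * w(x)`` with w = 1 below the
    diaphragm, a smooth cosine decay to 0 toward the lung apex, and a lateral
    taper toward the grid boundary; plus small seeded lateral components
    (<= 0.2 A).  Band-limited by construction, so the integrated flow is
    near-diffeomorphic.
    """
    if phase not in cfg.phases:
        raise ValueError(f"phase {phase} not in configured phases {cfg.phases}")
    grid = cfg.grid
    a = _amplitude_factor(phase)
    u = np.zeros((3,) + grid.shape)
    if a == 0.0 or cfg.amplitude_mm == 0.0:
        return VelocityField(grid, u)

    nx, ny, nz = grid.shape
    z = np.arange(nz, dtype=float)
    z_a = 0.96 * (nz - 1)
    if labels is not None:
        # diaphragm plane just above the liver dome, so the full excursion
        # is reached at the apex landmark
        z_d = min(_diaphragm_apex(labels)[2] + 1.5, z_a - 3.0)
    else:
        z_d = 0.72 * (nz - 1)
    wz = np.ones(nz)
    ramp = (z > z_d) & (z < z_a)
    wz[ramp] = 0.5 * (1.0 + np.cos(np.pi * (z[ramp] - z_d) / (z_a - z_d)))
    wz[z >= z_a] = 0.0

    def taper(n):
        t = np.ones(n)
        edge = max(2, int(0.15 * n))
        rampv = 0.5 * (1.0 - np.cos(np.pi * np.arange(edge) / edge))
        t[:edge] = rampv
        t[-edge:] = rampv[::-1]
        return t

    w = (taper(nx)[:, None, None] * taper(ny)[None, :, None]
         * wz[None, None, :])
    amp_vox = cfg.amplitude_mm / grid.spacing[2]
    u[2] = -a * amp_vox * w

    rng = np.random.default_rng(cfg.seed * 1009 + 17)
    for d in (0, 1):
        noise = gaussian_filter(rng.normal(size=grid.shape), sigma=6.0)
        peak = np.abs(noise).max()
        if peak > 0:
            lat_vox = 0.2 * cfg.amplitude_mm / grid.spacing[d]
            u[d] = a * lat_vox * (noise / peak) * w
    return VelocityField(grid, u)


def _contrast_table(rng: np.random.Generator, ct_means: np.ndarray) -> np.ndarray:
    """Seeded MR organ intensities with |Spearman rho| <= 0.5 vs the CT table."""
    n = len(ct_means)
    levels = np.linspace(0.15, 0.95, n)
    if n < 3:  # rank correlation is meaningless for fewer than 3 organs
        return levels[rng.permutation(n)]
    for _ in range(200):
        perm = rng.permutation(n)
        mr = levels[perm]
        rho = spearmanr(ct_means, mr).statistic
        if abs(rho) <= 0.5:
            return mr
    raise RuntimeError("could not draw a low-correlation contrast table")


def make_mr(cfg: PhantomConfig, ct50: Volume, labels: LabelMap
            ) -> tuple[Volume, LabelMap, BinaryMask]:
    """MR-like volume with permuted contrast, bias field, misalignment, and
    a cropped z field of view.

    Returns the MR on its own (cropped) grid, the transported MR label map,
    and the MR support mask on the CT grid.
    """
    rng = np.random.default_rng(cfg.seed * 7919 + 29)
    grid = ct50.grid
    organ_ids = sorted(labels.registry)
    ct_means = np.array([ct50.data[labels.data == oid].mean()
                         for oid in organ_ids])
    mr_means = _contrast_table(rng, ct_means)

    mr = np.full(grid.shape, 0.02)
    for oid, m in zip(organ_ids, mr_means):
        mr[labels.data == oid] = m
    bias = gaussian_filter(rng.normal(size=grid.shape), sigma=12.0)
    if np.abs(bias).max() > 0:
        bias = 1.0 + 0.1 * bias / np.abs(bias).max()
    mr = mr * bias + rng.normal(0.0, 0.03, grid.shape)

    # apply the *inverse* misalignment so that warping the result with
    # rigid_to_field(cfg.mr_misalignment) re-aligns it to CT-50
    R = rotation_matrix(cfg.mr_misalignment.rotation)
    t = np.asarray(cfg.mr_misalignment.translation)
    Rinv, tinv = R.T, -R.T @ t
    mr_mis = transform_array_rigid(mr, grid, Rinv, tinv, order=1)
    lab_mis = transform_array_rigid(labels.data.astype(float), grid, Rinv, tinv,
                                    order=0).astype(np.int32)

    # the MR FoV is centered on the liver, as in liver-SBRT acquisitions
    liver_id = next((k for k, v in labels.registry.items()
                     if v.name == "liver"), None)
    center_z = None
    if liver_id is not None:
        liver_z = np.argwhere(lab_mis == liver_id)
        if liver_z.size:
            center_z = float(liver_z[:, 2].mean())
    mr_grid = crop_grid_z(grid, cfg.mr_fov_crop, center_z=center_z)

    mr_vol = resample_to_grid(Volume(grid, mr_mis, modality="MR"), mr_grid)
    mr_vol.modality = "MR"
    full_labels = LabelMap(grid, lab_mis, registry=labels.registry)
    mr_labels = resample_to_grid(full_labels, mr_grid, interpolation="nearest")

    # organs fully inside the MR FoV keep their supervision eligibility
    new_registry = {}
    any_supervised = False
    for oid, info in labels.registry.items():
        n_full = int(np.sum(lab_mis == oid))
        n_crop = int(np.sum(mr_labels.data == oid))
        fully = n_full > 0 and n_crop >= 0.98 * n_full
        new_registry[oid] = OrganInfo(info.name, info.supervised, fully)
        if info.supervised and n_crop > 0:
            any_supervised = True
    if not any_supervised:
        raise ValueError("MR field-of-view crop removed all supervised organs")
    mr_labels.registry = new_registry
    sup = support_mask(mr_vol, grid)
    return mr_vol, mr_labels, sup


def make_study(cfg: PhantomConfig) -> PhantomStudy:
    """Assemble a full phantom study: 6 CT phases, MR, labels, ground truth."""
    ct50, labels50 = make_anatomy(cfg)
    rng = np.random.default_rng(cfg.seed * 524287 + 101)

    ct, labels_ct, gt_fields, gt_svfs = {}, {}, {}, {}
    for p in cfg.phases:
        svf = make_motion(cfg, p, labels50)
        fld = integrate_svf(svf)
        fld.provenance = "ground-truth"
        gt_svfs[p] = svf
        gt_fields[p] = fld
        if p == REFERENCE_PHASE:
            vol = Volume(ct50.grid, ct50.data.copy(), modality="CT", phase=p)
            lab = LabelMap(ct50.grid, labels50.data.copy(),
                           registry=labels50.registry)
        else:
            vol = warp(ct50, fld)
            vol.phase = p
            lab = warp(labels50, fld, interpolation="nearest")
        if cfg.artifact_rate > 0 and p != REFERENCE_PHASE \
                and rng.random() < cfg.artifact_rate:
            nz = vol.grid.shape[2]
            z0 = int(rng.integers(4, nz - 8))
            thick = int(rng.integers(2, 4))
            shift = 2
            vol.data[:, :, z0:z0 + thick] = vol.data[:, :, z0 + shift:
                                                     z0 + shift + thick]
        ct[p] = vol
        labels_ct[p] = lab

    mr, labels_mr, sup = make_mr(cfg, ct50, labels50)
    # propagate the fully-in-FoV flags to the CT-side registries
    for p in labels_ct:
        labels_ct[p].registry = labels_mr.registry
    record = StudyRecord(mr=mr, ct=ct, labels_mr=labels_mr,
                         labels_ct=labels_ct, native_grid=cfg.grid,
                         subject_id=f"phantom{cfg.seed:04d}")
    return PhantomStudy(record=record, gt_fields=gt_fields, gt_svfs=gt_svfs,
                        true_rigid=cfg.mr_misalignment, mr_support=sup,
                        diaphragm_apex=_diaphragm_apex(labels50), config=cfg)
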