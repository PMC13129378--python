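"""Contour propagation: run a registration method on an (MR, 4D-CT) study.

Three methods are supported, mirroring the clinical comparison:

* ``rigid`` — the rigid pre-alignment alone, applied to every phase (the
  clinical baseline; it cannot track respiratory motion);
* ``direct`` — one multi-modal network registers the rigidly pre-aligned MR
  to every CT phase;
* ``pipeline`` — the two-step decomposition: a multi-modal network maps MR
  to the reference expiration phase (CT-50), a mono-modal temporal network
  maps CT-50 to each phase, and the two fields are composed.

Deformable fields are predicted on the network's low-resolution working
grid, upsampled to the native grid, composed with the rigid map, and used
to warp the MR organ labels (nearest-neighbour, so exported contours are
crisp) onto every phase.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .fields import (DisplacementField, compose, integrate_svf, upsample_field,
                     warp, write_field)
from .grids import (PHASES, BinaryMask, Grid, LabelMap, OrganInfo, Volume,
                    normalize_intensity, read_labelmap, read_volume,
                    resample_to_grid, support_mask, write_volume)
from .network import RegistrationNetwork, predict_svf
from .rigid import RigidParams, rigid_align

__all__ = ["StudyRecord", "RegistrationResult", "propagate_rigid",
           "propagate_direct", "propagate_pipeline", "fit_grid",
           "save_study", "load_study", "save_result"]

REFERENCE_PHASE = 50


@dataclass
class StudyRecord:
    """One subject: an MR volume plus all six 4D-CT phase volumes."""

    mr: Volume
    ct: Mapping[int, Volume]
    labels_mr: LabelMap
    labels_ct: Mapping[int, LabelMap] | None = None
    native_grid: Grid | None = None
    subject_id: str = "subject"

    def __post_init__(self):
        missing = [p for p in PHASES if p not in self.ct]
        if missing:
            raise ValueError(f"study is missing CT phases {missing}")
        if self.native_grid is None:
            self.native_grid = self.ct[REFERENCE_PHASE].grid


@dataclass
class RegistrationResult:
    """Propagation output: one field and one warped label map per phase."""

    method: str
    fields: dict[int, DisplacementField]
    warped_labels: dict[int, LabelMap]
    runtime_s: float
    rigid_params: RigidParams | None = None
    omega: BinaryMask | None = None
    metrics: list = field(default_factory=list)


def fit_grid(native: Grid, shape: tuple[int, int, int]) -> Grid:
    """Low-resolution working grid covering the same physical extent."""
    ext = np.asarray(native.shape) * np.asarray(native.spacing)
    spacing = ext / np.asarray(shape)
    origin = np.asarray(native.origin) + 0.5 * (spacing - np.asarray(native.spacing))
    return Grid(tuple(shape), tuple(spacing), tuple(origin))


def _prepare_mr(study: StudyRecord, seed: int):
    """Resample/zero-pad MR to the CT grid, rigid-align, build the overlap mask."""
    native = study.native_grid
    mr_res = resample_to_grid(study.mr, native)
    sup = support_mask(study.mr, native)
    params, rigid_fld, omega = rigid_align(mr_res, study.ct[REFERENCE_PHASE],
                                           seed=seed, support=sup)
    labels_mr = resample_to_grid(study.labels_mr, native, interpolation="nearest")
    return mr_res, labels_mr, params, rigid_fld, omega


def _net_volume(v: Volume, wgrid: Grid) -> Volume:
    return resample_to_grid(normalize_intensity(v), wgrid)


def _deformable_leg(net: RegistrationNetwork, fixed: Volume, moving: Volume,
                    native: Grid) -> DisplacementField:
    """Predict SVF at working resolution, integrate, upsample to native."""
    wgrid = net.cfg.input_grid
    svf = predict_svf(net, _net_volume(fixed, wgrid), _net_volume(moving, wgrid))
    dd = integrate_svf(svf)
    return upsample_field(dd, native)


def _warp_labels(labels: LabelMap, fld: DisplacementField) -> LabelMap:
    return warp(labels, fld, interpolation="nearest")


def propagate_rigid(study: StudyRecord, seed: int = 0) -> RegistrationResult:
    """Clinical baseline: the rigid field alone, identical for every phase."""
    t0 = time.perf_counter()
    _, labels_mr, params, rigid_fld, omega = _prepare_mr(study, seed)
    fields = {p: rigid_fld for p in PHASES}
    warped = {p: _warp_labels(labels_mr, rigid_fld) for p in PHASES}
    return RegistrationResult("rigid", fields, warped,
                              time.perf_counter() - t0, params, omega)


def propagate_direct(study: StudyRecord, net_direct: RegistrationNetwork,
                     seed: int = 0) -> RegistrationResult:
    """Single-network design: MR registered to each CT phase independently."""
    t0 = time.perf_counter()
    native = study.native_grid
    mr_res, labels_mr, params, rigid_fld, omega = _prepare_mr(study, seed)
    mr_rigid = warp(mr_res, rigid_fld)
    fields, warped = {}, {}
    for p in PHASES:
        leg = _deformable_leg(net_direct, study.ct[p], mr_rigid, native)
        fields[p] = compose(rigid_fld, leg)
        warped[p] = _warp_labels(labels_mr, fields[p])
    return RegistrationResult("direct", fields, warped,
                              time.perf_counter() - t0, params, omega)


def propagate_pipeline(study: StudyRecord, net_multi: RegistrationNetwork,
                       net_mono: RegistrationNetwork,
                       seed: int = 0) -> RegistrationResult:
    """Two-step design: MR -> CT-50 (multi-modal), CT-50 -> CT-phase
    (temporal), composed into a single MR -> CT-phase map per phase."""
    t0 = time.perf_counter()
    native = study.native_grid
    ct50 = study.ct[REFERENCE_PHASE]
    mr_res, labels_mr, params, rigid_fld, omega = _prepare_mr(study, seed)
    mr_rigid = warp(mr_res, rigid_fld)
    multi_leg = _deformable_leg(net_multi, ct50, mr_rigid, native)
    phi_mr_ct50 = compose(rigid_fld, multi_leg)
    fields, warped = {}, {}
    for p in PHASES:
        temporal = _deformable_leg(net_mono, study.ct[p], ct50, native)
        fields[p] = compose(phi_mr_ct50, temporal)
        warped[p] = _warp_labels(labels_mr, fields[p])
    return RegistrationResult("pipeline", fields, warped,
                              time.perf_counter() - t0, params, omega)


# ---------------------------------------------------------------------------
# Study / result I/O


def _registry_to_json(registry) -> dict:
    return {str(k): {"name": v.name, "supervised": v.supervised,
                     "fully_in_fov": v.fully_in_fov}
            for k, v in registry.items()}


def _registry_from_json(d) -> dict[int, OrganInfo]:
    return {int(k): OrganInfo(v["name"], v["supervised"], v["fully_in_fov"])
            for k, v in d.items()}


def save_study(study: StudyRecord, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_volume(study.mr, out / "mr.nii.gz")
    write_volume(study.labels_mr, out / "labels_mr.nii.gz")
    for p, v in study.ct.items():
        write_volume(v, out / f"ct_{p:02d}.nii.gz")
    if study.labels_ct:
        for p, lm in study.labels_ct.items():
            write_volume(lm, out / f"labels_ct_{p:02d}.nii.gz")
    manifest = {
        "subject_id": study.subject_id,
        "phases": list(PHASES),
        "registry": _registry_to_json(study.labels_mr.registry),
        "has_ct_labels": bool(study.labels_ct),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_study(in_dir: str | Path) -> StudyRecord:
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    registry = _registry_from_json(manifest["registry"])
    mr = read_volume(src / "mr.nii.gz", modality="MR")
    labels_mr = read_labelmap(src / "labels_mr.nii.gz", registry)
    ct = {p: read_volume(src / f"ct_{p:02d}.nii.gz", modality="CT", phase=p)
          for p in PHASES}
    labels_ct = None
    if manifest.get("has_ct_labels"):
        labels_ct = {p: read_labelmap(src / f"labels_ct_{p:02d}.nii.gz", registry)
                     for p in PHASES}
    return StudyRecord(mr, ct, labels_mr, labels_ct,
                       subject_id=manifest["subject_id"])


def save_result(result: RegistrationResult, out_dir: str | Path) -> None:
    """Write per-phase warped labels + fields (mm) and a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for p in PHASES:
        write_volume(result.warped_labels[p], out / f"labels_{p:02d}.nii.gz")
        write_field(result.fields[p], out / f"field_{p:02d}.nii.gz")
    manifest = {
        "method": result.method,
        "runtime_s": result.runtime_s,
        "phases": list(PHASES),
        "rigid_params": None if result.rigid_params is None else {
            "translation_mm": list(result.rigid_params.translation),
            "rotation_rad": list(result.rigid_params.rotation),
            "converged": result.rigid_params.converged,
        },
    }
    (out / "result.json").write_text(json.dumps(manifest, indent=2))
    if result.omega is not None:
        write_volume(result.omega, out / "omega.nii.gz")
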