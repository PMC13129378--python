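"""Deformation-QA metric suite and statistical comparison machinery.

Per (phase, organ): Dice similarity coefficient and spacing-aware 95th
percentile Hausdorff distance (pooled symmetric surface distances).  Per
phase: mutual information between fixed CT and warped MR, whole-image and
restricted to the MR/CT overlap region; folding percentage and log-Jacobian
spread of the composed field, globally and within the union of organ masks.
Organs only partially inside the overlap region are evaluated within it.

Method comparisons follow the clinical-analysis recipe: endpoints are
reduced to patient-level medians, compared with paired Wilcoxon signed-rank
tests (exact distribution at small n, zeros dropped), and corrected across
the requested set of pairs with Benjamini-Hochberg FDR at q = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import binary_erosion, distance_transform_edt
from statsmodels.stats.multitest import multipletests

from .fields import jacobian_report, warp
from .grids import (BinaryMask, LabelMap, normalize_intensity,
                    resample_to_grid)
from .losses import neg_mutual_information
from .propagation import RegistrationResult, StudyRecord

__all__ = ["MetricRecord", "dice", "hausdorff95", "evaluate_result",
           "records_to_frame", "compare_methods", "binned_improvement",
           "significance_stars"]

FDR_Q = 0.05


@dataclass
class MetricRecord:
    """One row of the evaluation table."""

    subject: str
    phase: int
    method: str
    organ: str  # organ name, or "seen" / "unseen" / "all" aggregates
    dsc: float = np.nan
    h95_mm: float = np.nan
    mi_whole: float = np.nan
    mi_overlap: float = np.nan
    foldings_pct: float = np.nan
    stdlj: float = np.nan
    foldings_mask_pct: float = np.nan
    stdlj_mask: float = np.nan


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """2|A n B| / (|A| + |B|); 1 if both empty, 0 if exactly one is."""
    if a.grid.shape != b.grid.shape:
        raise ValueError("masks must share a grid")
    na, nb = int(a.data.sum()), int(b.data.sum())
    if na == 0 and nb == 0:
        return 1.0
    if na == 0 or nb == 0:
        return 0.0
    inter = int(np.logical_and(a.data, b.data).sum())
    return 2.0 * inter / (na + nb)


def _surface(mask: np.ndarray) -> np.ndarray:
    return mask & ~binary_erosion(mask)


def hausdorff95(a: BinaryMask, b: BinaryMask) -> float:
    """Spacing-aware 95th percentile of the pooled symmetric surface
    distances, in mm.  Undefined (NaN) when either mask is empty."""
    if a.grid.shape != b.grid.shape:
        raise ValueError("masks must share a grid")
    if not (a.data.any() and b.data.any()):
        return float("nan")
    spacing = a.grid.spacing
    sa, sb = _surface(a.data), _surface(b.data)
    dt_b = distance_transform_edt(~sb, sampling=spacing)
    dt_a = distance_transform_edt(~sa, sampling=spacing)
    pooled = np.concatenate([dt_b[sa], dt_a[sb]])
    return float(np.percentile(pooled, 95))


def _restrict(mask: BinaryMask, omega: BinaryMask | None) -> BinaryMask:
    if omega is None:
        return mask
    return BinaryMask(mask.grid, mask.data & omega.data)


def evaluate_result(result: RegistrationResult,
                    truth: Mapping[int, LabelMap],
                    omega: BinaryMask | None = None,
                    study: StudyRecord | None = None,
                    subject: str | None = None) -> list[MetricRecord]:
    """Score a propagation result against reference phase labels.

    One record per (phase, organ) plus "seen"/"unseen"/"all" aggregates per
    phase; aggregate rows also carry the per-phase field-regularity and MI
    metrics.  Organs not fully inside the MR field of view are compared only
    within the overlap mask.
    """
    omega = omega if omega is not None else result.omega
    records: list[MetricRecord] = []
    if study is not None:
        mr_native = resample_to_grid(normalize_intensity(study.mr),
                                     study.native_grid)
        ct_native = {p: normalize_intensity(study.ct[p]) for p in study.ct}

    for phase, pred in sorted(result.warped_labels.items()):
        if phase not in truth:
            import warnings
            warnings.warn(f"no reference labels for phase {phase}; skipped")
            continue
        ref = truth[phase]
        registry = ref.registry or pred.registry
        fld = result.fields[phase]

        organ_union = np.zeros(ref.grid.shape, dtype=bool)
        per_organ: dict[int, MetricRecord] = {}
        for oid, info in registry.items():
            ref_m = ref.organ_mask(oid)
            pred_m = pred.organ_mask(oid)
            organ_union |= ref_m.data
            if not info.fully_in_fov:
                ref_m = _restrict(ref_m, omega)
                pred_m = _restrict(pred_m, omega)
            rec = MetricRecord(
                subject or getattr(study, "subject_id", "subject"),
                phase, result.method, info.name,
                dsc=dice(pred_m, ref_m),
                h95_mm=hausdorff95(pred_m, ref_m))
            per_organ[oid] = rec
            records.append(rec)

        jac = jacobian_report(fld, BinaryMask(ref.grid, organ_union))
        mi_whole = mi_overlap = np.nan
        if study is not None:
            wm = warp(mr_native, fld)
            mi_whole = neg_mutual_information(ct_native[phase], wm)
            if omega is not None and omega.data.any():
                mi_overlap = neg_mutual_information(ct_native[phase], wm,
                                                    mask=omega)
        for agg in ("seen", "unseen", "all"):
            if agg == "seen":
                sel = [r for oid, r in per_organ.items()
                       if registry[oid].supervised]
            elif agg == "unseen":
                sel = [r for oid, r in per_organ.items()
                       if not registry[oid].supervised]
            else:
                sel = list(per_organ.values())
            if not sel:
                continue
            records.append(MetricRecord(
                sel[0].subject, phase, result.method, agg,
                dsc=float(np.mean([r.dsc for r in sel])),
                h95_mm=float(np.nanmean([r.h95_mm for r in sel])),
                mi_whole=mi_whole, mi_overlap=mi_overlap,
                foldings_pct=100.0 * jac.foldings_fraction,
                stdlj=jac.std_log_jacobian,
                foldings_mask_pct=100.0 * (jac.foldings_fraction_masked or 0.0),
                stdlj_mask=jac.std_log_jacobian_masked or 0.0))
    return records


def records_to_frame(records: Sequence[MetricRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])


def significance_stars(p: float) -> str:
    if p <= 1e-4:
        return "****"
    if p <= 1e-3:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def _paired_wilcoxon(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided paired Wilcoxon signed-rank p, zeros dropped, exact
    distribution at small n."""
    d = np.asarray(x) - np.asarray(y)
    d = d[d != 0.0]
    if d.size == 0:
        return 1.0
    has_ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= 25 and not has_ties) else "approx"
    return float(stats.wilcoxon(d, zero_method="wilcox", method=method).pvalue)


def compare_methods(records: Sequence[MetricRecord] | pd.DataFrame,
                    endpoint: str,
                    method_pairs: Sequence[tuple[str, str]],
                    q: float = FDR_Q) -> pd.DataFrame:
    """Paired Wilcoxon tests on patient-level medians, BH-FDR corrected.

    Each subject's endpoint values (across phases and organs) are reduced to
    their median before testing; adjusted p-values and significance stars are
    reported per requested method pair.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if len(set(df["method"])) < 2:
        raise ValueError("need at least two methods to compare")
    sub = df[df[endpoint].notna()]
    med = sub.groupby(["method", "subject"])[endpoint].median()

    rows = []
    for a, b in method_pairs:
        if a not in med.index.get_level_values(0) or \
                b not in med.index.get_level_values(0):
            raise ValueError(f"method pair ({a}, {b}) not present in records")
        xa, xb = med[a], med[b]
        common = xa.index.intersection(xb.index)
        p = _paired_wilcoxon(xa[common].to_numpy(), xb[common].to_numpy())
        rows.append({"method_a": a, "method_b": b, "endpoint": endpoint,
                     "n_subjects": len(common), "p_raw": p})
    rep = pd.DataFrame(rows)
    rejected, p_adj, _, _ = multipletests(rep["p_raw"], alpha=q,
                                          method="fdr_bh")
    rep["p_adj"] = p_adj
    rep["significant"] = rejected
    rep["stars"] = [significance_stars(p) for p in rep["p_adj"]]
    return rep


def binned_improvement(records: Sequence[MetricRecord] | pd.DataFrame,
                       rigid_records: Sequence[MetricRecord] | pd.DataFrame,
                       bin_width: float = 0.1) -> pd.DataFrame:
    """Post-registration Dice (and overlap MI) stratified by the quality of
    the initial rigid alignment, grouped into rigid-Dice bins."""
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    rg = rigid_records if isinstance(rigid_records, pd.DataFrame) \
        else records_to_frame(rigid_records)
    aggregates = {"seen", "unseen", "all"}
    df = df[~df["organ"].isin(aggregates) & df["dsc"].notna()]
    rg = rg[~rg["organ"].isin(aggregates) & rg["dsc"].notna()]
    key = ["subject", "phase", "organ"]
    merged = df.merge(rg[key + ["dsc"]], on=key, suffixes=("", "_rigid"))
    edges = np.arange(0.0, 1.0 + bin_width, bin_width)
    merged["bin"] = pd.cut(merged["dsc_rigid"], edges, include_lowest=True)
    out = (merged.groupby(["method", "bin"], observed=True)
           .agg(n=("dsc", "size"), mean_dice=("dsc", "mean"),
                mean_rigid_dice=("dsc_rigid", "mean"))
           .reset_index())
    return out[out["n"] > 0]
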