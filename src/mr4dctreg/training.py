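"""Weakly supervised training objectives and loops.

Three model kinds share one machinery:

* ``temporal`` — mono-modal CT-50 -> CT-phase registration: LNCC similarity,
  a Jacobian-determinant penalty (large motion allowed, foldings and extreme
  volume change discouraged) and Dice supervision; default weights
  lambda = 0.3, gamma = 0.7.
* ``multimodal`` — MR -> CT-50 after rigid pre-alignment: negative mutual
  information restricted to the overlap region, first-order smoothness
  (only small plausible warps are wanted here) and Dice supervision;
  default weights lambda = 0.5, gamma = 0.5.
* ``direct`` — the multimodal objective applied to (MR, CT-phase) pairs for
  every phase: mutual information is the only similarity valid across
  modalities at all phases.

Dice supervision warps the *moving organ probabilities with the field
predicted from the images* (one field per pair), uses trilinear soft
warping for differentiability, and is restricted to supervised organs fully
contained in the MR field of view.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .autodiff import Tensor, channel, grid_sample
from .fields import warp
from .grids import (PHASES, BinaryMask, Grid, LabelMap, Volume,
                    normalize_intensity, resample_to_grid, support_mask)
from .losses import (LossWeights, detjac_penalty_t, gradient_l2_t, lncc_t,
                     neg_mutual_information_t, one_hot, soft_dice_t)
from .network import Adam, NetworkConfig, RegistrationNetwork, build_network
from .propagation import REFERENCE_PHASE, StudyRecord
from .rigid import rigid_align

__all__ = ["TrainConfig", "PairSampler", "SubjectData", "prepare_subject",
           "temporal_objective", "multimodal_objective", "train",
           "qc_filter", "patient_split", "k_fold",
           "DEFAULT_WEIGHTS"]

ModelKind = Literal["temporal", "multimodal", "direct"]

#: Final-training loss weights (lambda, gamma) per model kind.
DEFAULT_WEIGHTS: dict[str, LossWeights] = {
    "temporal": LossWeights(0.3, 0.7),
    "multimodal": LossWeights(0.5, 0.5),
    "direct": LossWeights(0.5, 0.5),
}

_PAIRING_FOR_KIND = {
    "temporal": "ct50-to-phase",
    "multimodal": "mr-to-ct50",
    "direct": "mr-to-any-phase",
}


@dataclass
class TrainConfig:
    model_kind: ModelKind
    working_grid: Grid
    weights: LossWeights | None = None
    iterations: int = 300
    batch_size: int = 1
    learning_rate: float = 1e-3
    seed: int = 0
    levels: int = 3
    base_channels: int = 8
    attention_gates: bool = True
    integration_steps: int = 7
    lncc_window: int = 9
    mi_bins: int = 32
    val_every: int = 25

    def __post_init__(self):
        if self.weights is None:
            self.weights = DEFAULT_WEIGHTS[self.model_kind]
        if self.iterations < 1 or self.batch_size < 1:
            raise ValueError("iterations and batch_size must be >= 1")

    def to_yaml(self, path) -> None:
        import yaml
        d = {k: getattr(self, k) for k in (
            "model_kind", "iterations", "batch_size", "learning_rate",
            "seed", "levels", "base_channels", "attention_gates",
            "integration_steps", "lncc_window", "mi_bins", "val_every")}
        d["lam"], d["gamma"] = self.weights.lam, self.weights.gamma
        d["grid"] = {"shape": list(self.working_grid.shape),
                     "spacing": list(self.working_grid.spacing),
                     "origin": list(self.working_grid.origin)}
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        import yaml
        d = yaml.safe_load(Path(path).read_text())
        g = d.pop("grid")
        grid = Grid(tuple(g["shape"]), tuple(g["spacing"]), tuple(g["origin"]))
        weights = LossWeights(d.pop("lam"), d.pop("gamma"))
        return cls(model_kind=d.pop("model_kind"), working_grid=grid,
                   weights=weights, **d)


@dataclass
class SubjectData:
    """One subject prepared at working resolution: normalized images,
    soft organ-probability channels, and the MR overlap mask."""

    subject_id: str
    ct: dict[int, np.ndarray]
    ct_probs: dict[int, np.ndarray]
    mr: np.ndarray | None = None
    mr_probs: np.ndarray | None = None
    omega: np.ndarray | None = None
    supervised_ids: tuple[int, ...] = ()


def _soft_probs(labels: LabelMap, organ_ids: Sequence[int],
                wgrid: Grid) -> np.ndarray:
    """One-hot organ channels resampled (trilinearly, hence soft) to wgrid."""
    chans = []
    for oid in organ_ids:
        v = Volume(labels.grid, (labels.data == oid).astype(np.float64))
        chans.append(resample_to_grid(v, wgrid).data)
    return np.stack(chans, axis=0)


def prepare_subject(study: StudyRecord, wgrid: Grid, seed: int = 0,
                    with_mr: bool = True) -> SubjectData:
    """Resample a study to the working grid; rigid-align the MR branch.

    The MR is resampled/zero-padded to the CT grid, rigidly aligned to
    CT-50, warped by the recovered rigid map, and only then brought to the
    working grid, so training sees the same preprocessing as inference.
    """
    native = study.native_grid
    if study.labels_ct is None:
        raise ValueError("training requires CT-phase label maps")
    reg = study.labels_mr.registry
    supervised = tuple(k for k, v in reg.items()
                       if v.supervised and v.fully_in_fov)
    if not supervised:
        raise ValueError("no supervised organs fully inside the field of view")

    ct, ct_probs = {}, {}
    for p, vol in study.ct.items():
        ct[p] = resample_to_grid(normalize_intensity(vol), wgrid).data
        ct_probs[p] = _soft_probs(study.labels_ct[p], supervised, wgrid)

    data = SubjectData(study.subject_id, ct, ct_probs,
                       supervised_ids=supervised)
    if with_mr:
        mr_res = resample_to_grid(study.mr, native)
        sup = support_mask(study.mr, native)
        _, rigid_fld, omega = rigid_align(mr_res, study.ct[REFERENCE_PHASE],
                                          seed=seed, support=sup)
        mr_rigid = warp(normalize_intensity(mr_res), rigid_fld)
        labels_mr = resample_to_grid(study.labels_mr, native,
                                     interpolation="nearest")
        labels_mr_rigid = warp(labels_mr, rigid_fld, interpolation="nearest")
        data.mr = resample_to_grid(mr_rigid, wgrid).data
        data.mr_probs = _soft_probs(labels_mr_rigid, supervised, wgrid)
        om = resample_to_grid(Volume(native, omega.data.astype(np.float64)),
                              wgrid, interpolation="nearest").data > 0.5
        data.omega = om
    return data


@dataclass
class PairSampler:
    """Seeded sampler of training pairs at the working resolution."""

    subjects: list[SubjectData]
    pairing: Literal["ct50-to-phase", "mr-to-ct50", "mr-to-any-phase"]
    seed: int = 0

    def __post_init__(self):
        if not self.subjects:
            raise ValueError("sampler needs at least one subject")
        self._rng = np.random.default_rng(self.seed)
        self._pairs = self.all_pairs()

    def all_pairs(self) -> list[tuple]:
        pairs = []
        for s in self.subjects:
            if self.pairing == "ct50-to-phase":
                for p in PHASES:
                    if p != REFERENCE_PHASE:
                        pairs.append((s, p))
            elif self.pairing == "mr-to-ct50":
                pairs.append((s, REFERENCE_PHASE))
            else:
                for p in PHASES:
                    pairs.append((s, p))
        return pairs

    def reset(self) -> None:
        """Re-seed the draw sequence (called at the start of every
        training run so repeated runs are reproducible)."""
        self._rng = np.random.default_rng(self.seed)

    def draw(self) -> tuple[SubjectData, int]:
        return self._pairs[self._rng.integers(len(self._pairs))]


# ---------------------------------------------------------------------------
# Objective graphs


def _integrate_t(svf: Tensor, steps: int) -> Tensor:
    u = svf * (2.0 ** -steps)
    for _ in range(steps):
        u = u + grid_sample(u, u, mode="border")
    return u


def _pair_loss(kind: str, fixed: np.ndarray, moving: np.ndarray,
               fixed_probs: np.ndarray, moving_probs: np.ndarray,
               mask: np.ndarray | None, net: RegistrationNetwork,
               w: LossWeights, cfg: TrainConfig) -> tuple[Tensor, dict]:
    """Build the loss graph for one pair; returns (loss tensor, term values)."""
    x = Tensor(np.stack([fixed, moving], axis=0))
    svf = net.forward(x)
    u = _integrate_t(svf, cfg.integration_steps)
    comps = [channel(u, c) for c in range(3)]

    mov_t = Tensor(moving[None])
    warped = channel(grid_sample(mov_t, u, mode="zero"), 0)
    warped_probs = grid_sample(Tensor(moving_probs), u, mode="zero")
    dice = soft_dice_t(Tensor(fixed_probs), warped_probs)

    if kind == "temporal":
        sim = lncc_t(Tensor(fixed), warped, window=cfg.lncc_window)
        reg = detjac_penalty_t(comps)
    else:
        sim = neg_mutual_information_t(Tensor(fixed), warped,
                                       bins=cfg.mi_bins, mask=mask)
        reg = gradient_l2_t(comps)
    loss = sim + w.lam * reg + w.gamma * dice
    terms = {"similarity": sim.item(), "regularization": reg.item(),
             "dice_loss": dice.item(), "total": loss.item()}
    return loss, terms


def _labels_to_probs(labels: LabelMap, organ_ids: Sequence[int]) -> np.ndarray:
    return one_hot(labels, list(organ_ids))


def temporal_objective(ct_phi: Volume, ct50: Volume, labels50: LabelMap,
                       labels_phi: LabelMap, net: RegistrationNetwork,
                       w: LossWeights | None = None,
                       cfg: TrainConfig | None = None) -> tuple[float, dict]:
    """Mono-modal objective value for one (CT-50, CT-phase) pair.

    loss = LNCC(CT-phi, CT-50 o Phi) + lambda * DetJac(Phi)
         + gamma * Dice(S_phi, S_50 o Phi),  Phi = exp(SVF(net)).
    """
    w = w or DEFAULT_WEIGHTS["temporal"]
    cfg = cfg or TrainConfig("temporal", net.cfg.input_grid)
    ids = [k for k, v in labels50.registry.items() if v.supervised]
    loss, terms = _pair_loss(
        "temporal", ct_phi.data, ct50.data,
        _labels_to_probs(labels_phi, ids), _labels_to_probs(labels50, ids),
        None, net, w, cfg)
    return loss.item(), terms


def multimodal_objective(ct50: Volume, mr: Volume, labels50: LabelMap,
                         labels_mr: LabelMap, omega: BinaryMask,
                         net: RegistrationNetwork,
                         w: LossWeights | None = None,
                         cfg: TrainConfig | None = None) -> tuple[float, dict]:
    """Multi-modal objective for one rigidly pre-aligned (MR, CT-50) pair.

    loss = -MI(CT-50, MR o Phi; within Omega) + lambda * ||grad Phi||^2
         + gamma * Dice(S_50, S_MR o Phi).
    """
    if not np.any(omega.data):
        raise ValueError("empty overlap mask")
    w = w or DEFAULT_WEIGHTS["multimodal"]
    cfg = cfg or TrainConfig("multimodal", net.cfg.input_grid)
    ids = [k for k, v in labels50.registry.items()
           if v.supervised and v.fully_in_fov]
    loss, terms = _pair_loss(
        "multimodal", ct50.data, mr.data,
        _labels_to_probs(labels50, ids), _labels_to_probs(labels_mr, ids),
        omega.data, net, w, cfg)
    return loss.item(), terms


def _draw_pair(kind: str, sampler: PairSampler):
    s, p = sampler.draw()
    if kind == "temporal":
        return (s.ct[p], s.ct[REFERENCE_PHASE], s.ct_probs[p],
                s.ct_probs[REFERENCE_PHASE], None)
    return (s.ct[p], s.mr, s.ct_probs[p], s.mr_probs, s.omega)


def _val_loss(kind: str, pairs, net, w, cfg) -> float:
    net.set_requires_grad(False)
    total = 0.0
    for s, p in pairs:
        if kind == "temporal":
            args = (s.ct[p], s.ct[REFERENCE_PHASE], s.ct_probs[p],
                    s.ct_probs[REFERENCE_PHASE], None)
        else:
            args = (s.ct[p], s.mr, s.ct_probs[p], s.mr_probs, s.omega)
        loss, _ = _pair_loss(kind, *args, net, w, cfg)
        total += loss.item()
    net.set_requires_grad(True)
    return total / len(pairs)


def train(model_kind: ModelKind, sampler: PairSampler, cfg: TrainConfig,
          val_sampler: PairSampler | None = None
          ) -> tuple[RegistrationNetwork, pd.DataFrame]:
    """Seeded training loop; retains the parameters with the best
    validation loss (training pairs are used for validation when no
    validation sampler is given)."""
    if sampler.pairing != _PAIRING_FOR_KIND[model_kind]:
        raise ValueError(
            f"model kind {model_kind!r} expects pairing "
            f"{_PAIRING_FOR_KIND[model_kind]!r}, got {sampler.pairing!r}")
    net = build_network(NetworkConfig(
        input_grid=cfg.working_grid, levels=cfg.levels,
        base_channels=cfg.base_channels, attention_gates=cfg.attention_gates,
        seed=cfg.seed))
    opt = Adam(net.params(), lr=cfg.learning_rate)
    w = cfg.weights
    sampler.reset()
    val_pairs = (val_sampler or sampler).all_pairs()

    best_val = _val_loss(model_kind, val_pairs, net, w, cfg)
    best_params = [p.data.copy() for p in net.params()]
    rows = [{"iteration": 0, "val_loss": best_val}]

    for it in range(1, cfg.iterations + 1):
        opt.zero_grad()
        terms_acc = None
        for _ in range(cfg.batch_size):
            args = _draw_pair(model_kind, sampler)
            loss, terms = _pair_loss(model_kind, *args, net, w, cfg)
            (loss * (1.0 / cfg.batch_size)).backward()
            terms_acc = terms if terms_acc is None else {
                k: terms_acc[k] + v for k, v in terms.items()}
        opt.step()
        row = {"iteration": it,
               **{k: v / cfg.batch_size for k, v in terms_acc.items()}}
        if it % cfg.val_every == 0 or it == cfg.iterations:
            val = _val_loss(model_kind, val_pairs, net, w, cfg)
            row["val_loss"] = val
            if val < best_val:
                best_val = val
                best_params = [p.data.copy() for p in net.params()]
        rows.append(row)

    for p, saved in zip(net.params(), best_params):
        p.data = saved
    log = pd.DataFrame(rows)
    log.attrs["best_val_loss"] = best_val
    return net, log


# ---------------------------------------------------------------------------
# QC filter and patient-level splitting


def qc_filter(candidate_labels: list[LabelMap], reference_labels: list[LabelMap],
              threshold: float = 0.5) -> tuple[list[LabelMap], list[dict]]:
    """Keep candidates whose mean per-organ Dice vs the reference reaches
    ``threshold``; report the rejected ones.  Used to drop failed automatic
    segmentations before they bias training or evaluation."""
    if len(candidate_labels) != len(reference_labels):
        raise ValueError("candidate and reference lists must be paired")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    from .evaluation import dice as dice_fn

    kept, report = [], []
    for i, (cand, ref) in enumerate(zip(candidate_labels, reference_labels)):
        if cand.grid.shape != ref.grid.shape:
            raise ValueError(f"pair {i}: grids do not match")
        ids = sorted(set(np.unique(ref.data)) - {0})
        scores = [dice_fn(cand.organ_mask(i_), ref.organ_mask(i_)) for i_ in ids]
        mean_d = float(np.mean(scores)) if scores else 0.0
        if mean_d >= threshold:
            kept.append(cand)
        else:
            report.append({"index": i, "mean_dice": mean_d})
    return kept, report


def patient_split(subject_ids: Sequence, fractions: tuple[float, float, float],
                  seed: int = 0) -> tuple[list, list, list]:
    """Seeded patient-level split into train/val/test by fractions."""
    if abs(sum(fractions) - 1.0) > 1e-6:
        raise ValueError("fractions must sum to 1")
    ids = list(subject_ids)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_train = int(round(fractions[0] * len(ids)))
    n_val = int(round(fractions[1] * len(ids)))
    n_val = min(n_val, len(ids) - n_train)
    tr = [ids[i] for i in perm[:n_train]]
    va = [ids[i] for i in perm[n_train:n_train + n_val]]
    te = [ids[i] for i in perm[n_train + n_val:]]
    return tr, va, te


def save_split(train_ids: Sequence, val_ids: Sequence, test_ids: Sequence,
               path) -> None:
    """Write a patient-level split manifest as JSON."""
    import json
    Path(path).write_text(json.dumps(
        {"train": list(train_ids), "val": list(val_ids),
         "test": list(test_ids)}, indent=2))


def k_fold(subject_ids: Sequence, k: int, seed: int = 0) -> list[list]:
    """Seeded k-fold patient-level partition (disjoint, exhaustive)."""
    ids = list(subject_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(ids) < k:
        raise ValueError("fewer subjects than folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    return [[ids[i] for i in chunk] for chunk in np.array_split(perm, k)]
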