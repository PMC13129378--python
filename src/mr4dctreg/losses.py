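"""Differentiable training losses.

The building blocks of the weakly supervised registration objectives:

* ``lncc`` — squared local normalized cross-correlation (mono-modal
  similarity, robust to local affine intensity changes);
* ``neg_mutual_information`` — Parzen-window mutual information (multi-modal
  similarity, optionally restricted to the MR/CT overlap region);
* ``soft_dice_loss`` — weak contour supervision on warped organ
  probabilities;
* ``detjac_penalty`` — mean squared deviation of the Jacobian determinant
  from 1 (discourages foldings and extreme volume change without penalizing
  large plausible motion);
* ``gradient_l2_penalty`` — first-order smoothness on displacement
  magnitudes (keeps the multi-modal warp small and plausible).

Each loss exists in two layers: a tensor-level function (suffix ``_t``) used
inside the training graph, and a thin array-facing wrapper operating on
:class:`~mr4dctreg.grids.Volume` / fields that returns a float.  All losses
reduce by the mean so the weight coefficients are resolution-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, box_sum, linear_op
from .fields import DisplacementField
from .grids import BinaryMask, LabelMap, Volume

__all__ = [
    "LossWeights",
    "lncc",
    "neg_mutual_information",
    "soft_dice_loss",
    "detjac_penalty",
    "gradient_l2_penalty",
    "one_hot",
    "lncc_t",
    "neg_mutual_information_t",
    "soft_dice_t",
    "detjac_penalty_t",
    "gradient_l2_t",
]

_EPS_LNCC = 1e-5
_EPS_DICE = 1e-5
_EPS_LOG = 1e-12


@dataclass(frozen=True)
class LossWeights:
    """Weights of the regularization (lambda) and Dice (gamma) terms."""

    lam: float
    gamma: float

    def __post_init__(self):
        if not (np.isfinite(self.lam) and np.isfinite(self.gamma)):
            raise ValueError("loss weights must be finite")
        if self.lam < 0 or self.gamma < 0:
            raise ValueError("loss weights must be >= 0")


# ---------------------------------------------------------------------------
# LNCC


def lncc_t(fixed: Tensor, moving: Tensor, window: int = 9,
           mask: np.ndarray | None = None) -> Tensor:
    """1 - mean squared windowed NCC; 0 at perfect (affine) intensity match.

    Window statistics are normalized by the per-voxel in-window count, so
    boundary windows use correct partial-window statistics.  Variances are
    clamped from below by ``1e-5`` which stabilizes constant patches.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    ones = Tensor(np.ones_like(fixed.data))
    n = box_sum(ones, window)
    sf = box_sum(fixed, window)
    sm = box_sum(moving, window)
    sff = box_sum(fixed * fixed, window)
    smm = box_sum(moving * moving, window)
    sfm = box_sum(fixed * moving, window)
    mu_f = sf / n
    mu_m = sm / n
    var_f = (sff / n - mu_f * mu_f).clamp_min(_EPS_LNCC)
    var_m = (smm / n - mu_m * mu_m).clamp_min(_EPS_LNCC)
    cov = sfm / n - mu_f * mu_m
    cc2 = (cov * cov) / (var_f * var_m)
    if mask is not None:
        m = mask.astype(np.float64)
        if m.sum() == 0:
            raise ValueError("empty mask in lncc")
        mean_cc2 = (cc2 * Tensor(m)).sum() / float(m.sum())
    else:
        mean_cc2 = cc2.mean()
    return 1.0 - mean_cc2


def lncc(fixed: Volume, moving_warped: Volume, window: int = 9,
         mask: BinaryMask | None = None) -> float:
    """Squared-LNCC loss between two volumes on the same grid (lower is better)."""
    if fixed.grid.shape != moving_warped.grid.shape:
        raise ValueError("volumes must share a grid")
    m = mask.data if mask is not None else None
    return lncc_t(Tensor(fixed.data), Tensor(moving_warped.data), window, m).item()


# ---------------------------------------------------------------------------
# Mutual information (Parzen window)


def _parzen_weights(img: Tensor, bins: int) -> Tensor:
    """Per-voxel normalized Gaussian bin weights, shape (N, bins).

    Kernels are centered on the bin centers with width (sigma) equal to one
    bin; weights are normalized per voxel so each voxel contributes one unit
    of mass to the histogram.
    """
    centers = (np.arange(bins) + 0.5) / bins
    sigma = 1.0 / bins
    flat = img.reshape(-1, 1)
    z = (flat - Tensor(centers.reshape(1, -1))) * (1.0 / sigma)
    w = (z * z * (-0.5)).exp()
    return w / w.sum(axis=1, keepdims=True)


def neg_mutual_information_t(fixed: Tensor, moving: Tensor, bins: int = 32,
                             mask: np.ndarray | None = None) -> Tensor:
    """Negative mutual information (nats) from a differentiable joint histogram."""
    if mask is not None:
        m = mask.astype(np.float64).reshape(-1, 1)
        count = float(m.sum())
        if count == 0:
            raise ValueError("empty mask in mutual information")
    else:
        m = None
        count = float(fixed.data.size)
    wf = _parzen_weights(fixed, bins)
    wm = _parzen_weights(moving, bins)
    if m is not None:
        wf = wf * Tensor(m)
    joint = wf.transpose(1, 0) @ wm * (1.0 / count)  # (bins, bins)
    pf = joint.sum(axis=1, keepdims=True)
    pm = joint.sum(axis=0, keepdims=True)
    ratio = joint.clamp_min(_EPS_LOG) / (pf.clamp_min(_EPS_LOG) * pm.clamp_min(_EPS_LOG))
    mi = (joint * ratio.log()).sum()
    return -mi


def neg_mutual_information(fixed: Volume, moving_warped: Volume, bins: int = 32,
                           mask: BinaryMask | None = None) -> float:
    """-MI between two volumes with intensities in [0, 1] (lower is better)."""
    if fixed.grid.shape != moving_warped.grid.shape:
        raise ValueError("volumes must share a grid")
    for v in (fixed, moving_warped):
        if v.data.min() < -1e-6 or v.data.max() > 1 + 1e-6:
            raise ValueError("intensities must be normalized to [0, 1] for MI")
    m = mask.data if mask is not None else None
    return neg_mutual_information_t(
        Tensor(fixed.data), Tensor(moving_warped.data), bins, m).item()


# ---------------------------------------------------------------------------
# Soft Dice


def one_hot(labels: LabelMap, organ_ids: list[int]) -> np.ndarray:
    """Stack per-organ indicator channels, shape (len(organ_ids), X, Y, Z)."""
    return np.stack([(labels.data == oid).astype(np.float64)
                     for oid in organ_ids], axis=0)


def soft_dice_t(fixed_probs: Tensor, moving_probs: Tensor) -> Tensor:
    """1 - mean per-channel soft Dice of probability maps (O, X, Y, Z)."""
    o = fixed_probs.data.shape[0]
    p = fixed_probs.reshape(o, -1)
    q = moving_probs.reshape(o, -1)
    inter = (p * q).sum(axis=1)
    dice = (2.0 * inter + _EPS_DICE) / (p.sum(axis=1) + q.sum(axis=1) + _EPS_DICE)
    return 1.0 - dice.mean()


def soft_dice_loss(fixed_probs: np.ndarray, warped_moving_probs: np.ndarray) -> float:
    """Soft Dice loss over organ probability channels; 0 for identical maps."""
    fixed_probs = np.asarray(fixed_probs, dtype=np.float64)
    warped_moving_probs = np.asarray(warped_moving_probs, dtype=np.float64)
    if fixed_probs.shape != warped_moving_probs.shape:
        raise ValueError("probability maps must have identical shapes")
    if fixed_probs.shape[0] == 0:
        raise ValueError("organ subset must be non-empty")
    return soft_dice_t(Tensor(fixed_probs), Tensor(warped_moving_probs)).item()


# ---------------------------------------------------------------------------
# Field penalties (finite-difference stencils as explicit linear operators)


def _np_gradient_axis(x: np.ndarray, axis: int) -> np.ndarray:
    return np.gradient(x, axis=axis)


def _np_gradient_adjoint(g: np.ndarray, axis: int) -> np.ndarray:
    """Adjoint of np.gradient along one axis (central interior, one-sided edges)."""
    y = np.zeros_like(g)
    g0 = np.moveaxis(g, axis, 0)
    y0 = np.moveaxis(y, axis, 0)
    n = g0.shape[0]
    if n < 2:
        return y
    y0[0] -= g0[0]
    y0[1] += g0[0]
    y0[-1] += g0[-1]
    y0[-2] -= g0[-1]
    if n > 2:
        y0[2:] += g0[1:-1] / 2.0
        y0[:-2] -= g0[1:-1] / 2.0
    return y


def _grad_axis(t: Tensor, axis: int) -> Tensor:
    return linear_op(t, lambda x: _np_gradient_axis(x, axis),
                     lambda g: _np_gradient_adjoint(g, axis))


def _fwd_diff(x: np.ndarray, axis: int) -> np.ndarray:
    out = np.zeros_like(x)
    x0 = np.moveaxis(x, axis, 0)
    o0 = np.moveaxis(out, axis, 0)
    o0[:-1] = x0[1:] - x0[:-1]
    return out


def _fwd_diff_adjoint(g: np.ndarray, axis: int) -> np.ndarray:
    y = np.zeros_like(g)
    g0 = np.moveaxis(g, axis, 0)
    y0 = np.moveaxis(y, axis, 0)
    y0[1:] += g0[:-1]
    y0[:-1] -= g0[:-1]
    return y


def _fwd_diff_axis(t: Tensor, axis: int) -> Tensor:
    return linear_op(t, lambda x: _fwd_diff(x, axis),
                     lambda g: _fwd_diff_adjoint(g, axis))


def jacobian_det_t(u: list[Tensor]) -> Tensor:
    """Determinant of the Jacobian of x + u(x) from three component tensors."""
    J = [[_grad_axis(u[i], j) + (1.0 if i == j else 0.0) for j in range(3)]
         for i in range(3)]
    return (
        J[0][0] * (J[1][1] * J[2][2] - J[1][2] * J[2][1])
        - J[0][1] * (J[1][0] * J[2][2] - J[1][2] * J[2][0])
        + J[0][2] * (J[1][0] * J[2][1] - J[1][1] * J[2][0])
    )


def detjac_penalty_t(u: list[Tensor]) -> Tensor:
    det = jacobian_det_t(u)
    dev = det - 1.0
    return (dev * dev).mean()


def detjac_penalty(phi: DisplacementField) -> float:
    """Mean squared deviation of the Jacobian determinant from the identity."""
    comps = [Tensor(phi.u[c]) for c in range(3)]
    return detjac_penalty_t(comps).item()


def gradient_l2_t(u: list[Tensor]) -> Tensor:
    total = None
    for c in range(3):
        for ax in range(3):
            d = _fwd_diff_axis(u[c], ax)
            term = (d * d).mean()
            total = term if total is None else total + term
    return total * (1.0 / 9.0)


def gradient_l2_penalty(phi: DisplacementField) -> float:
    """Mean squared forward-difference derivative of the displacement,
    averaged over the 3 components x 3 axes.  Zero for any pure translation."""
    comps = [Tensor(phi.u[c]) for c in range(3)]
    return gradient_l2_t(comps).item()
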