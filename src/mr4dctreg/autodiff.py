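"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the tensor backend for the registration networks and the
differentiable training losses.  It implements exactly the operations the
pipeline needs — elementwise arithmetic, reductions, matmul, 3D convolution
(stride 1, odd kernels, same padding), 2x average pooling / nearest
upsampling, trilinear grid sampling with gradients w.r.t. both the image and
the sampling displacements, and generic linear operators with user-supplied
adjoints (used for finite-difference stencils and box filters).

Feature maps are laid out channel-first: ``(C, X, Y, Z)``.  All data is
float64; graphs are built eagerly and freed after ``backward``.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from scipy.ndimage import uniform_filter

__all__ = ["Tensor", "concat", "grid_sample", "conv3d", "avg_pool2",
           "upsample2", "linear_op", "box_sum"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """Node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: Sequence["Tensor"] = (), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    # -- graph -------------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
            # free graph refs early
            node._backward = None
            node._parents = ()

    # -- elementwise arithmetic --------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))

    def __add__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data ** 2,
                                          other.data.shape))

        out._backward = bwd
        return out

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        out._backward = bwd
        return out

    def exp(self):
        out = Tensor(np.exp(self.data), parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g / self.data)
        return out

    def sqrt(self):
        return self ** 0.5

    def clamp_min(self, lo: float):
        keep = self.data > lo
        out = Tensor(np.maximum(self.data, lo), parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * keep)
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60.0, 60.0)))
        out = Tensor(s, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * s * (1 - s))
        return out

    def leaky_relu(self, slope: float = 0.1):
        factor = np.where(self.data > 0, 1.0, slope)
        out = Tensor(self.data * factor, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * factor)
        return out

    # -- reductions / reshapes ---------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                ge = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(ge, self.data.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(*axes), parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            g.transpose(*inv))
        return out

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        out._backward = bwd
        return out


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    out._backward = bwd
    return out


def channel(t: Tensor, c: int) -> Tensor:
    """Select channel ``c`` of a channel-first tensor."""
    out = Tensor(t.data[c], parents=(t,))

    def bwd(g):
        if t.requires_grad:
            z = np.zeros_like(t.data)
            z[c] = g
            t._accum(z)

    out._backward = bwd
    return out


def linear_op(t: Tensor, fwd: Callable[[np.ndarray], np.ndarray],
              adj: Callable[[np.ndarray], np.ndarray]) -> Tensor:
    """Apply a linear operator with an explicitly supplied adjoint."""
    out = Tensor(fwd(t.data), parents=(t,))
    out._backward = lambda g: t.requires_grad and t._accum(adj(g))
    return out


def box_sum(t: Tensor, size: int) -> Tensor:
    """Zero-padded moving-window sum over a cubic ``size**3`` window.

    The kernel is symmetric, so the operator is self-adjoint.
    """
    n = float(size ** 3)

    def f(x):
        return uniform_filter(x, size=size, mode="constant", cval=0.0) * n

    return linear_op(t, f, f)


# ---------------------------------------------------------------------------
# Convolution / pooling / upsampling (channel-first (C, X, Y, Z))


def _conv3d_raw(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Correlation with 'same' zero padding; x (Ci,X,Y,Z), w (Co,Ci,k,k,k).

    Computed as a sum of 27 (k^3) small matmuls over shifted slices, which
    avoids the expensive im2col gather on strided 7D views.
    """
    co, ci, k = w.shape[0], w.shape[1], w.shape[2]
    p = k // 2
    sx, sy, sz = x.shape[1:]
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p)))
    out = np.zeros((co, sx * sy * sz), dtype=x.dtype)
    for a in range(k):
        for b_ in range(k):
            for c in range(k):
                xs = xp[:, a:a + sx, b_:b_ + sy, c:c + sz].reshape(ci, -1)
                out += w[:, :, a, b_, c] @ xs
    return out.reshape(co, sx, sy, sz)


def _conv3d_wgrad(x: np.ndarray, g: np.ndarray, k: int) -> np.ndarray:
    """Gradient w.r.t. the kernel: per-offset (Co,N) @ (N,Ci) products."""
    ci = x.shape[0]
    co = g.shape[0]
    p = k // 2
    sx, sy, sz = x.shape[1:]
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p)))
    gf = g.reshape(co, -1)
    dw = np.empty((co, ci, k, k, k), dtype=x.dtype)
    for a in range(k):
        for b_ in range(k):
            for c in range(k):
                xs = xp[:, a:a + sx, b_:b_ + sy, c:c + sz].reshape(ci, -1)
                dw[:, :, a, b_, c] = gf @ xs.T
    return dw


def conv3d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """3D convolution, stride 1, odd kernel, same zero padding."""
    k = w.data.shape[2]
    if k % 2 != 1:
        raise ValueError("conv3d requires odd kernel sizes")
    out_data = _conv3d_raw(x.data, w.data) + b.data.reshape(-1, 1, 1, 1)
    out = Tensor(out_data, parents=(x, w, b))

    def bwd(g):
        if b.requires_grad:
            b._accum(g.sum(axis=(1, 2, 3)))
        if w.requires_grad:
            w._accum(_conv3d_wgrad(x.data, g, k))
        if x.requires_grad:
            # grad wrt input = convolution of g with spatially flipped,
            # channel-transposed kernels
            wt = w.data[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
            x._accum(_conv3d_raw(g, np.ascontiguousarray(wt)))

    out._backward = bwd
    return out


def avg_pool2(x: Tensor) -> Tensor:
    """2x average pooling along each spatial axis (dims must be even)."""
    c, sx, sy, sz = x.data.shape
    if sx % 2 or sy % 2 or sz % 2:
        raise ValueError(f"avg_pool2 needs even spatial dims, got {x.data.shape}")
    r = x.data.reshape(c, sx // 2, 2, sy // 2, 2, sz // 2, 2)
    out = Tensor(r.mean(axis=(2, 4, 6)), parents=(x,))

    def bwd(g):
        if x.requires_grad:
            ge = np.repeat(np.repeat(np.repeat(g, 2, 1), 2, 2), 2, 3) / 8.0
            x._accum(ge)

    out._backward = bwd
    return out


def upsample2(x: Tensor) -> Tensor:
    """2x nearest-neighbour upsampling along each spatial axis."""
    out = Tensor(np.repeat(np.repeat(np.repeat(x.data, 2, 1), 2, 2), 2, 3),
                 parents=(x,))

    def bwd(g):
        if x.requires_grad:
            c, sx, sy, sz = g.shape
            gr = g.reshape(c, sx // 2, 2, sy // 2, 2, sz // 2, 2).sum(axis=(2, 4, 6))
            x._accum(gr)

    out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# Trilinear grid sampling (spatial transformer)


def grid_sample(img: Tensor, disp: Tensor, mode: str = "zero") -> Tensor:
    """Sample ``img`` (C,X,Y,Z) at ``x + disp(x)``; ``disp`` is (3,X,Y,Z).

    ``mode='zero'`` returns 0 outside the grid (image warping);
    ``mode='border'`` clamps sample coordinates to the grid (used for field
    self-composition in scaling-and-squaring).  Gradients flow to both the
    image values and the displacements.
    """
    C = img.data.shape[0]
    shape = img.data.shape[1:]
    if disp.data.shape != (3,) + shape:
        raise ValueError("displacement must be (3,) + image spatial shape")
    base = np.stack(np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape],
                                indexing="ij"), axis=0)
    g = base + disp.data
    dims = np.array(shape, dtype=np.float64).reshape(3, 1, 1, 1)

    if mode == "border":
        clamped = np.clip(g, 0.0, dims - 1.0)
        active = (g > 0.0) & (g < dims - 1.0)  # df/dg = 1 only off the border
        g = clamped
    else:
        active = np.ones_like(g, dtype=bool)

    f0 = np.floor(g)
    frac = g - f0
    i0 = f0.astype(np.int64)

    flat_img = img.data.reshape(C, -1)
    strides = np.array([shape[1] * shape[2], shape[2], 1], dtype=np.int64)
    N = shape[0] * shape[1] * shape[2]

    out_data = np.zeros((C,) + shape, dtype=np.float64)
    corners = []
    for cx in (0, 1):
        for cy in (0, 1):
            for cz in (0, 1):
                idx = np.stack([i0[0] + cx, i0[1] + cy, i0[2] + cz], axis=0)
                valid = np.ones(shape, dtype=bool)
                for d in range(3):
                    valid &= (idx[d] >= 0) & (idx[d] < shape[d])
                idx_c = np.clip(idx, 0, np.array(shape).reshape(3, 1, 1, 1) - 1)
                flat = (idx_c[0] * strides[0] + idx_c[1] * strides[1]
                        + idx_c[2] * strides[2])
                wx = frac[0] if cx else 1.0 - frac[0]
                wy = frac[1] if cy else 1.0 - frac[1]
                wz = frac[2] if cz else 1.0 - frac[2]
                wgt = wx * wy * wz * valid
                vals = flat_img[:, flat.ravel()].reshape((C,) + shape)
                vals = vals * valid  # zero-fill outside
                out_data += wgt * vals
                corners.append((cx, cy, cz, flat, valid, wgt, vals,
                                (wx, wy, wz)))

    out = Tensor(out_data, parents=(img, disp))

    def bwd(gout):
        if img.requires_grad:
            gimg = np.zeros((C, N), dtype=np.float64)
            for (_, _, _, flat, valid, wgt, _, _) in corners:
                contrib = (gout * wgt).reshape(C, -1)
                np.add.at(gimg.T, flat.ravel(), contrib.T)
            img._accum(gimg.reshape(img.data.shape))
        if disp.requires_grad:
            gdisp = np.zeros((3,) + shape, dtype=np.float64)
            for (cx, cy, cz, flat, valid, wgt, vals, (wx, wy, wz)) in corners:
                dot = (gout * vals).sum(axis=0)  # sum over channels
                sx = 1.0 if cx else -1.0
                sy = 1.0 if cy else -1.0
                sz = 1.0 if cz else -1.0
                gdisp[0] += dot * sx * wy * wz * valid
                gdisp[1] += dot * wx * sy * wz * valid
                gdisp[2] += dot * wx * wy * sz * valid
            disp._accum(gdisp * active)

    out._backward = bwd
    return out
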