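"""SVF-predicting registration network.

A 3D attention-gated encoder-decoder (Attention U-Net style): the fixed and
moving volumes are stacked channel-wise into a ``(2, X, Y, Z)`` input, and
the network outputs a stationary velocity field ``(3, X, Y, Z)`` on the same
grid.  The final layer is initialized near zero so an untrained network
predicts a near-identity warp — the safe starting point for registration.

Capacity is fully configurable (depth, base channels, attention on/off) so
the same code runs desk-scale experiments on small grids and the full
(128, 128, 64) working-resolution profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .autodiff import Tensor, avg_pool2, concat, conv3d, upsample2
from .fields import VelocityField
from .grids import Grid, Volume

__all__ = ["NetworkConfig", "RegistrationNetwork", "build_network",
           "predict_svf", "save_checkpoint", "load_checkpoint", "Adam"]

_HEAD_INIT_SCALE = 1e-5


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture/working-resolution configuration."""

    input_grid: Grid
    levels: int = 3
    base_channels: int = 8
    attention_gates: bool = True
    velocity_scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        div = 2 ** (self.levels - 1)
        bad = [s for s in self.input_grid.shape if s % div]
        if bad:
            raise ValueError(
                f"input grid dims {self.input_grid.shape} must be divisible by "
                f"2**(levels-1) = {div}"
            )
        if self.velocity_scale <= 0:
            raise ValueError("velocity_scale must be > 0")


class _Conv:
    """One conv layer; holds weight/bias parameter tensors."""

    def __init__(self, rng, c_in: int, c_out: int, k: int = 3,
                 init_scale: float | None = None):
        fan_in = c_in * k ** 3
        std = init_scale if init_scale is not None else np.sqrt(2.0 / fan_in)
        self.w = Tensor(rng.normal(0.0, std, size=(c_out, c_in, k, k, k)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv3d(x, self.w, self.b)

    def params(self):
        return [self.w, self.b]


class _Block:
    """conv -> lrelu -> conv -> lrelu."""

    def __init__(self, rng, c_in, c_out):
        self.c1 = _Conv(rng, c_in, c_out)
        self.c2 = _Conv(rng, c_out, c_out)

    def __call__(self, x):
        return self.c2(self.c1(x).leaky_relu()).leaky_relu()

    def params(self):
        return self.c1.params() + self.c2.params()


class _AttentionGate:
    """Additive attention gate: skip features are reweighted by a sigmoid map
    computed from the skip and the (upsampled) gating signal."""

    def __init__(self, rng, c_skip, c_gate):
        c_int = max(c_skip // 2, 1)
        self.theta = _Conv(rng, c_skip, c_int, k=1)
        self.phi = _Conv(rng, c_gate, c_int, k=1)
        self.psi = _Conv(rng, c_int, 1, k=1)

    def __call__(self, skip, gate):
        a = (self.theta(skip) + self.phi(gate)).leaky_relu()
        att = self.psi(a).sigmoid()
        return skip * att

    def params(self):
        return self.theta.params() + self.phi.params() + self.psi.params()


class RegistrationNetwork:
    """Attention U-Net mapping a (2, X, Y, Z) image stack to an SVF."""

    def __init__(self, cfg: NetworkConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        L = cfg.levels
        chans = [cfg.base_channels * 2 ** min(l, 2) for l in range(L)]
        self.enc = []
        c_in = 2
        for l in range(L):
            self.enc.append(_Block(rng, c_in, chans[l]))
            c_in = chans[l]
        self.gates = []
        self.dec = []
        for l in range(L - 2, -1, -1):
            if cfg.attention_gates:
                self.gates.append(_AttentionGate(rng, chans[l], chans[l + 1]))
            else:
                self.gates.append(None)
            self.dec.append(_Block(rng, chans[l] + chans[l + 1], chans[l]))
        self.head = _Conv(rng, chans[0], 3, init_scale=_HEAD_INIT_SCALE)

    def params(self) -> list[Tensor]:
        out = []
        for b in self.enc:
            out += b.params()
        for g in self.gates:
            if g is not None:
                out += g.params()
        for b in self.dec:
            out += b.params()
        out += self.head.params()
        return out

    def forward(self, x: Tensor) -> Tensor:
        """Predict the velocity field tensor (3, X, Y, Z) from a (2,...) stack."""
        skips = []
        h = x
        for l, blk in enumerate(self.enc):
            h = blk(h)
            if l < len(self.enc) - 1:
                skips.append(h)
                h = avg_pool2(h)
        for gate, blk, skip in zip(self.gates, self.dec, reversed(skips)):
            up = upsample2(h)
            s = gate(skip, up) if gate is not None else skip
            h = blk(concat([s, up], axis=0))
        return self.head(h) * self.cfg.velocity_scale

    def set_requires_grad(self, flag: bool) -> None:
        for p in self.params():
            p.requires_grad = flag


def build_network(cfg: NetworkConfig) -> RegistrationNetwork:
    """Build a network with deterministic, seeded initialization."""
    return RegistrationNetwork(cfg)


def predict_svf(net: RegistrationNetwork, fixed: Volume,
                moving: Volume) -> VelocityField:
    """Run inference: stack (fixed, moving) and predict the SVF."""
    grid = net.cfg.input_grid
    for v, name in ((fixed, "fixed"), (moving, "moving")):
        if v.grid.shape != grid.shape:
            raise ValueError(
                f"{name} volume shape {v.grid.shape} does not match the "
                f"network working grid {grid.shape}"
            )
    net.set_requires_grad(False)
    x = Tensor(np.stack([fixed.data, moving.data], axis=0))
    out = net.forward(x)
    net.set_requires_grad(True)
    return VelocityField(grid, out.data)


# ---------------------------------------------------------------------------
# Checkpoints


def save_checkpoint(net: RegistrationNetwork, path: str | Path) -> None:
    """Save parameters (.npz) with the config as a YAML sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"p{i}": p.data for i, p in enumerate(net.params())}
    np.savez(path, **arrays)
    cfg = net.cfg
    meta = {
        "levels": cfg.levels,
        "base_channels": cfg.base_channels,
        "attention_gates": cfg.attention_gates,
        "velocity_scale": cfg.velocity_scale,
        "seed": cfg.seed,
        "grid": {
            "shape": list(cfg.input_grid.shape),
            "spacing": list(cfg.input_grid.spacing),
            "origin": list(cfg.input_grid.origin),
        },
    }
    path.with_suffix(".yaml").write_text(yaml.safe_dump(meta))


def load_checkpoint(path: str | Path) -> RegistrationNetwork:
    path = Path(path)
    meta = yaml.safe_load(path.with_suffix(".yaml").read_text())
    grid = Grid(tuple(meta["grid"]["shape"]), tuple(meta["grid"]["spacing"]),
                tuple(meta["grid"]["origin"]))
    cfg = NetworkConfig(input_grid=grid, levels=meta["levels"],
                        base_channels=meta["base_channels"],
                        attention_gates=meta["attention_gates"],
                        velocity_scale=meta["velocity_scale"],
                        seed=meta["seed"])
    net = RegistrationNetwork(cfg)
    npz_path = path if path.suffix == ".npz" else path.with_suffix(".npz")
    with np.load(npz_path) as data:
        for i, p in enumerate(net.params()):
            p.data = data[f"p{i}"].astype(np.float64)
    return net


class Adam:
    """Adam optimizer over a parameter list."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 clip_norm: float | None = 1.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((p.grad ** 2).sum())
                                for p in self.params if p.grad is not None))
            if total > self.clip_norm:
                scale = self.clip_norm / total
                for p in self.params:
                    if p.grad is not None:
                        p.grad = p.grad * scale
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
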