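"""Minimal CPU implementation of a 2D U-Net with manual backpropagation.

Layers: 3x3 same-padding convolutions, per-channel batch normalization,
ReLU, 2x2 max pooling, nearest-neighbour x2 upsampling, channel
concatenation skips, and a linear 1x1 output convolution.  Gradients are
derived analytically per layer; optimization is Adam.  Everything is plain
numpy; gradient correctness is covered by finite-difference tests.
"""

from __future__ import annotations

from typing import Dict, Iterator, List, Tuple

import numpy as np


class Param:
    __slots__ = ("v", "g")

    def __init__(self, value: np.ndarray):
        self.v = value
        self.g = np.zeros_like(value)


class Conv2d:
    """k x k convolution, stride 1, 'same' zero padding (k odd)."""

    def __init__(self, rng: np.random.Generator, cin: int, cout: int, k: int = 3):
        std = np.sqrt(2.0 / (cin * k * k))  # He init for ReLU nets
        self.k = k
        self.W = Param(rng.normal(0.0, std, (cout, cin, k, k)))
        self.b = Param(np.zeros(cout))
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        N, C, H, Wd = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        self._xp = xp
        self._shape = (N, C, H, Wd)
        out = np.zeros((self.W.v.shape[0], N, H, Wd))
        for i in range(k):
            for j in range(k):
                out += np.tensordot(
                    self.W.v[:, :, i, j], xp[:, :, i : i + H, j : j + Wd], axes=([1], [1])
                )
        return out.transpose(1, 0, 2, 3) + self.b.v[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        N, C, H, Wd = self._shape
        xp = self._xp
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                self.W.g[:, :, i, j] += np.tensordot(
                    dy, xp[:, :, i : i + H, j : j + Wd], axes=([0, 2, 3], [0, 2, 3])
                )
                dxp[:, :, i : i + H, j : j + Wd] += np.tensordot(
                    self.W.v[:, :, i, j], dy, axes=([0], [1])
                ).transpose(1, 0, 2, 3)
        self.b.g += dy.sum(axis=(0, 2, 3))
        return dxp[:, :, p : p + H, p : p + Wd] if p else dxp

    def params(self) -> List[Param]:
        return [self.W, self.b]


class BatchNorm2d:
    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(ch))
        self.beta = Param(np.zeros(ch))
        self.running_mean = np.zeros(ch)
        self.running_var = np.ones(ch)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, train)
        return self.gamma.v[None, :, None, None] * xhat + self.beta.v[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, train = self._cache
        self.gamma.g += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.g += dy.sum(axis=(0, 2, 3))
        g = self.gamma.v[None, :, None, None]
        if not train:
            return dy * g * inv[None, :, None, None]
        n = dy.shape[0] * dy.shape[2] * dy.shape[3]
        dxhat = dy * g
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (inv[None, :, None, None] / n) * (n * dxhat - s1 - xhat * s2)

    def params(self) -> List[Param]:
        return [self.gamma, self.beta]


class ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._m = x > 0
        return x * self._m

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._m


class MaxPool2:
    def forward(self, x: np.ndarray) -> np.ndarray:
        N, C, H, W = x.shape
        xr = x.reshape(N, C, H // 2, 2, W // 2, 2)
        out = xr.max(axis=(3, 5))
        self._mask = xr == out[:, :, :, None, :, None]
        self._shape = x.shape
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dyr = dy[:, :, :, None, :, None] * self._mask
        return dyr.reshape(self._shape)


class UpNearest2:
    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        N, C, H, W = dy.shape
        return dy.reshape(N, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5))


class ConvBlock:
    """conv -> (batch norm) -> ReLU."""

    def __init__(self, rng, cin: int, cout: int, batch_norm: bool = True):
        self.conv = Conv2d(rng, cin, cout)
        self.bn = BatchNorm2d(cout) if batch_norm else None
        self.act = ReLU()

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        x = self.conv.forward(x)
        if self.bn is not None:
            x = self.bn.forward(x, train)
        return self.act.forward(x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = self.act.backward(dy)
        if self.bn is not None:
            dy = self.bn.backward(dy)
        return self.conv.backward(dy)

    def params(self) -> List[Param]:
        p = self.conv.params()
        if self.bn is not None:
            p += self.bn.params()
        return p


class UNet2D:
    """Encoder-decoder with skip connections and a linear 1x1 output.

    With ``depth`` encoder levels the network has depth + 1 + depth
    convolutional blocks plus the output convolution; depth=3 gives the
    canonical 8-convolution configuration.  Channels double per level.
    Input sizes must be divisible by 2**depth.
    """

    def __init__(
        self,
        depth: int = 3,
        base_channels: int = 16,
        in_channels: int = 1,
        out_channels: int = 1,
        batch_norm: bool = True,
        seed: int = 0,
        dtype=np.float64,
    ):
        rng = np.random.default_rng(seed)
        self.depth = depth
        self.base_channels = base_channels
        self.batch_norm = batch_norm
        self.dtype = np.dtype(dtype)
        chans = [base_channels * 2**i for i in range(depth)]
        self.enc: List[ConvBlock] = []
        ch = in_channels
        for c in chans:
            self.enc.append(ConvBlock(rng, ch, c, batch_norm))
            ch = c
        self.bottleneck = ConvBlock(rng, ch, 2 * ch, batch_norm)
        ch = 2 * ch
        self.dec: List[ConvBlock] = []
        for c in reversed(chans):
            self.dec.append(ConvBlock(rng, ch + c, c, batch_norm))
            ch = c
        self.out_conv = Conv2d(rng, ch, out_channels, k=1)
        self.pools = [MaxPool2() for _ in range(depth)]
        self.ups = [UpNearest2() for _ in range(depth)]
        self._skip_ch = chans
        if self.dtype != np.float64:
            for p in self.params():
                p.v = p.v.astype(self.dtype)
                p.g = p.g.astype(self.dtype)
            for b in self.blocks():
                if b.bn is not None:
                    b.bn.running_mean = b.bn.running_mean.astype(self.dtype)
                    b.bn.running_var = b.bn.running_var.astype(self.dtype)

    # -- plumbing ----------------------------------------------------------
    def blocks(self) -> List[ConvBlock]:
        return self.enc + [self.bottleneck] + self.dec

    def params(self) -> List[Param]:
        out: List[Param] = []
        for b in self.blocks():
            out += b.params()
        out += self.out_conv.params()
        return out

    def n_parameters(self) -> int:
        return int(sum(p.v.size for p in self.params()))

    def zero_grad(self) -> None:
        for p in self.params():
            p.g[...] = 0.0

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.ndim != 4:
            raise ValueError("input must be (batch, channel, H, W)")
        x = np.asarray(x, dtype=self.dtype)
        H, W = x.shape[2:]
        f = 2**self.depth
        if H % f or W % f:
            raise ValueError(f"input size {H}x{W} not divisible by 2^depth={f}")
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            x = blk.forward(x, train)
            skips.append(x)
            x = pool.forward(x)
        x = self.bottleneck.forward(x, train)
        for blk, up, skip in zip(self.dec, self.ups, reversed(skips)):
            x = up.forward(x)
            x = np.concatenate([x, skip], axis=1)
            x = blk.forward(x, train)
        return self.out_conv.forward(x)

    def backward(self, dy: np.ndarray) -> None:
        dy = self.out_conv.backward(np.asarray(dy, dtype=self.dtype))
        skip_grads = []
        for blk, up, c in zip(
            reversed(self.dec), reversed(self.ups), self._skip_ch
        ):
            dy = blk.backward(dy)
            n_up = dy.shape[1] - c
            skip_grads.append(dy[:, n_up:])
            dy = up.backward(dy[:, :n_up])
        dy = self.bottleneck.backward(dy)
        for blk, pool, ds in zip(
            reversed(self.enc), reversed(self.pools), reversed(skip_grads)
        ):
            dy = pool.backward(dy)
            dy = blk.backward(dy + ds)

    # -- (de)serialization -------------------------------------------------
    def state_dict(self) -> Dict[str, np.ndarray]:
        state: Dict[str, np.ndarray] = {}
        for i, p in enumerate(self.params()):
            state[f"p{i}"] = p.v
        for i, b in enumerate(self.blocks()):
            if b.bn is not None:
                state[f"rm{i}"] = b.bn.running_mean
                state[f"rv{i}"] = b.bn.running_var
        return state

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            p.v = np.array(state[f"p{i}"], dtype=self.dtype)
            p.g = np.zeros_like(p.v)
        for i, b in enumerate(self.blocks()):
            if b.bn is not None:
                b.bn.running_mean = np.array(state[f"rm{i}"], dtype=self.dtype)
                b.bn.running_var = np.array(state[f"rv{i}"], dtype=self.dtype)


class Adam:
    def __init__(self, params: List[Param], lr: float = 1e-3,
                 betas: Tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.v) for p in params]
        self.v = [np.zeros_like(p.v) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * p.g
            v[...] = self.b2 * v + (1 - self.b2) * p.g**2
            p.v -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
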