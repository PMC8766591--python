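"""Minimal pure-numpy encoder-decoder (U-net style) with explicit backprop.

Sized for CPU training at desk scale: im2col convolutions backed by BLAS
matmuls, 2x2 max pooling, nearest-neighbour upsampling, skip concatenation,
Adam.  Arrays are NCHW float64.  Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (C*k*k, N*H*W) patch matrix for stride-1 'same' conv."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (k, k), axis=(2, 3))  # (N, C, H, W, k, k)
    cols = win.transpose(1, 4, 5, 0, 2, 3).reshape(c * k * k, n * h * w)
    return np.ascontiguousarray(cols)


def _col2im(dcols: np.ndarray, shape: Tuple[int, int, int, int], k: int, pad: int) -> np.ndarray:
    """Adjoint of :func:`_im2col` (scatter-add patches back)."""
    n, c, h, w = shape
    dx = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
    d = dcols.reshape(c, k, k, n, h, w).transpose(3, 0, 1, 2, 4, 5)  # (N,C,k,k,H,W)
    for di in range(k):
        for dj in range(k):
            dx[:, :, di : di + h, dj : dj + w] += d[:, :, di, dj]
    if pad:
        dx = dx[:, :, pad:-pad, pad:-pad]
    return dx


class Conv:
    """Stride-1 convolution with 'same' padding (k=3) or 1x1 (k=1)."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (cin * k * k))  # He init for ReLU nets
        self.w = rng.normal(0.0, scale, size=(cout, cin * k * k))
        self.b = np.zeros(cout)
        self.k = k
        self.pad = k // 2
        self._cols: np.ndarray | None = None
        self._xshape: Tuple[int, int, int, int] | None = None
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        cols = _im2col(x, self.k, self.pad)
        self._cols, self._xshape = cols, x.shape
        out = self.w @ cols + self.b[:, None]  # (cout, N*H*W)
        return out.reshape(-1, n, h, w).transpose(1, 0, 2, 3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, cout, h, w = dout.shape
        dm = dout.transpose(1, 0, 2, 3).reshape(cout, n * h * w)
        self.dw = dm @ self._cols.T
        self.db = dm.sum(axis=1)
        dcols = self.w.T @ dm
        dx = _col2im(dcols, self._xshape, self.k, self.pad)
        self._cols = None
        return dx

    def params(self) -> List[np.ndarray]:
        return [self.w, self.b]

    def grads(self) -> List[np.ndarray]:
        return [self.dw, self.db]


class ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2:
    """2x2 max pooling, stride 2; gradient routed to the first argmax."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = xr.reshape(n, c, h // 2, w // 2, 4)
        self._idx = flat.argmax(axis=-1)
        self._xshape = x.shape
        return np.take_along_axis(flat, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._xshape
        dflat = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(dflat, self._idx[..., None], dout[..., None], axis=-1)
        return (
            dflat.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )


class Upsample2:
    """Nearest-neighbour 2x upsampling; gradient sums 2x2 blocks."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = dout.shape
        return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class _Block:
    """conv3x3-ReLU-conv3x3-ReLU."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.layers = [Conv(cin, cout, 3, rng), ReLU(), Conv(cout, cout, 3, rng), ReLU()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, d: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            d = layer.backward(d)
        return d

    def convs(self) -> List[Conv]:
        return [l for l in self.layers if isinstance(l, Conv)]


class UNet:
    """Encoder-decoder with skip connections and a 1-channel logit output.

    ``n_levels`` counts resolution levels including the bottleneck; channel
    widths double per level starting at ``base_channels``.
    """

    def __init__(self, n_levels: int = 3, base_channels: int = 8, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.n_levels = n_levels
        chans = [base_channels * 2**i for i in range(n_levels)]
        self.enc = []
        cin = 1
        for ch in chans[:-1]:
            self.enc.append(_Block(cin, ch, rng))
            cin = ch
        self.pools = [MaxPool2() for _ in chans[:-1]]
        self.bottleneck = _Block(cin, chans[-1], rng)
        self.ups: List[Upsample2] = []
        self.up_convs: List[Conv] = []
        self.dec: List[_Block] = []
        cin = chans[-1]
        for ch in reversed(chans[:-1]):
            self.ups.append(Upsample2())
            self.up_convs.append(Conv(cin, ch, 3, rng))
            self.dec.append(_Block(2 * ch, ch, rng))
            cin = ch
        self.head = Conv(chans[0], 1, 1, rng)
        self._skip_chans = list(reversed(chans[:-1]))

    # -- plumbing -----------------------------------------------------------
    def _all_convs(self) -> List[Conv]:
        convs: List[Conv] = []
        for blk in self.enc:
            convs += blk.convs()
        convs += self.bottleneck.convs()
        for upc, blk in zip(self.up_convs, self.dec):
            convs.append(upc)
            convs += blk.convs()
        convs.append(self.head)
        return convs

    def parameters(self) -> List[np.ndarray]:
        return [p for c in self._all_convs() for p in c.params()]

    def gradients(self) -> List[np.ndarray]:
        return [g for c in self._all_convs() for g in c.grads()]

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {f"p{i}": p for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("state dict does not match architecture")
        for i, p in enumerate(params):
            p[...] = state[f"p{i}"]

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """(N, 1, H, W) in [0, 1] -> (N, 1, H, W) logits.  H, W must be
        divisible by 2**(n_levels-1)."""
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            x = blk.forward(x)
            skips.append(x)
            x = pool.forward(x)
        x = self.bottleneck.forward(x)
        for up, upc, blk, skip in zip(self.ups, self.up_convs, self.dec, reversed(skips)):
            x = upc.forward(up.forward(x))
            x = np.concatenate([skip, x], axis=1)
            x = blk.forward(x)
        return self.head.forward(x)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        dskips = []
        for blk, upc, up, ch in zip(reversed(self.dec), reversed(self.up_convs),
                                    reversed(self.ups), reversed(self._skip_chans)):
            d = blk.backward(d)
            dskips.append(d[:, :ch])
            d = up.backward(upc.backward(d[:, ch:]))
        d = self.bottleneck.backward(d)
        # dskips were collected highest-resolution first; encoder unwinds deepest-first
        for blk, pool, dskip in zip(reversed(self.enc), reversed(self.pools), reversed(dskips)):
            d = blk.backward(pool.backward(d) + dskip)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, y: np.ndarray) -> Tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits; returns (loss, dloss/dz)."""
    loss = float(np.mean(np.logaddexp(0.0, z) - y * z))
    dz = (sigmoid(z) - y) / z.size
    return loss, dz


def dice_with_logits(z: np.ndarray, y: np.ndarray, eps: float = 1.0) -> Tuple[float, np.ndarray]:
    """Soft Dice loss on sigmoid probabilities; returns (loss, dloss/dz)."""
    p = sigmoid(z)
    inter = float((p * y).sum())
    denom = float(p.sum() + y.sum()) + eps
    dice = (2.0 * inter + eps) / denom
    dp = (2.0 * y * denom - (2.0 * inter + eps)) / denom**2
    dz = -dp * p * (1.0 - p)
    return 1.0 - dice, dz


class Adam:
    def __init__(self, params: List[np.ndarray], lr: float = 2e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: List[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1.0 - self.b1) * g
            v[...] = self.b2 * v + (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
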