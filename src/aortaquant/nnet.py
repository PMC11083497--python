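"""Minimal CPU neural-network primitives (numpy, float32).

Implements exactly what the pipeline's two learned models need: 3D "same"
convolutions via im2col, batch normalization, ReLU, 2x max pooling, nearest
upsampling, a sigmoid/BCE head, a dense MLP, and Adam. Shapes follow the
(C, D, H, W) single-sample convention; training is patch-at-a-time, which
keeps memory bounded and runs deterministically for a fixed seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Adam", "Conv3d", "BatchNorm", "ReLU", "MaxPool2", "UpsampleNearest2",
           "UNet3D", "MLP", "sigmoid", "bce_with_logits"]


class Adam:
    """Adam optimizer over a flat list of (param, grad) pairs."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv3d:
    """3x3x3 (or 1x1x1) same-padded convolution on (C, D, H, W) tensors."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        assert k in (1, 3)
        self.k, self.cin, self.cout = k, cin, cout
        self.W = _he_init(rng, (cin * k ** 3, cout), cin * k ** 3)
        self.b = np.zeros(cout, dtype=np.float32)
        self._cols = None
        self._shape = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        c, d, h, w = x.shape
        if self.k == 1:
            cols = x.reshape(c, -1).T
        else:
            xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
            win = sliding_window_view(xp, (3, 3, 3), axis=(1, 2, 3))  # (c,d,h,w,3,3,3)
            cols = win.transpose(1, 2, 3, 0, 4, 5, 6).reshape(d * h * w, c * 27)
            cols = np.ascontiguousarray(cols, dtype=np.float32)
        out = cols @ self.W + self.b
        if train:
            self._cols, self._shape = cols, (c, d, h, w)
        return out.T.reshape(self.cout, d, h, w)

    def backward(self, dout: np.ndarray):
        c, d, h, w = self._shape
        dflat = np.ascontiguousarray(dout.reshape(self.cout, -1).T, dtype=np.float32)
        self.dW = self._cols.T @ dflat
        self.db = dflat.sum(axis=0)
        if self.k == 1:
            dx = (dflat @ self.W.T).T.reshape(c, d, h, w)
        else:
            # dx = dout convolved with the spatially flipped, io-swapped kernel
            Wr = self.W.reshape(self.cin, 3, 3, 3, self.cout)
            Wd = np.ascontiguousarray(
                Wr[:, ::-1, ::-1, ::-1, :].transpose(4, 1, 2, 3, 0)
            ).reshape(self.cout * 27, self.cin)
            dp = np.pad(dout, ((0, 0), (1, 1), (1, 1), (1, 1)))
            win = sliding_window_view(dp, (3, 3, 3), axis=(1, 2, 3))
            cols = np.ascontiguousarray(
                win.transpose(1, 2, 3, 0, 4, 5, 6), dtype=np.float32
            ).reshape(d * h * w, self.cout * 27)
            dx = (cols @ Wd).T.reshape(c, d, h, w)
        self._cols = None
        return dx

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class BatchNorm:
    """Per-channel normalization over the spatial axes of one sample.

    Training normalizes each sample by its own spatial statistics (the batch
    is a single patch), so inference defaults to the same per-input statistics
    ("instance" mode); running averages are still tracked and available via
    ``eval_stats="running"``.
    """

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5,
                 eval_stats: str = "instance"):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.run_mean = np.zeros(c, dtype=np.float32)
        self.run_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self.eval_stats = eval_stats

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        c = x.shape[0]
        xf = x.reshape(c, -1)
        if train:
            mu = xf.mean(axis=1)
            var = xf.var(axis=1)
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mu
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        elif self.eval_stats == "instance":
            mu = xf.mean(axis=1)
            var = xf.var(axis=1)
        else:
            mu, var = self.run_mean, self.run_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (xf - mu[:, None]) * inv[:, None]
        if train:
            self._xhat, self._inv, self._shape = xhat, inv, x.shape
        return (self.gamma[:, None] * xhat + self.beta[:, None]).reshape(x.shape).astype(np.float32)

    def backward(self, dout: np.ndarray):
        c = dout.shape[0]
        df = dout.reshape(c, -1).astype(np.float32)
        n = df.shape[1]
        self.dgamma = (df * self._xhat).sum(axis=1)
        self.dbeta = df.sum(axis=1)
        dxhat = df * self.gamma[:, None]
        dx = (self._inv[:, None] / n) * (
            n * dxhat - dxhat.sum(axis=1, keepdims=True)
            - self._xhat * (dxhat * self._xhat).sum(axis=1, keepdims=True))
        self._xhat = None
        return dx.reshape(self._shape)

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]


class ReLU:
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dout: np.ndarray):
        return dout * self._mask

    def params(self):
        return []

    def grads(self):
        return []


class MaxPool2:
    """2x2x2 max pooling; spatial dims must be even."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        c, d, h, w = x.shape
        xr = (x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
              .transpose(0, 1, 3, 5, 2, 4, 6)
              .reshape(c, d // 2, h // 2, w // 2, 8))
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx, self._shape = idx, x.shape
        return out

    def backward(self, dout: np.ndarray):
        c, d, h, w = self._shape
        g = np.zeros((c, d // 2, h // 2, w // 2, 8), dtype=np.float32)
        np.put_along_axis(g, self._idx[..., None], dout[..., None], axis=-1)
        return (g.reshape(c, d // 2, h // 2, w // 2, 2, 2, 2)
                .transpose(0, 1, 4, 2, 5, 3, 6)
                .reshape(c, d, h, w))


class UpsampleNearest2:
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout: np.ndarray):
        c, d, h, w = dout.shape
        return (dout.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
                .sum(axis=(2, 4, 6)))


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce_with_logits(logits: np.ndarray, target: np.ndarray):
    """Mean binary cross entropy; returns (loss, dlogits)."""
    p = sigmoid(logits)
    eps = 1e-7
    loss = -np.mean(target * np.log(p + eps) + (1 - target) * np.log(1 - p + eps))
    dlogits = ((p - target) / target.size).astype(np.float32)
    return float(loss), dlogits


class _ConvBlock:
    """conv -> BN -> ReLU, twice."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.layers = [Conv3d(cin, cout, 3, rng), BatchNorm(cout), ReLU(),
                       Conv3d(cout, cout, 3, rng), BatchNorm(cout), ReLU()]

    def forward(self, x, train=True):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, d):
        for l in reversed(self.layers):
            d = l.backward(d)
        return d

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def grads(self):
        return [g for l in self.layers for g in l.grads()]


class UNet3D:
    """Encoder-decoder segmentation network with skip connections.

    ``depth`` encoder levels with ``base_filters`` doubling per level,
    3x3x3 kernels, batch norm and ReLU throughout, nearest upsampling in the
    decoder and a 1x1x1 sigmoid head. Input spatial dims must be divisible by
    2**(depth-1).
    """

    def __init__(self, depth: int = 3, base_filters: int = 8, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.depth = depth
        chans = [base_filters * 2 ** i for i in range(depth)]
        self.enc = []
        cin = 1
        for c in chans[:-1]:
            self.enc.append(_ConvBlock(cin, c, rng))
            cin = c
        self.pools = [MaxPool2() for _ in range(depth - 1)]
        self.bottleneck = _ConvBlock(cin, chans[-1], rng)
        self.ups = [UpsampleNearest2() for _ in range(depth - 1)]
        self.dec = []
        cin = chans[-1]
        for c in reversed(chans[:-1]):
            self.dec.append(_ConvBlock(cin + c, c, rng))
            cin = c
        self.head = Conv3d(cin, 1, 1, rng)

    # -- plumbing ----------------------------------------------------------

    def _modules(self):
        return self.enc + [self.bottleneck] + self.dec + [self.head]

    def params(self):
        return [p for m in self._modules() for p in m.params()]

    def grads(self):
        return [g for m in self._modules() for g in m.grads()]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """x: (D, H, W) normalized intensities -> logits (D, H, W)."""
        t = x[None].astype(np.float32)
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            t = blk.forward(t, train)
            skips.append(t)
            t = pool.forward(t, train)
        t = self.bottleneck.forward(t, train)
        self._skip_channels = []
        for up, blk, skip in zip(self.ups, self.dec, reversed(skips)):
            t = up.forward(t, train)
            t = np.concatenate([skip, t], axis=0)
            self._skip_channels.append(skip.shape[0])
            t = blk.forward(t, train)
        logits = self.head.forward(t, train)
        return logits[0]

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits[None])
        dskips = []
        for blk, up, nskip in zip(reversed(self.dec), reversed(self.ups),
                                  reversed(self._skip_channels)):
            d = blk.backward(d)
            dskips.append(d[:nskip])
            d = up.backward(d[nskip:])
        d = self.bottleneck.backward(d)
        # dskips were collected decoder-first, i.e. for skips[0], skips[1], ...
        # reversed(enc) needs the deepest skip first
        for blk, pool, dskip in zip(reversed(self.enc), reversed(self.pools),
                                    reversed(dskips)):
            d = pool.backward(d)
            d = blk.backward(d + dskip)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Inference on an arbitrary (D, H, W) grid (padded to stride)."""
        stride = 2 ** (self.depth - 1)
        shp = np.asarray(x.shape)
        pad = (-shp) % stride
        xp = np.pad(x, [(0, int(p)) for p in pad], mode="edge")
        logits = self.forward(xp, train=False)
        logits = logits[: shp[0], : shp[1], : shp[2]]
        return sigmoid(logits)

    # -- persistence ---------------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for i, m in enumerate(self._modules()):
            for j, p in enumerate(m.params()):
                out[f"p_{i}_{j}"] = p
        # running stats live outside params()
        k = 0
        for m in self._modules():
            layers = m.layers if isinstance(m, _ConvBlock) else [m]
            for l in layers:
                if isinstance(l, BatchNorm):
                    out[f"bn_{k}_mean"] = l.run_mean
                    out[f"bn_{k}_var"] = l.run_var
                    k += 1
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, m in enumerate(self._modules()):
            for j, p in enumerate(m.params()):
                p[...] = state[f"p_{i}_{j}"]
        k = 0
        for m in self._modules():
            layers = m.layers if isinstance(m, _ConvBlock) else [m]
            for l in layers:
                if isinstance(l, BatchNorm):
                    l.run_mean[...] = state[f"bn_{k}_mean"]
                    l.run_var[...] = state[f"bn_{k}_var"]
                    k += 1


class MLP:
    """Small dense network (float64) for Q-value regression."""

    def __init__(self, sizes: list[int], seed: int = 0):
        rng = np.random.default_rng(seed)
        self.Ws = [rng.standard_normal((a, b)) * np.sqrt(2.0 / a)
                   for a, b in zip(sizes[:-1], sizes[1:])]
        self.bs = [np.zeros(b) for b in sizes[1:]]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._acts = [x]
        for i, (W, b) in enumerate(zip(self.Ws, self.bs)):
            x = x @ W + b
            if i < len(self.Ws) - 1:
                x = np.maximum(x, 0.0)
            self._acts.append(x)
        return x

    def backward_step(self, dout: np.ndarray, opt: "Adam") -> None:
        grads_W, grads_b = [], []
        d = dout
        for i in range(len(self.Ws) - 1, -1, -1):
            a = self._acts[i]
            grads_W.append(a.T @ d)
            grads_b.append(d.sum(axis=0))
            if i > 0:
                d = d @ self.Ws[i].T
                d = d * (self._acts[i] > 0)
        opt.step(list(reversed(grads_W)) + list(reversed(grads_b)))

    def params(self):
        return self.Ws + self.bs

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for i, W in enumerate(self.Ws):
            out[f"W_{i}"] = W
        for i, b in enumerate(self.bs):
            out[f"b_{i}"] = b
        return out

    def load_state_arrays(self, state) -> None:
        for i in range(len(self.Ws)):
            self.Ws[i][...] = state[f"W_{i}"]
            self.bs[i][...] = state[f"b_{i}"]

    def copy_from(self, other: "MLP") -> None:
        for a, b in zip(self.Ws + self.bs, other.Ws + other.bs):
            a[...] = b
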