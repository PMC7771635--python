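"""A small, self-contained 2D U-Net in numpy.

Encoder-decoder with skip concatenations: each contracting level applies two
3x3 convolutions (ReLU) and a 2x2 max-pool, doubling the feature count; the
expanding path mirrors it with nearest-neighbour upsampling, a channel-
reducing convolution, and concatenation with the matching encoder features.
A final 1x1 convolution and softmax produce per-pixel class probabilities
(background + 3 foreground labels).  Training uses per-pixel cross-entropy
and Adam.

Convolutions are im2col matrix products; gradients are computed analytically
(the input gradient of a convolution is a convolution with the 180-degree
rotated, transposed kernel).  Everything is float32 and deterministic given
the seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np


@dataclasses.dataclass
class NetConfig:
    """Architecture and training hyper-parameters.

    ``input_size`` must be divisible by ``2**n_levels`` so that pooling and
    upsampling round-trip exactly.  The full-scale configuration is
    input_size=320 with 5 levels; tests and desk-scale training shrink both.
    """

    input_size: int = 320
    n_levels: int = 5
    base_features: int = 16
    n_classes: int = 4  # background + blood pool + veins + valve
    learning_rate: float = 1e-3
    batch_size: int = 8
    epochs_phase1: int = 12
    epochs_phase2: int = 4
    seed: int = 0
    dtype: str = "float32"  # float64 useful for finite-difference checks

    def __post_init__(self):
        if self.input_size % (2**self.n_levels) != 0:
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2^{self.n_levels}"
            )
        if self.n_classes != 4:
            raise ValueError("the multilabel net uses 4 output channels (background + 3)")


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> (N, H, W, C*9) patches of the 1-padded input."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
    # win: (N, C, H, W, 3, 3) -> (N, H, W, C, 3, 3)
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n, h, w, c * 9)


class Conv3x3:
    """3x3 same-padding convolution with optional fused ReLU."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, relu: bool = True, dtype=np.float32):
        scale = np.sqrt(2.0 / (9 * c_in))  # He initialization
        self.w = (rng.standard_normal((c_out, c_in, 3, 3)) * scale).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.relu = relu
        self.c_in, self.c_out = c_in, c_out

    def forward(self, x, train=True):
        cols = _im2col(x)  # (N, H, W, C*9)
        y = cols @ self.w.reshape(self.c_out, -1).T + self.b
        y = y.transpose(0, 3, 1, 2)
        if self.relu:
            mask = y > 0
            y = y * mask
            if train:
                self._relu_mask = mask
        if train:
            self._cols = cols
        return np.ascontiguousarray(y)

    def backward(self, dy):
        if self.relu:
            dy = dy * self._relu_mask
        n, c, h, w = dy.shape
        dyf = dy.transpose(0, 2, 3, 1).reshape(-1, self.c_out)  # (NHW, c_out)
        self.dw = (dyf.T @ self._cols.reshape(-1, self.c_in * 9)).reshape(self.w.shape)
        self.db = dyf.sum(axis=0)
        # dx = conv(dy, flipped & transposed kernels)
        w_t = self.w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (c_in, c_out, 3, 3)
        cols = _im2col(dy)
        dx = cols @ w_t.reshape(self.c_in, -1).T
        self._cols = None
        self._relu_mask = None
        return np.ascontiguousarray(dx.transpose(0, 3, 1, 2))

    def params(self):
        return [("w", self), ("b", self)]


class Conv1x1:
    def __init__(self, c_in, c_out, rng, dtype=np.float32):
        scale = np.sqrt(2.0 / c_in)
        self.w = (rng.standard_normal((c_out, c_in)) * scale).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.c_in, self.c_out = c_in, c_out

    def forward(self, x, train=True):
        if train:
            self._x = x
        y = np.einsum("nchw,oc->nohw", x, self.w) + self.b[:, None, None]
        return y

    def backward(self, dy):
        self.dw = np.einsum("nohw,nchw->oc", dy, self._x)
        self.db = dy.sum(axis=(0, 2, 3))
        self._x = None
        return np.einsum("nohw,oc->nchw", dy, self.w)


class MaxPool2:
    def forward(self, x, train=True):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        y = xr.max(axis=(3, 5))
        if train:
            self._mask = xr == y[:, :, :, None, :, None]
            # break ties deterministically: keep only the first max per window
            flat = self._mask.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
            first = np.cumsum(flat, axis=-1) == 1
            self._mask = (flat & first).reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return y

    def backward(self, dy):
        n, c, h2, w2 = dy.shape
        dx = self._mask * dy[:, :, :, None, :, None]
        self._mask = None
        return dx.reshape(n, c, h2 * 2, w2 * 2)


def _upsample2(x):
    return x.repeat(2, axis=2).repeat(2, axis=3)


def _downsample_grad(dy):
    n, c, h, w = dy.shape
    return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

class UNet:
    """Multilabel U-Net; ``n_levels`` pool/upsample stages with skip concatenations."""

    def __init__(self, cfg: NetConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.dtype = np.dtype(cfg.dtype).type
        f = cfg.base_features
        self.enc = []  # per level: (conv_a, conv_b)
        c_in = 1
        feats = []
        for lvl in range(cfg.n_levels):
            c_out = f * 2**lvl
            self.enc.append((Conv3x3(c_in, c_out, rng, dtype=self.dtype), Conv3x3(c_out, c_out, rng, dtype=self.dtype)))
            feats.append(c_out)
            c_in = c_out
        c_bot = f * 2**cfg.n_levels
        self.bottleneck = (Conv3x3(c_in, c_bot, rng, dtype=self.dtype), Conv3x3(c_bot, c_bot, rng, dtype=self.dtype))
        self.dec = []  # per level (deep->shallow): (reduce_conv, conv_a, conv_b)
        c_in = c_bot
        for lvl in reversed(range(cfg.n_levels)):
            c_out = feats[lvl]
            reduce = Conv3x3(c_in, c_out, rng, dtype=self.dtype)
            conv_a = Conv3x3(2 * c_out, c_out, rng, dtype=self.dtype)  # after skip concatenation
            conv_b = Conv3x3(c_out, c_out, rng, dtype=self.dtype)
            self.dec.append((reduce, conv_a, conv_b))
            c_in = c_out
        self.head = Conv1x1(c_in, cfg.n_classes, rng, dtype=self.dtype)
        self._check_shapes()

    def _check_shapes(self):
        """Assert the encoder/decoder shape arithmetic at construction time."""
        s, f = self.cfg.input_size, self.cfg.base_features
        for lvl, (ca, cb) in enumerate(self.enc):
            assert ca.c_out == cb.c_out == f * 2**lvl
            assert s % 2 == 0, f"spatial size {s} not divisible at level {lvl}"
            s //= 2
        for (reduce, ca, _), (enc_a, _) in zip(self.dec, reversed(self.enc)):
            s *= 2
            assert ca.c_in == reduce.c_out + enc_a.c_out, "skip concatenation shape mismatch"
        assert s == self.cfg.input_size

    def _layers(self):
        for pair in self.enc:
            yield from pair
        yield from self.bottleneck
        for triple in self.dec:
            yield from triple
        yield self.head

    # forward / backward -------------------------------------------------
    def forward(self, x, train=True):
        """x: (N, 1, H, W) float32 in [0, 1] -> per-pixel class probabilities."""
        skips = []
        self._pools = []
        h = x.astype(self.dtype)
        for ca, cb in self.enc:
            h = cb.forward(ca.forward(h, train), train)
            skips.append(h)
            h = self._pool(h, train)
        ca, cb = self.bottleneck
        h = cb.forward(ca.forward(h, train), train)
        self._concat_sizes = []
        for (reduce, conv_a, conv_b), skip in zip(self.dec, reversed(skips)):
            h = reduce.forward(_upsample2(h), train)
            h = np.concatenate([skip, h], axis=1)
            self._concat_sizes.append(skip.shape[1])
            h = conv_b.forward(conv_a.forward(h, train), train)
        logits = self.head.forward(h, train)
        # numerically stable softmax over the channel axis
        m = logits.max(axis=1, keepdims=True)
        e = np.exp(logits - m)
        probs = e / e.sum(axis=1, keepdims=True)
        if train:
            self._probs = probs
        return probs

    def _pool(self, h, train):
        pool = MaxPool2()
        if train:
            self._pools.append(pool)
        return pool.forward(h, train)

    def backward(self, onehot):
        """Backprop of mean per-pixel cross-entropy; ``onehot``: (N, K, H, W)."""
        n, _, h, w = onehot.shape
        dy = (self._probs - onehot) / (n * h * w)
        dy = self.head.backward(dy.astype(self.dtype))
        dskips = []
        for (reduce, conv_a, conv_b), k in zip(reversed(self.dec), reversed(self._concat_sizes)):
            d = conv_a.backward(conv_b.backward(dy))
            dskips.append(d[:, :k])
            dy = _downsample_grad(reduce.backward(d[:, k:]))
        ca, cb = self.bottleneck
        dy = ca.backward(cb.backward(dy))
        for (ca, cb), pool, dskip in zip(
            reversed(self.enc), reversed(self._pools), reversed(dskips)
        ):
            dy = pool.backward(dy) + dskip
            dy = ca.backward(cb.backward(dy))
        self._pools = []
        self._probs = None
        return dy

    def loss(self, probs, onehot):
        eps = 1e-7
        return float(-(onehot * np.log(probs + eps)).sum() / (probs.shape[0] * probs.shape[2] * probs.shape[3]))

    # parameter access for the optimizer ---------------------------------
    def parameters(self):
        for layer in self._layers():
            yield layer, "w"
            yield layer, "b"

    def state_dict(self):
        return {
            f"{i}.{name}": getattr(layer, name).copy()
            for i, (layer, name) in enumerate(self.parameters())
        }

    def load_state_dict(self, state):
        for i, (layer, name) in enumerate(self.parameters()):
            setattr(layer, name, state[f"{i}.{name}"].copy())

    def save(self, path):
        np.savez(path, **self.state_dict())

    @classmethod
    def load(cls, path, cfg: NetConfig):
        net = cls(cfg)
        net.load_state_dict(dict(np.load(path)))
        return net


class Adam:
    def __init__(self, net: UNet, lr: float):
        self.net = net
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {}
        self.v = {}

    def step(self):
        self.t += 1
        for i, (layer, name) in enumerate(self.net.parameters()):
            g = getattr(layer, "d" + name)
            key = (i, name)
            m = self.m.get(key, 0.0) * self.b1 + (1 - self.b1) * g
            v = self.v.get(key, 0.0) * self.b2 + (1 - self.b2) * g * g
            self.m[key], self.v[key] = m, v
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p = getattr(layer, name)
            setattr(layer, name, (p - self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype))
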