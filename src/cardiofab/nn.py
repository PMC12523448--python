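"""Minimal 3D convolutional network framework (numpy, CPU).

Implements exactly what the segmentation cascade needs: 3x3x3 and 1x1x1
convolutions (shift-and-add formulation, which on CPU beats an im2col
matmul for the small channel counts used here), ReLU, 2x max pooling,
nearest-neighbour upsampling, a U-Net-style encoder-decoder with skip
connections, a multi-scale spatial-channel co-attention block, a
soft-Dice + cross-entropy loss, and Adam.  All arithmetic is float32
numpy with explicit backward passes, so training is bit-deterministic
for a fixed seed within one process.

Tensors are channel-first: ``(C, D, H, W)``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Param", "Conv3d", "UNet3D", "CoAttention", "Adam",
           "softmax", "dice_ce_loss"]

F32 = np.float32


class Param:
    """A trainable array with its gradient and Adam state."""

    __slots__ = ("v", "g", "m", "s")

    def __init__(self, value: np.ndarray):
        self.v = value.astype(F32)
        self.g = np.zeros_like(self.v)
        self.m = np.zeros_like(self.v)
        self.s = np.zeros_like(self.v)


def _shifted(xp: np.ndarray, i: int, shape) -> np.ndarray:
    """View of padded input shifted by kernel offset i (k=3)."""
    dz, r = divmod(i, 9)
    dy, dx = divmod(r, 3)
    C = xp.shape[0]
    D, H, W = shape
    return xp[:, dz:dz + D, dy:dy + H, dx:dx + W].reshape(C, -1)


class Conv3d:
    """3D convolution, kernel 3 (padded) or 1, with bias.

    Weights are stored as ``(k^3, cin, cout)`` so the forward pass is a
    sum of k^3 small matrix products over shifted views of the input.
    """

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 zero_init: bool = False):
        assert k in (1, 3)
        self.cin, self.cout, self.k = cin, cout, k
        fan_in = cin * k ** 3
        if zero_init:
            w = np.zeros((k ** 3, cin, cout))
        else:
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(k ** 3, cin, cout))
        self.W = Param(w)
        self.b = Param(np.zeros(cout))

    def params(self) -> list[Param]:
        return [self.W, self.b]

    @staticmethod
    def _apply(x: np.ndarray, W: np.ndarray, b: np.ndarray | None) -> np.ndarray:
        cout = W.shape[2]
        C, D, H, Wd = x.shape
        if W.shape[0] == 1:
            y = W[0].T @ x.reshape(C, -1)
        else:
            xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
            y = np.zeros((cout, D * H * Wd), dtype=F32)
            for i in range(27):
                y += W[i].T @ _shifted(xp, i, (D, H, Wd))
        if b is not None:
            y += b[:, None]
        return y.reshape(cout, D, H, Wd)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        if self.k == 1:
            self._cols = None
            return self._apply(x, self.W.v, self.b.v)
        C, D, H, Wd = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
        # keep the shifted views materialized: the backward pass reuses
        # them for the weight gradient, halving the copy traffic
        self._cols = [_shifted(xp, i, (D, H, Wd)) for i in range(27)]
        y = np.zeros((self.cout, D * H * Wd), dtype=F32)
        for i in range(27):
            y += self.W.v[i].T @ self._cols[i]
        y += self.b.v[:, None]
        return y.reshape(self.cout, D, H, Wd)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        C, D, H, Wd = x.shape
        dyf = dy.reshape(self.cout, -1)
        self.b.g += dyf.sum(axis=1)
        if self.k == 1:
            self.W.g[0] += x.reshape(C, -1) @ dyf.T
            return (self.W.v[0] @ dyf).reshape(x.shape)
        for i in range(27):
            self.W.g[i] += self._cols[i] @ dyf.T
        self._cols = None  # free before allocating the dx pass
        # dx = "full" correlation of dy with the flipped kernel
        Wflip = self.W.v[::-1].transpose(0, 2, 1).copy()
        return self._apply(dy, Wflip, None)


class _ReLU:
    def forward(self, x):
        self._m = x > 0
        return np.where(self._m, x, F32(0))

    def backward(self, dy):
        return np.where(self._m, dy, F32(0))


def maxpool2(x: np.ndarray) -> tuple[np.ndarray, tuple]:
    C, D, H, W = x.shape
    xr = x.reshape(C, D // 2, 2, H // 2, 2, W // 2, 2)
    y = xr.max(axis=(2, 4, 6))
    return y, (x, y)


def maxpool2_back(dy: np.ndarray, cache: tuple) -> np.ndarray:
    x, y = cache
    up = upsample2(y)
    m = (x == up).astype(F32)
    # distribute over ties so the gradient check stays exact
    cnt = sumpool2(m)
    return m * upsample2(dy / cnt)


def upsample2(x: np.ndarray) -> np.ndarray:
    return x.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)


def sumpool2(x: np.ndarray) -> np.ndarray:
    C, D, H, W = x.shape
    return x.reshape(C, D // 2, 2, H // 2, 2, W // 2, 2).sum(axis=(2, 4, 6))


def avgpool2(x: np.ndarray) -> np.ndarray:
    return sumpool2(x) / F32(8)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class CoAttention:
    """Multi-scale spatial-channel co-attention.

    Operates on the encoder-decoder junction features of one forward
    pass (the skip tensors plus the bottleneck, ordered fine to
    coarse, each scale half the resolution of the previous).  Channel
    descriptors (global average pooling) from *all* scales are
    concatenated and passed through one learned linear + sigmoid, then
    redistributed, so each scale's channel weights depend on every
    scale.  Channel-pooled spatial maps are resampled to the coarsest
    grid, stacked, and passed through a shared 3x3x3 convolution +
    sigmoid to produce one spatial weight map per scale.  The output is
    ``x * cw * sw + x`` (multiplicative reweighting with a residual
    path).

    Both transforms are zero-initialized, so an untrained module applies
    uniform weights of sigmoid(0) = 0.5 at every channel and location.
    """

    def __init__(self, channels: list[int], rng: np.random.Generator):
        self.channels = list(channels)
        self.S = len(channels)
        total = sum(channels)
        self.Wc = Param(np.zeros((total, total)))
        self.bc = Param(np.zeros(total))
        self.spatial = Conv3d(self.S, self.S, 3, rng, zero_init=True)

    def params(self) -> list[Param]:
        return [self.Wc, self.bc] + self.spatial.params()

    def saturate(self, level: float = 60.0) -> None:
        """Push both sigmoids toward 1 (weights saturate; output -> 2x)."""
        self.bc.v[:] = level
        self.spatial.b.v[:] = level

    def forward(self, feats: list[np.ndarray]) -> list[np.ndarray]:
        ndims = {f.ndim for f in feats}
        if len(ndims) != 1 or ndims != {4}:
            raise ValueError("all feature maps must be (C, D, H, W)")
        if [f.shape[0] for f in feats] != self.channels:
            raise ValueError("feature channel counts do not match module config")
        self._f = feats
        self._n = [int(np.prod(f.shape[1:])) for f in feats]
        # channel branch: joint transform of concatenated GAP descriptors
        d = np.concatenate([f.mean(axis=(1, 2, 3)) for f in feats])
        a = self.Wc.v @ d + self.bc.v
        cw = _sigmoid(a)
        self._d, self._cw = d, cw
        # spatial branch: channel means, resampled to the coarsest scale
        coarse = []
        for i, f in enumerate(feats):
            m = f.mean(axis=0, keepdims=True)
            for _ in range(self.S - 1 - i):
                m = avgpool2(m)
            coarse.append(m[0])
        M = np.stack(coarse).astype(F32)
        sraw = self.spatial.forward(M)
        swc = _sigmoid(sraw)
        self._swc = swc
        outs = []
        self._cw_split, self._sw_up = [], []
        pos = 0
        for i, f in enumerate(feats):
            c = self.channels[i]
            cwi = cw[pos:pos + c].astype(F32)
            pos += c
            sw = swc[i][None]
            for _ in range(self.S - 1 - i):
                sw = upsample2(sw)
            self._cw_split.append(cwi)
            self._sw_up.append(sw)
            outs.append(f * cwi[:, None, None, None] * sw + f)
        return outs

    def backward(self, douts: list[np.ndarray]) -> list[np.ndarray]:
        feats = self._f
        dfeats = []
        dcw_cat = np.zeros_like(self._d)
        dswc = np.zeros((self.S,) + self._swc.shape[1:], dtype=F32)
        pos = 0
        for i, (f, dout) in enumerate(zip(feats, douts)):
            c = self.channels[i]
            cwi = self._cw_split[i]
            sw = self._sw_up[i]
            df = dout * (cwi[:, None, None, None] * sw) + dout
            dcw_cat[pos:pos + c] = (dout * f * sw).sum(axis=(1, 2, 3))
            dsw = (dout * f * cwi[:, None, None, None]).sum(axis=0, keepdims=True)
            for _ in range(self.S - 1 - i):
                dsw = sumpool2(dsw)
            dswc[i] = dsw[0]
            dfeats.append(df)
            pos += c
        # spatial branch
        dsraw = (dswc * self._swc * (1.0 - self._swc)).astype(F32)
        dM = self.spatial.backward(dsraw)
        for i in range(self.S):
            dm = dM[i][None]
            k = self.S - 1 - i
            dm = dm / F32(8 ** k)
            for _ in range(k):
                dm = upsample2(dm)
            dfeats[i] += dm / F32(feats[i].shape[0])
        # channel branch
        da = dcw_cat * self._cw * (1.0 - self._cw)
        self.Wc.g += np.outer(da, self._d)
        self.bc.g += da
        dd = self.Wc.v.T @ da
        pos = 0
        for i, f in enumerate(feats):
            c = self.channels[i]
            dfeats[i] += (dd[pos:pos + c] / F32(self._n[i]))[:, None, None, None]
            pos += c
        return dfeats


class InstanceNorm:
    """Per-channel spatial normalization with learned scale and shift.

    Small segmentation nets train poorly without feature normalization;
    instance norm (statistics over the spatial axes of the single input
    volume) is the standard choice when the batch is one patch.
    """

    def __init__(self, channels: int, eps: float = 1e-5):
        self.g = Param(np.ones(channels))
        self.b = Param(np.zeros(channels))
        self.eps = eps

    def params(self):
        return [self.g, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        C = x.shape[0]
        flat = x.reshape(C, -1)
        mu = flat.mean(axis=1, keepdims=True)
        var = flat.var(axis=1, keepdims=True)
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (flat - mu) * self._istd
        self._shape = x.shape
        y = self.g.v[:, None] * self._xhat + self.b.v[:, None]
        return y.reshape(x.shape).astype(F32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        C = dy.shape[0]
        dyf = dy.reshape(C, -1)
        self.g.g += (dyf * self._xhat).sum(axis=1)
        self.b.g += dyf.sum(axis=1)
        dxhat = self.g.v[:, None] * dyf
        m1 = dxhat.mean(axis=1, keepdims=True)
        m2 = (dxhat * self._xhat).mean(axis=1, keepdims=True)
        dx = self._istd * (dxhat - m1 - self._xhat * m2)
        return dx.reshape(self._shape).astype(F32)


class _ConvBlock:
    """conv3-IN-ReLU-conv3-IN-ReLU."""

    def __init__(self, cin, cout, rng):
        self.c1 = Conv3d(cin, cout, 3, rng)
        self.n1 = InstanceNorm(cout)
        self.r1 = _ReLU()
        self.c2 = Conv3d(cout, cout, 3, rng)
        self.n2 = InstanceNorm(cout)
        self.r2 = _ReLU()

    def params(self):
        return (self.c1.params() + self.n1.params()
                + self.c2.params() + self.n2.params())

    def forward(self, x):
        h = self.r1.forward(self.n1.forward(self.c1.forward(x)))
        return self.r2.forward(self.n2.forward(self.c2.forward(h)))

    def backward(self, dy):
        d = self.c2.backward(self.n2.backward(self.r2.backward(dy)))
        return self.c1.backward(self.n1.backward(self.r1.backward(d)))


class UNet3D:
    """3D U-Net-style encoder-decoder with optional co-attention.

    ``depth`` encoder levels (the last is the bottleneck), channel width
    doubling per level from ``base_width``.  When attention is enabled,
    the co-attention block reweights the skip tensors and the bottleneck
    jointly before decoding.
    """

    def __init__(self, in_channels: int, out_classes: int, depth: int = 2,
                 base_width: int = 4, attention: bool = False, seed: int = 0):
        if depth < 2:
            raise ValueError("depth must be >= 2")
        if out_classes < 2:
            raise ValueError("out_classes must be >= 2")
        if base_width < 4:
            raise ValueError("base_width must be >= 4")
        rng = np.random.default_rng(seed)
        self.in_channels, self.out_classes = in_channels, out_classes
        self.depth, self.base_width = depth, base_width
        self.attention_enabled = attention
        widths = [base_width * 2 ** l for l in range(depth)]
        self.enc = []
        cin = in_channels
        for w in widths:
            self.enc.append(_ConvBlock(cin, w, rng))
            cin = w
        self.dec = [_ConvBlock(widths[l + 1] + widths[l], widths[l], rng)
                    for l in range(depth - 1)]
        self.out = Conv3d(widths[0], out_classes, 1, rng)
        self.coatt = CoAttention(widths, rng) if attention else None

    def params(self) -> list[Param]:
        ps = []
        for b in self.enc + self.dec:
            ps += b.params()
        ps += self.out.params()
        if self.coatt is not None:
            ps += self.coatt.params()
        return ps

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim == 3:
            x = x[None]
        x = x.astype(F32, copy=False)
        div = 2 ** (self.depth - 1)
        if any(s % div for s in x.shape[1:]):
            raise ValueError(f"spatial dims must be divisible by {div}")
        feats = []
        self._pools = []
        h = x
        for l, blk in enumerate(self.enc):
            h = blk.forward(h)
            feats.append(h)
            if l < self.depth - 1:
                h, cache = maxpool2(h)
                self._pools.append(cache)
        if self.coatt is not None:
            feats = self.coatt.forward(feats)
        self._n_feats = len(feats)
        h = feats[-1]
        self._cat_channels = []
        for l in range(self.depth - 2, -1, -1):
            h = upsample2(h)
            self._cat_channels.append((feats[l].shape[0], h.shape[0]))
            h = np.concatenate([feats[l], h], axis=0)
            h = self.dec[l].forward(h)
        return self.out.forward(h)

    def backward(self, dlogits: np.ndarray) -> None:
        dh = self.out.backward(dlogits)
        dfeats = [None] * self._n_feats
        for idx, l in enumerate(range(0, self.depth - 1)):
            dh = self.dec[l].backward(dh)
            c_skip, _ = self._cat_channels[self.depth - 2 - l]
            dskip, dup = dh[:c_skip], dh[c_skip:]
            dfeats[l] = dskip
            dh = sumpool2(dup)  # nearest-upsample backward
        dfeats[self.depth - 1] = dh
        if self.coatt is not None:
            dfeats = self.coatt.backward(dfeats)
        dcur = None
        for l in range(self.depth - 1, -1, -1):
            d = dfeats[l] if dcur is None else dfeats[l] + dcur
            d = self.enc[l].backward(d)
            if l > 0:
                d = maxpool2_back(d, self._pools[l - 1])
            dcur = d

    def zero_grad(self) -> None:
        for p in self.params():
            p.g[:] = 0


def softmax(logits: np.ndarray) -> np.ndarray:
    """Softmax over axis 0 (classes)."""
    z = logits - logits.max(axis=0, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=0, keepdims=True)


def dice_ce_loss(logits: np.ndarray, labels: np.ndarray,
                 w_dice: float = 1.0, w_ce: float = 1.0,
                 eps: float = 1e-5,
                 class_weights: np.ndarray | None = None) -> tuple[float, np.ndarray]:
    """Weighted soft-Dice + cross-entropy loss and its logits gradient.

    ``logits``: (K, *spatial); ``labels``: integer map in 0..K-1.
    ``class_weights`` (K,) scales each voxel's cross-entropy term by the
    weight of its true class — the standard counter to extreme class
    imbalance, where the rarest structures otherwise never leave the
    all-background optimum.  Returns (loss, dlogits).
    """
    if w_dice < 0 or w_ce < 0 or (w_dice == 0 and w_ce == 0):
        raise ValueError("loss weights must be >= 0 and not both zero")
    K = logits.shape[0]
    flat = logits.reshape(K, -1)
    y = labels.reshape(-1)
    N = flat.shape[1]
    p = softmax(flat)
    g = np.zeros_like(p)
    g[y, np.arange(N)] = 1.0
    if class_weights is None:
        vw = np.ones(N, dtype=F32)
    else:
        vw = np.asarray(class_weights, dtype=F32)[y]
    ce = -float(np.mean(vw * np.log(p[y, np.arange(N)] + 1e-12)))
    num = 2.0 * (p * g).sum(axis=1) + eps
    den = p.sum(axis=1) + g.sum(axis=1) + eps
    dice = num / den
    loss = w_ce * ce + w_dice * (1.0 - float(dice.mean()))
    # gradients
    dz = np.zeros_like(p)
    if w_ce:
        dz += w_ce * vw[None, :] * (p - g) / F32(N)
    if w_dice:
        dLdp = -(2.0 * g * den[:, None] - num[:, None]) / (den ** 2)[:, None] / K
        dLdp = (w_dice * dLdp).astype(F32)
        dz += p * (dLdp - (dLdp * p).sum(axis=0, keepdims=True))
    return loss, dz.reshape(logits.shape)


class Adam:
    """Adam optimizer over a parameter list."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p in self.params:
            p.m = self.b1 * p.m + (1 - self.b1) * p.g
            p.s = self.b2 * p.s + (1 - self.b2) * p.g ** 2
            p.v -= (self.lr * (p.m / b1t) / (np.sqrt(p.s / b2t) + self.eps)).astype(F32)
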