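"""Minimal 2D U-Net in numpy: forward, backprop and Adam.

Hand-written so the image-translation recipe (encoder-decoder with skip
connections, ReLU, dropout, MSE loss, whole-batch Adam) runs on a plain
CPU scientific stack.  Arrays are float32 in NCHW layout.  All randomness
(He initialization, dropout masks) flows from one generator, so training
is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np


def _im2col(x: np.ndarray, k: int = 3) -> np.ndarray:
    """(N, C, H, W) -> (N, C*k*k, H*W) patch matrix with same padding."""
    n, c, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    s = xp.strides
    windows = np.lib.stride_tricks.as_strided(
        xp, shape=(n, c, k, k, h, w), strides=(s[0], s[1], s[2], s[3], s[2], s[3]))
    return windows.reshape(n, c * k * k, h * w)


class Conv2d:
    """3x3 (or 1x1) same-padding convolution."""

    def __init__(self, c_in, c_out, k, rng):
        fan_in = c_in * k * k
        self.w = rng.normal(0, np.sqrt(2.0 / fan_in),
                            size=(c_out, c_in * k * k)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k = k
        self.c_in, self.c_out = c_in, c_out

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        n, c, h, w = x.shape
        cols = _im2col(x, self.k)
        out = np.einsum("fp,npq->nfq", self.w, cols, optimize=True)
        out += self.b[None, :, None]
        self._cache = (cols, x.shape)
        return out.reshape(n, self.c_out, h, w)

    def backward(self, dout):
        cols, xshape = self._cache
        n, c, h, w = xshape
        dflat = dout.reshape(n, self.c_out, h * w)
        self.dw = np.einsum("nfq,npq->fp", dflat, cols, optimize=True) / 1.0
        self.db = dflat.sum(axis=(0, 2))
        # dx = conv of dout with the spatially-flipped, transposed kernel
        wk = self.w.reshape(self.c_out, self.c_in, self.k, self.k)
        wt = np.flip(wk, axis=(2, 3)).transpose(1, 0, 2, 3)  # (C_in, C_out, k, k)
        cols_d = _im2col(dout, self.k)
        dx = np.einsum("fp,npq->nfq", wt.reshape(self.c_in, -1), cols_d,
                       optimize=True)
        return dx.reshape(xshape)

    def grads(self):
        return [self.dw, self.db]


class ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Dropout:
    """Inverted dropout; active only when the net is in training mode."""

    def __init__(self, rate):
        self.rate = rate

    def forward(self, x, rng, training):
        if not training or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class MaxPool2x2:
    def forward(self, x):
        n, c, h, w = x.shape
        r = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        r = r.reshape(n, c, h // 2, w // 2, 4)
        self._arg = r.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(r, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        n, c, h, w = self._shape
        dr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dout.dtype)
        np.put_along_axis(dr, self._arg[..., None], dout[..., None], axis=-1)
        dr = dr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dr.reshape(n, c, h, w)


class UpNearest2x:
    def forward(self, x):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout):
        n, c, h, w = dout.shape
        return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class ConvBlock:
    """convs_per_block x (conv3x3 -> ReLU) followed by dropout."""

    def __init__(self, c_in, c_out, n_convs, dropout, rng):
        self.convs, self.relus = [], []
        for i in range(n_convs):
            self.convs.append(Conv2d(c_in if i == 0 else c_out, c_out, 3, rng))
            self.relus.append(ReLU())
        self.drop = Dropout(dropout)

    def forward(self, x, rng, training):
        for conv, relu in zip(self.convs, self.relus):
            x = relu.forward(conv.forward(x))
        return self.drop.forward(x, rng, training)

    def backward(self, dout):
        dout = self.drop.backward(dout)
        for conv, relu in zip(reversed(self.convs), reversed(self.relus)):
            dout = conv.backward(relu.backward(dout))
        return dout

    def layers(self):
        return self.convs


class UNet2D:
    """Encoder-decoder with skip connections and a linear 1x1 output head."""

    def __init__(self, levels=4, base_filters=32, convs_per_block=2,
                 dropout=0.2, seed=0):
        rng = np.random.default_rng(seed)
        self.levels = levels
        self.enc, self.dec, self.upconvs = [], [], []
        ch = [base_filters * 2 ** i for i in range(levels)]
        c_in = 1
        for i in range(levels):
            self.enc.append(ConvBlock(c_in, ch[i], convs_per_block, dropout, rng))
            c_in = ch[i]
        self.pools = [MaxPool2x2() for _ in range(levels - 1)]
        self.ups = [UpNearest2x() for _ in range(levels - 1)]
        for i in range(levels - 2, -1, -1):
            self.upconvs.append(Conv2d(ch[i + 1], ch[i], 3, rng))
            self.dec.append(ConvBlock(2 * ch[i], ch[i], convs_per_block,
                                      dropout, rng))
        self.head = Conv2d(ch[0], 1, 1, rng)
        # start the linear head at water (1/3 in CT-normalized units) so
        # early epochs refine tissue contrast instead of climbing from air
        self.head.b[:] = 1.0 / 3.0
        self._drop_rng = np.random.default_rng([seed, 1])

    # -- plumbing ---------------------------------------------------------
    def _conv_layers(self):
        layers = []
        for block in self.enc + self.dec:
            layers.extend(block.layers())
        layers.extend(self.upconvs)
        layers.append(self.head)
        return layers

    def parameters(self):
        out = []
        for layer in self._conv_layers():
            out.extend(layer.params())
        return out

    def gradients(self):
        out = []
        for layer in self._conv_layers():
            out.extend(layer.grads())
        return out

    def n_weight_layers(self):
        return len(self._conv_layers())

    # -- forward / backward ----------------------------------------------
    def forward(self, x, training=False):
        x = x.astype(np.float32)
        if x.ndim == 3:
            x = x[:, None]
        rng = self._drop_rng
        skips = []
        for i in range(self.levels - 1):
            x = self.enc[i].forward(x, rng, training)
            skips.append(x)
            x = self.pools[i].forward(x)
        x = self.enc[-1].forward(x, rng, training)
        self._skip_channels = []
        for j, i in enumerate(range(self.levels - 2, -1, -1)):
            x = self.ups[j].forward(x)
            x = self.upconvs[j].forward(x)
            self._skip_channels.append(x.shape[1])
            x = np.concatenate([skips[i], x], axis=1)
            x = self.dec[j].forward(x, rng, training)
        return self.head.forward(x)[:, 0]

    def backward(self, dout):
        d = self.head.backward(dout[:, None].astype(np.float32))
        dskips = {}
        for j in range(len(self.dec) - 1, -1, -1):
            i = self.levels - 2 - j
            d = self.dec[j].backward(d)
            c = self._skip_channels[j]
            dskip, d = d[:, :-c], d[:, -c:]
            dskips[i] = dskip
            d = self.ups[j].backward(self.upconvs[j].backward(d))
        d = self.enc[-1].backward(d)
        for i in range(self.levels - 2, -1, -1):
            d = self.pools[i].backward(d)
            d = d + dskips[i]
            d = self.enc[i].backward(d)
        return d


class Adam:
    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
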