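"""Minimal numpy neural-network engine for the dual-head classifier.

Implements exactly what the classifier needs — strided 2-D convolution
via im2col, ReLU, global average pooling, dense layers, inverted
dropout, softmax cross-entropy, and Adam with decoupled L2 weight
decay — in float32, single-process, fully determined by the seeds fed
to it.
"""

from __future__ import annotations

import numpy as np

EPS = 1e-12


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """(N, C, H, W) -> (N, OH, OW, C*kh*kw) patch matrix."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    hp, wp = x.shape[2], x.shape[3]
    oh = (hp - kh) // stride + 1
    ow = (wp - kw) // stride + 1
    sN, sC, sH, sW = x.strides
    patches = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, oh, ow, c, kh, kw),
        strides=(sN, sH * stride, sW * stride, sC, sH, sW),
        writeable=False,
    )
    return patches.reshape(n, oh, ow, c * kh * kw), (n, c, hp, wp, oh, ow)


def conv_forward(x, W, b, stride, pad):
    """W: (F, C, kh, kw).  Returns out (N, F, OH, OW) and a cache."""
    f, c, kh, kw = W.shape
    cols, geom = _im2col(x, kh, kw, stride, pad)
    out = cols @ W.reshape(f, -1).T + b  # (N, OH, OW, F)
    cache = (cols, geom, W.shape, stride, pad)
    return np.ascontiguousarray(out.transpose(0, 3, 1, 2)), cache


def conv_backward_full(dout, cache, W):
    """Gradient wrt weights, bias, and input (col2im scatter)."""
    cols, geom, wshape, stride, pad = cache
    f, c, kh, kw = wshape
    n, _, hp, wp, oh, ow = geom
    dout_h = dout.transpose(0, 2, 3, 1)  # (N, OH, OW, F)
    flat = dout_h.reshape(-1, f)
    dW = (flat.T @ cols.reshape(-1, cols.shape[-1])).reshape(wshape)
    db = flat.sum(axis=0)
    dcols = (flat @ W.reshape(f, -1)).reshape(n, oh, ow, c, kh, kw)
    dxp = np.zeros((n, c, hp, wp), dtype=dout.dtype)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + oh * stride : stride, j : j + ow * stride : stride] += (
                dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            )
    if pad:
        dxp = dxp[:, :, pad:-pad, pad:-pad]
    return dW, db, dxp


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(y_onehot: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Per-sample categorical cross-entropy with a probability floor."""
    return -(y_onehot * np.log(np.clip(p, EPS, None))).sum(axis=-1)


def one_hot(codes: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((len(codes), n_classes), dtype=np.float32)
    out[np.arange(len(codes)), codes] = 1.0
    return out


class Adam:
    """Adam with decoupled L2 weight decay (applied to weight tensors only)."""

    def __init__(self, params: dict, lr=1e-4, weight_decay=5e-4, beta1=0.9, beta2=0.999):
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2 = beta1, beta2
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            update = (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + 1e-8)
            if self.wd and not k.endswith("_b"):
                update = update + self.wd * params[k]
            params[k] -= self.lr * update.astype(params[k].dtype)


class DualHeadNet:
    """Small strided CNN backbone with two parallel softmax heads.

    conv(k5,s4) -> conv(k3,s2) -> conv(k3,s2), ReLU throughout, global
    average pooling, one dense layer, dropout, then two fully connected
    softmax heads (4-class coarse and 7-class fine).
    """

    def __init__(
        self,
        input_shape=(128, 96),
        channels=(16, 32, 64),
        dense_units=128,
        heads=(4, 7),
        dropout_rate=0.8,
        seed=0,
    ):
        self.input_shape = tuple(input_shape)
        self.channels = tuple(channels)
        self.dense_units = dense_units
        self.heads = tuple(heads)
        self.dropout_rate = float(dropout_rate)
        rng = np.random.default_rng(seed)
        c1, c2, c3 = channels

        def he(shape, fan_in):
            return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)

        self.params = {
            "conv1_W": he((c1, 1, 5, 5), 25),
            "conv1_b": np.zeros(c1, dtype=np.float32),
            "conv2_W": he((c2, c1, 3, 3), c1 * 9),
            "conv2_b": np.zeros(c2, dtype=np.float32),
            "conv3_W": he((c3, c2, 3, 3), c2 * 9),
            "conv3_b": np.zeros(c3, dtype=np.float32),
            "fc_W": he((c3, dense_units), c3),
            "fc_b": np.zeros(dense_units, dtype=np.float32),
            "head_c_W": he((dense_units, heads[0]), dense_units),
            "head_c_b": np.zeros(heads[0], dtype=np.float32),
            "head_f_W": he((dense_units, heads[1]), dense_units),
            "head_f_b": np.zeros(heads[1], dtype=np.float32),
        }

    # -- forward -----------------------------------------------------------

    @staticmethod
    def normalize(x: np.ndarray) -> np.ndarray:
        """Per-frame standardization to zero mean, unit variance."""
        x = np.asarray(x, dtype=np.float32)
        flat = x.reshape(x.shape[0], -1)
        mu = flat.mean(axis=1, keepdims=True)
        sd = flat.std(axis=1, keepdims=True)
        sd = np.maximum(sd, 1e-6)
        return ((flat - mu) / sd).reshape(x.shape)

    def forward(self, x, training=False, rng=None):
        """x: (N, H, W) raw depth.  Returns (p_coarse, p_fine, cache)."""
        if x.ndim != 3 or x.shape[1:] != self.input_shape:
            raise ValueError(
                f"input shape {x.shape[1:]} does not match model {self.input_shape}"
            )
        p = self.params
        xn = self.normalize(x)[:, None, :, :]
        z1, c1 = conv_forward(xn, p["conv1_W"], p["conv1_b"], stride=4, pad=2)
        a1 = np.maximum(z1, 0.0)
        z2, c2 = conv_forward(a1, p["conv2_W"], p["conv2_b"], stride=2, pad=1)
        a2 = np.maximum(z2, 0.0)
        z3, c3 = conv_forward(a2, p["conv3_W"], p["conv3_b"], stride=2, pad=1)
        a3 = np.maximum(z3, 0.0)
        g = a3.mean(axis=(2, 3))  # global average pool -> (N, C3)
        zf = g @ p["fc_W"] + p["fc_b"]
        af = np.maximum(zf, 0.0)
        if training and self.dropout_rate > 0:
            if rng is None:
                raise ValueError("training-mode forward requires an rng for dropout")
            keep = 1.0 - self.dropout_rate
            mask = (rng.random(af.shape) < keep).astype(np.float32) / keep
            ad = af * mask
        else:
            mask = None
            ad = af
        logit_c = ad @ p["head_c_W"] + p["head_c_b"]
        logit_f = ad @ p["head_f_W"] + p["head_f_b"]
        pc, pf = softmax(logit_c), softmax(logit_f)
        cache = (xn, z1, c1, a1, z2, c2, a2, z3, c3, a3, g, zf, af, mask, ad, pc, pf)
        return pc, pf, cache

    # -- backward ----------------------------------------------------------

    def backward(self, cache, y_c, y_f):
        """Gradients of mean joint loss (CE_coarse + CE_fine) over the batch."""
        p = self.params
        (xn, z1, c1, a1, z2, c2, a2, z3, c3, a3, g, zf, af, mask, ad, pc, pf) = cache
        n = xn.shape[0]
        dlogit_c = (pc - y_c) / n
        dlogit_f = (pf - y_f) / n
        grads = {
            "head_c_W": ad.T @ dlogit_c,
            "head_c_b": dlogit_c.sum(axis=0),
            "head_f_W": ad.T @ dlogit_f,
            "head_f_b": dlogit_f.sum(axis=0),
        }
        dad = dlogit_c @ p["head_c_W"].T + dlogit_f @ p["head_f_W"].T
        daf = dad * mask if mask is not None else dad
        dzf = daf * (zf > 0)
        grads["fc_W"] = g.T @ dzf
        grads["fc_b"] = dzf.sum(axis=0)
        dg = dzf @ p["fc_W"].T
        da3 = (dg[:, :, None, None] / (a3.shape[2] * a3.shape[3])) * np.ones_like(a3)
        dz3 = da3 * (z3 > 0)
        gW3, gb3, da2 = conv_backward_full(dz3, c3, p["conv3_W"])
        dz2 = da2 * (z2 > 0)
        gW2, gb2, da1 = conv_backward_full(dz2, c2, p["conv2_W"])
        dz1 = da1 * (z1 > 0)
        gW1, gb1, _ = conv_backward_full(dz1, c1, p["conv1_W"])
        grads.update(
            conv1_W=gW1, conv1_b=gb1, conv2_W=gW2, conv2_b=gb2, conv3_W=gW3, conv3_b=gb3
        )
        return grads
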