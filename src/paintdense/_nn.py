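"""Minimal NumPy CNN: layers with manual backprop and an Adam optimizer.

Everything operates on float32 arrays of shape (B, C, H, W). Convolutions are
3x3, stride 1, "same" padding, computed by im2col + matmul so the heavy
lifting lands in BLAS; the gradient w.r.t. the input reuses the forward path
with flipped, channel-transposed kernels (a full correlation). Pooling is
2x2 max with argmax routing; upsampling is 2x nearest-neighbour; the final
depth-to-space (pixel shuffle) turns u^2 channels into a u-times upsampled
single-channel map, which is how the network reaches super-resolution
without ever convolving on the fine grid.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F32 = np.float32


def _im2col3(x: np.ndarray) -> np.ndarray:
    """(B, C, H, W) -> (B, H*W, C*9) patches of the zero-padded input."""
    B, C, H, W = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (B, C, H, W, 3, 3)
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(B, H * W, C * 9)


def conv3x3_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """x (B,C,H,W), W (O,C,3,3), b (O,) -> (out (B,O,H,W), cols cache)."""
    B, C, H, Wd = x.shape
    O = W.shape[0]
    cols = _im2col3(x)
    out = cols @ W.reshape(O, C * 9).T + b
    return out.transpose(0, 2, 1).reshape(B, O, H, Wd), cols


def conv3x3_backward(dout: np.ndarray, cols: np.ndarray, W: np.ndarray,
                     need_dx: bool = True):
    """Gradients of conv3x3: returns (dx, dW, db)."""
    B, O, H, Wd = dout.shape
    C = W.shape[1]
    dr = dout.reshape(B, O, H * Wd).transpose(0, 2, 1)  # (B, HW, O)
    dW = np.einsum("bpo,bpc->oc", dr, cols, optimize=True).reshape(W.shape)
    db = dout.sum(axis=(0, 2, 3))
    dx = None
    if need_dx:
        # dL/dx = full-correlation of dout with flipped, transposed kernels
        Wt = np.ascontiguousarray(W[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
        dx, _ = conv3x3_forward(dout, Wt, np.zeros(C, dtype=W.dtype))
    return dx, dW.astype(W.dtype), db.astype(W.dtype)


def relu_forward(x):
    return np.maximum(x, 0.0), x > 0


def relu_backward(dout, mask):
    return dout * mask


def maxpool2_forward(x: np.ndarray):
    """2x2 max pool, H and W must be even. Returns (out, argmax cache)."""
    B, C, H, W = x.shape
    xr = x.reshape(B, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    flat = np.ascontiguousarray(xr).reshape(B, C, H // 2, W // 2, 4)
    arg = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
    return out, (arg, x.shape)


def maxpool2_backward(dout: np.ndarray, cache):
    arg, (B, C, H, W) = cache
    dflat = np.zeros((B, C, H // 2, W // 2, 4), dtype=dout.dtype)
    np.put_along_axis(dflat, arg[..., None], dout[..., None], axis=-1)
    dx = dflat.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    return np.ascontiguousarray(dx).reshape(B, C, H, W)


def upsample2_forward(x: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)


def upsample2_backward(dout: np.ndarray) -> np.ndarray:
    B, C, H2, W2 = dout.shape
    return dout.reshape(B, C, H2 // 2, 2, W2 // 2, 2).sum(axis=(3, 5))


def pixel_shuffle_forward(x: np.ndarray, u: int) -> np.ndarray:
    """(B, u*u, H, W) -> (B, H*u, W*u); channel c = i*u + j feeds offset (i, j)."""
    B, C, H, W = x.shape
    assert C == u * u
    return np.ascontiguousarray(
        x.reshape(B, u, u, H, W).transpose(0, 3, 1, 4, 2)
    ).reshape(B, H * u, W * u)


def pixel_shuffle_backward(dout: np.ndarray, u: int) -> np.ndarray:
    B, Hu, Wu = dout.shape
    H, W = Hu // u, Wu // u
    return np.ascontiguousarray(
        dout.reshape(B, H, u, W, u).transpose(0, 2, 4, 1, 3)
    ).reshape(B, u * u, H, W)


class Adam:
    """Adam optimizer over a dict of named parameter arrays (in-place steps)."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            m = self.m[k]
            v = self.v[k]
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            self.params[k] -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)


class EncoderDecoder:
    """3-level encoder-decoder with skip connections and pixel-shuffle output.

    Input: (B, 1, H, W) normalized camera counts, H and W divisible by 4.
    Output: (B, H*u, W*u) linear-activation emitter-intensity map (callers
    clip to >= 0 at prediction time). Channel widths are (c, 2c, 4c) for
    ``base_filters`` c; all weights He-initialized from one seed.
    """

    def __init__(self, upsampling: int = 8, base_filters: int = 16, seed: int = 0):
        if upsampling < 2:
            raise ValueError("upsampling must be >= 2")
        self.u = int(upsampling)
        self.base = int(base_filters)
        c1, c2, c3 = self.base, 2 * self.base, 4 * self.base
        rng = np.random.default_rng(seed)

        def he(o, i):
            w = rng.normal(0.0, np.sqrt(2.0 / (i * 9)), size=(o, i, 3, 3))
            return w.astype(F32)

        u2 = self.u * self.u
        self.params = {
            "W1": he(c1, 1), "b1": np.zeros(c1, F32),
            "W2": he(c2, c1), "b2": np.zeros(c2, F32),
            "W3": he(c3, c2), "b3": np.zeros(c3, F32),
            "W4": he(c2, c3 + c2), "b4": np.zeros(c2, F32),
            "W5": he(c1, c2 + c1), "b5": np.zeros(c1, F32),
            "W6": he(u2, c1), "b6": np.zeros(u2, F32),
        }

    def forward(self, x: np.ndarray, need_cache: bool = False):
        """x (B, 1, H, W) -> map (B, H*u, W*u) [, cache]."""
        p = self.params
        cache = {}
        a1, cols1 = conv3x3_forward(x, p["W1"], p["b1"])
        e1, m1 = relu_forward(a1)
        p1, pc1 = maxpool2_forward(e1)
        a2, cols2 = conv3x3_forward(p1, p["W2"], p["b2"])
        e2, m2 = relu_forward(a2)
        p2, pc2 = maxpool2_forward(e2)
        a3, cols3 = conv3x3_forward(p2, p["W3"], p["b3"])
        e3, m3 = relu_forward(a3)
        u2x = upsample2_forward(e3)
        cat2 = np.concatenate([u2x, e2], axis=1)
        a4, cols4 = conv3x3_forward(cat2, p["W4"], p["b4"])
        d2, m4 = relu_forward(a4)
        u1x = upsample2_forward(d2)
        cat1 = np.concatenate([u1x, e1], axis=1)
        a5, cols5 = conv3x3_forward(cat1, p["W5"], p["b5"])
        d1, m5 = relu_forward(a5)
        a6, cols6 = conv3x3_forward(d1, p["W6"], p["b6"])
        out = pixel_shuffle_forward(a6, self.u)
        if not need_cache:
            return out
        cache.update(cols1=cols1, m1=m1, pc1=pc1, cols2=cols2, m2=m2, pc2=pc2,
                     cols3=cols3, m3=m3, cols4=cols4, m4=m4, cols5=cols5, m5=m5,
                     cols6=cols6, ch=(e1.shape[1], e2.shape[1], e3.shape[1]))
        return out, cache

    def backward(self, dmap: np.ndarray, cache: dict) -> dict:
        """dmap (B, H*u, W*u) -> gradients dict matching ``self.params``."""
        p = self.params
        c1n, c2n, c3n = cache["ch"]
        da6 = pixel_shuffle_backward(dmap.astype(F32), self.u)
        dd1, dW6, db6 = conv3x3_backward(da6, cache["cols6"], p["W6"])
        da5 = relu_backward(dd1, cache["m5"])
        dcat1, dW5, db5 = conv3x3_backward(da5, cache["cols5"], p["W5"])
        du1 = dcat1[:, :c2n]
        de1_skip = dcat1[:, c2n:]
        dd2 = upsample2_backward(du1)
        da4 = relu_backward(dd2, cache["m4"])
        dcat2, dW4, db4 = conv3x3_backward(da4, cache["cols4"], p["W4"])
        du2 = dcat2[:, :c3n]
        de2_skip = dcat2[:, c3n:]
        de3 = upsample2_backward(du2)
        da3 = relu_backward(de3, cache["m3"])
        dp2, dW3, db3 = conv3x3_backward(da3, cache["cols3"], p["W3"])
        de2 = maxpool2_backward(dp2, cache["pc2"]) + de2_skip
        da2 = relu_backward(de2, cache["m2"])
        dp1, dW2, db2 = conv3x3_backward(da2, cache["cols2"], p["W2"])
        de1 = maxpool2_backward(dp1, cache["pc1"]) + de1_skip
        da1 = relu_backward(de1, cache["m1"])
        _, dW1, db1 = conv3x3_backward(da1, cache["cols1"], p["W1"], need_dx=False)
        return {"W1": dW1, "b1": db1, "W2": dW2, "b2": db2, "W3": dW3, "b3": db3,
                "W4": dW4, "b4": db4, "W5": dW5, "b5": db5, "W6": dW6, "b6": db6}

    def state_dict(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict) -> None:
        for k in self.params:
            self.params[k] = np.asarray(state[k], dtype=F32)
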