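"""Minimal numpy neural-network core for the 3D blind-spot denoiser.

Implements exactly the pieces the volumetric U-Net needs — 3D convolution
(im2col through BLAS matmul), leaky ReLU, group normalization, window-2 max
pooling, nearest-neighbor upsampling, channel concatenation — each with a
hand-written backward pass, plus an Adam optimizer.  Arrays are
``(batch, channels, z, y, x)`` float32 throughout.

The implementation favors clarity and exact reproducibility over raw speed;
it is fast enough for the desk-scale training configurations this package
uses (seconds per epoch on one CPU).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _pad_spatial(x: np.ndarray, pad: tuple[int, int, int]) -> np.ndarray:
    """Reflect-pad the three spatial axes; size-1 axes fall back to edge."""
    widths = [(0, 0), (0, 0)] + [(p, p) for p in pad]
    # np.pad 'reflect' needs length >= 2 on the padded axis
    if all(x.shape[2 + i] >= 2 or pad[i] == 0 for i in range(3)):
        return np.pad(x, widths, mode="reflect")
    out = x
    for i in range(3):
        if pad[i] == 0:
            continue
        w = [(0, 0)] * out.ndim
        w[2 + i] = (pad[i], pad[i])
        mode = "reflect" if out.shape[2 + i] >= 2 else "edge"
        out = np.pad(out, w, mode=mode)
    return out


def _fold_pad_grad(gpad: np.ndarray, pad: tuple[int, int, int]) -> np.ndarray:
    """Adjoint of :func:`_pad_spatial` (fold pad gradients back inside)."""
    g = gpad
    for i in range(3):
        p = pad[i]
        if p == 0:
            continue
        ax = 2 + i
        n = g.shape[ax] - 2 * p
        sl = [slice(None)] * g.ndim

        def take(j):
            sl2 = list(sl)
            sl2[ax] = j
            return g[tuple(sl2)]

        core_sl = list(sl)
        core_sl[ax] = slice(p, p + n)
        core = g[tuple(core_sl)].copy()
        for k in range(p):
            # pad slot k mirrors interior index p-k (reflect) or 0 (edge)
            src = p - k if n >= 2 else 0
            dst_lo = min(src, n - 1)
            idx = list(sl)
            idx[ax] = dst_lo
            core[tuple(idx)] += take(k)
            src_hi = n - 1 - (p - k) if n >= 2 else 0
            idx[ax] = max(src_hi, 0)
            core[tuple(idx)] += take(g.shape[ax] - 1 - k)
        g = core
    return g


class Conv3d:
    """Same-size 3D convolution with reflect padding."""

    def __init__(self, in_ch: int, out_ch: int, kernel=(3, 3, 3),
                 rng: np.random.Generator | None = None, name: str = "conv"):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel = tuple(kernel)
        kvol = int(np.prod(self.kernel))
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * kvol
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, fan_in))
        self.params = {"w": w.astype(np.float32),
                       "b": np.zeros(out_ch, dtype=np.float32)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.name = name
        self._cache = None

    @property
    def n_params(self) -> int:
        return sum(v.size for v in self.params.values())

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        pad = tuple(k // 2 for k in self.kernel)
        xp = _pad_spatial(x, pad)
        win = sliding_window_view(xp, self.kernel, axis=(2, 3, 4))
        # (N, C, D, H, W, kz, ky, kx) -> (N*D*H*W, C*kvol)
        n, c, d, h, w_ = win.shape[:5]
        col = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(
            n * d * h * w_, c * int(np.prod(self.kernel)))
        return np.ascontiguousarray(col, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, _, d, h, w_ = x.shape
        col = self._im2col(x)
        out = col @ self.params["w"].T + self.params["b"]
        self._cache = (x.shape, col)
        return np.ascontiguousarray(
            out.reshape(n, d, h, w_, self.out_ch).transpose(0, 4, 1, 2, 3))

    def backward(self, gout: np.ndarray) -> np.ndarray:
        x_shape, col = self._cache
        n, _, d, h, w_ = x_shape
        g2 = gout.transpose(0, 2, 3, 4, 1).reshape(-1, self.out_ch)
        self.grads["w"] += (g2.T @ col).astype(np.float32)
        self.grads["b"] += g2.sum(axis=0).astype(np.float32)
        dcol = (g2 @ self.params["w"]).reshape(
            n, d, h, w_, self.in_ch, *self.kernel)
        pad = tuple(k // 2 for k in self.kernel)
        gpad = np.zeros((n, self.in_ch, d + 2 * pad[0], h + 2 * pad[1],
                         w_ + 2 * pad[2]), dtype=np.float32)
        dcol = dcol.transpose(0, 4, 1, 2, 3, 5, 6, 7)
        for kz in range(self.kernel[0]):
            for ky in range(self.kernel[1]):
                for kx in range(self.kernel[2]):
                    gpad[:, :, kz:kz + d, ky:ky + h, kx:kx + w_] += \
                        dcol[..., kz, ky, kx]
        self._cache = None
        return _fold_pad_grad(gpad, pad)


class LeakyReLU:
    def __init__(self, slope: float = 0.01):
        self.slope = slope
        self.params, self.grads = {}, {}
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        g = np.where(self._mask, gout, self.slope * gout)
        self._mask = None
        return g


class GroupNorm:
    def __init__(self, channels: int, groups: int = 8, eps: float = 1e-5,
                 name: str = "gn"):
        groups = min(groups, channels)
        while channels % groups != 0:
            groups -= 1
        self.c, self.g, self.eps = channels, groups, eps
        self.params = {"gamma": np.ones(channels, dtype=np.float32),
                       "beta": np.zeros(channels, dtype=np.float32)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.name = name
        self._cache = None

    @property
    def n_params(self) -> int:
        return 2 * self.c

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, d, h, w = x.shape
        xg = x.reshape(n, self.g, -1)
        mu = xg.mean(axis=2, keepdims=True)
        var = xg.var(axis=2, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = ((xg - mu) * inv).reshape(x.shape)
        self._cache = (xhat, inv)
        gamma = self.params["gamma"].reshape(1, c, 1, 1, 1)
        beta = self.params["beta"].reshape(1, c, 1, 1, 1)
        return gamma * xhat + beta

    def backward(self, gout: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        n, c = gout.shape[:2]
        self.grads["gamma"] += (gout * xhat).sum(axis=(0, 2, 3, 4))
        self.grads["beta"] += gout.sum(axis=(0, 2, 3, 4))
        gamma = self.params["gamma"].reshape(1, c, 1, 1, 1)
        dxhat = (gout * gamma).reshape(n, self.g, -1)
        xh = xhat.reshape(n, self.g, -1)
        m = dxhat.shape[2]
        dx = inv * (dxhat - dxhat.mean(axis=2, keepdims=True)
                    - xh * (dxhat * xh).mean(axis=2, keepdims=True))
        self._cache = None
        return dx.reshape(gout.shape).astype(np.float32)


class MaxPool:
    """Window-2 max pooling with per-axis factors in {1, 2}."""

    def __init__(self, factors: tuple[int, int, int]):
        self.f = tuple(factors)
        self.params, self.grads = {}, {}
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, d, h, w = x.shape
        fz, fy, fx = self.f
        r = x.reshape(n, c, d // fz, fz, h // fy, fy, w // fx, fx)
        r = r.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(
            n, c, d // fz, h // fy, w // fx, fz * fy * fx)
        idx = r.argmax(axis=-1)
        out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
        self._cache = (x.shape, idx)
        return np.ascontiguousarray(out)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        x_shape, idx = self._cache
        n, c, d, h, w = x_shape
        fz, fy, fx = self.f
        g = np.zeros((n, c, d // fz, h // fy, w // fx, fz * fy * fx),
                     dtype=np.float32)
        np.put_along_axis(g, idx[..., None], gout[..., None], axis=-1)
        g = g.reshape(n, c, d // fz, h // fy, w // fx, fz, fy, fx)
        g = g.transpose(0, 1, 2, 5, 3, 6, 4, 7).reshape(x_shape)
        self._cache = None
        return np.ascontiguousarray(g)


class Upsample:
    """Nearest-neighbor upsampling by per-axis integer factors."""

    def __init__(self, factors: tuple[int, int, int]):
        self.f = tuple(factors)
        self.params, self.grads = {}, {}

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = x
        for ax, f in zip((2, 3, 4), self.f):
            if f > 1:
                out = np.repeat(out, f, axis=ax)
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        n, c, d, h, w = gout.shape
        fz, fy, fx = self.f
        g = gout.reshape(n, c, d // fz, fz, h // fy, fy, w // fx, fx)
        return g.sum(axis=(3, 5, 7))


class Adam:
    """Adam optimizer over a flat name->array parameter mapping."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.5, 0.99), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.betas
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
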