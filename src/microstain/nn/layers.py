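"""Layers: forward/backward pairs over float32 NHWC arrays."""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


class Param:
    """A learnable array with an accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def truncated_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Normal(0, std) samples re-drawn until within 2 std (seeded init)."""
    out = rng.normal(0.0, std, size=shape)
    bad = np.abs(out) > 2 * std
    while np.any(bad):
        out[bad] = rng.normal(0.0, std, size=int(bad.sum()))
        bad = np.abs(out) > 2 * std
    return out.astype(DTYPE)


# below this many input channels the one-shot im2col GEMM wins; above it,
# k*k shifted GEMMs on near-contiguous slices avoid the large gather copy
_IM2COL_MAX_CIN = 16


def _pad_same(x: np.ndarray, k: int) -> np.ndarray:
    p = k // 2
    return np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))


def _im2col(xp: np.ndarray, k: int, shape) -> np.ndarray:
    """padded (N, Hp, Wp, Cin) -> (N*H*W, k*k*Cin) patch matrix."""
    n, h, w, cin = shape
    win = sliding_window_view(xp, (k, k), axis=(1, 2))  # (N,H,W,Cin,k,k)
    win = win.transpose(0, 1, 2, 4, 5, 3)  # (N,H,W,k,k,Cin)
    return np.ascontiguousarray(win).reshape(n * h * w, k * k * cin)


def _conv_same(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Stride-1 cross-correlation with same padding.

    x: (N, H, W, Cin); w: (k, k, Cin, Cout) -> (N, H, W, Cout)
    """
    k, _, cin, cout = w.shape
    n, h, wd, _ = x.shape
    xp = _pad_same(x, k)
    if cin <= _IM2COL_MAX_CIN:
        cols = _im2col(xp, k, x.shape)
        return (cols @ w.reshape(k * k * cin, cout)).reshape(n, h, wd, cout)
    ym: np.ndarray | None = None
    for a in range(k):
        for b in range(k):
            xa = np.ascontiguousarray(xp[:, a : a + h, b : b + wd, :]).reshape(-1, cin)
            t = xa @ w[a, b]
            ym = t if ym is None else ym + t
    return ym.reshape(n, h, wd, cout)


class Conv2D:
    """3x3 (or kxk) same-padding convolution, optional stride 2.

    Stride 2 is realised as the stride-1 result subsampled on even pixels,
    which for even input sizes matches 'same' downsampling exactly.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int = 3,
        stride: int = 1,
        rng: np.random.Generator | None = None,
        name: str = "conv",
    ) -> None:
        if stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")
        rng = rng or np.random.default_rng()
        self.stride = stride
        self.w = Param(
            truncated_normal(rng, (kernel, kernel, in_channels, out_channels)),
            name=f"{name}.w",
        )
        self.b = Param(np.zeros(out_channels), name=f"{name}.b")
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        k = self.w.value.shape[0]
        self._xp = _pad_same(x, k)
        cin = x.shape[3]
        n, h, wd, _ = x.shape
        if cin <= _IM2COL_MAX_CIN:
            self._cols = _im2col(self._xp, k, x.shape)
            y = (self._cols @ self.w.value.reshape(k * k * cin, -1)).reshape(
                n, h, wd, -1
            )
        else:
            self._cols = None
            y = _conv_same(x, self.w.value)
        y = y + self.b.value
        if self.stride == 2:
            y = y[:, ::2, ::2, :]
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h, w, cin = self._shape
        if self.stride == 2:
            full = np.zeros((n, h, w, grad.shape[3]), dtype=DTYPE)
            full[:, ::2, ::2, :] = grad
            grad = full
        k = self.w.value.shape[0]
        cout = grad.shape[3]
        gm = grad.reshape(n * h * w, cout)
        if self._cols is not None:
            self.w.grad += (self._cols.T @ gm).reshape(k, k, cin, cout)
        else:
            for a in range(k):
                for b in range(k):
                    xa = np.ascontiguousarray(
                        self._xp[:, a : a + h, b : b + w, :]
                    ).reshape(-1, cin)
                    self.w.grad[a, b] += xa.T @ gm
        self.b.grad += gm.sum(axis=0)
        w_flip = np.ascontiguousarray(self.w.value[::-1, ::-1].transpose(0, 1, 3, 2))
        return _conv_same(grad, w_flip)


def leaky_relu(x, slope: float = 0.1):
    """LeakyReLU(x) = x for x > 0, slope*x otherwise."""
    x = np.asarray(x)
    return np.where(x > 0, x, slope * x)


class LeakyReLU:
    def __init__(self, slope: float = 0.1) -> None:
        self.slope = slope
        self._mask: np.ndarray | None = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x).astype(DTYPE)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, self.slope * grad).astype(DTYPE)


class AvgPool2:
    """2x2 average pooling, stride 2 (input sizes must be even)."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        self._shape = x.shape
        return x.reshape(n, h // 2, 2, w // 2, 2, c).mean(axis=(2, 4))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        out = np.repeat(np.repeat(grad, 2, axis=1), 2, axis=2) * DTYPE(0.25)
        return out.astype(DTYPE)


class BilinearUp2:
    """Bilinear 2x upsampling as a fixed linear operator (exact transpose).

    Output sample i maps to source coordinate (i + 0.5)/2 - 0.5 with edge
    clamping (half-pixel-centred convention).
    """

    _cache: dict[int, np.ndarray] = {}

    @classmethod
    def _matrix(cls, n: int) -> np.ndarray:
        u = cls._cache.get(n)
        if u is None:
            u = np.zeros((2 * n, n), dtype=DTYPE)
            for i in range(2 * n):
                src = (i + 0.5) / 2.0 - 0.5
                lo = int(np.floor(src))
                frac = src - lo
                lo_c = min(max(lo, 0), n - 1)
                hi_c = min(max(lo + 1, 0), n - 1)
                u[i, lo_c] += 1.0 - frac
                u[i, hi_c] += frac
            cls._cache[n] = u
        return u

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        _, h, w, _ = x.shape
        self._hw = (h, w)
        uh = self._matrix(h)
        uw = self._matrix(w)
        y = np.einsum("ph,nhwc->npwc", uh, x, optimize=True)
        return np.einsum("qw,npwc->npqc", uw, y, optimize=True).astype(DTYPE)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        h, w = self._hw
        uh = self._matrix(h)
        uw = self._matrix(w)
        g = np.einsum("qw,npqc->npwc", uw, grad, optimize=True)
        return np.einsum("ph,npwc->nhwc", uh, g, optimize=True).astype(DTYPE)


class Flatten:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense:
    def __init__(
        self,
        in_features: int,
        out_features: int,
        rng: np.random.Generator | None = None,
        name: str = "dense",
    ) -> None:
        rng = rng or np.random.default_rng()
        self.w = Param(truncated_normal(rng, (in_features, out_features)), name=f"{name}.w")
        self.b = Param(np.zeros(out_features), name=f"{name}.b")

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.w.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.w.value.T


class Sigmoid:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-x.astype(np.float64)))
        return self._y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return (grad * self._y * (1.0 - self._y)).astype(DTYPE)
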