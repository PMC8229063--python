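"""Minimal CNN building blocks on numpy with explicit forward/backward passes.

Every layer caches what its backward pass needs only when ``train=True``;
inference-mode forwards are cache-free and therefore cheap on memory.
Parameters are held in :class:`Parameter` objects so optimizers can update
them in place.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Parameter",
    "Module",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "AvgPool2d",
    "GlobalAvgPool",
    "Flatten",
    "Linear",
    "Sequential",
]


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = "") -> None:
        self.data = data
        self.grad = np.zeros_like(data)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Module:
    """Base class: a module owns parameters and child modules."""

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        for value in self.__dict__.values():
            if isinstance(value, Parameter):
                out.append(value)
            elif isinstance(value, Module):
                out.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def modules(self) -> list["Module"]:
        out: list[Module] = [self]
        for value in self.__dict__.values():
            if isinstance(value, Module):
                out.extend(value.modules())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        out.extend(item.modules())
        return out

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.forward(x, train=train)

    # --- weight (de)serialization -------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        self._collect_state(state, "")
        return state

    def _collect_state(self, state: dict[str, np.ndarray], prefix: str) -> None:
        for key, value in self.__dict__.items():
            if isinstance(value, Parameter):
                state[prefix + key] = value.data
            elif isinstance(value, np.ndarray) and key.startswith("running_"):
                state[prefix + key] = value
            elif isinstance(value, Module):
                value._collect_state(state, f"{prefix}{key}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        item._collect_state(state, f"{prefix}{key}.{i}.")

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = self.state_dict()
        missing = set(own) - set(state)
        if missing:
            raise ValueError(f"missing weights for: {sorted(missing)[:5]} ...")
        self._assign_state(state, "")

    def _assign_state(self, state: dict[str, np.ndarray], prefix: str) -> None:
        for key, value in self.__dict__.items():
            if isinstance(value, Parameter):
                value.data[...] = state[prefix + key]
            elif isinstance(value, np.ndarray) and key.startswith("running_"):
                value[...] = state[prefix + key]
            elif isinstance(value, Module):
                value._assign_state(state, f"{prefix}{key}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        item._assign_state(state, f"{prefix}{key}.{i}.")


def _im2col(x: np.ndarray, kh: int, kw: int, sh: int, sw: int, ph: int, pw: int,
            pad_value: float = 0.0):
    """Unfold (N,C,H,W) into a (N*Ho*Wo, C*kh*kw) patch matrix."""
    n, c, h, w = x.shape
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)),
                   constant_values=pad_value)
    ho = (x.shape[2] - kh) // sh + 1
    wo = (x.shape[3] - kw) // sw + 1
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))[:, :, ::sh, ::sw]
    col = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)
    return col, ho, wo


def _col2im(dcol: np.ndarray, x_shape, kh, kw, sh, sw, ph, pw) -> np.ndarray:
    """Adjoint of :func:`_im2col` (scatter-add patches back)."""
    n, c, h, w = x_shape
    hp, wp = h + 2 * ph, w + 2 * pw
    ho = (hp - kh) // sh + 1
    wo = (wp - kw) // sw + 1
    dcol = dcol.reshape(n, ho, wo, c, kh, kw).transpose(0, 3, 1, 2, 4, 5)
    dxp = np.zeros((n, c, hp, wp), dtype=dcol.dtype)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i:i + sh * ho:sh, j:j + sw * wo:sw] += dcol[:, :, :, :, i, j]
    if ph or pw:
        dxp = dxp[:, :, ph:hp - ph, pw:wp - pw]
    return dxp


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int = 0, bias: bool = False, *,
                 rng: np.random.Generator, dtype=np.float32) -> None:
        fan_in = in_ch * kernel * kernel
        std = np.sqrt(2.0 / fan_in)  # He initialization for ReLU nets
        w = rng.normal(0.0, std, size=(out_ch, in_ch, kernel, kernel))
        self.weight = Parameter(w.astype(dtype), "conv.weight")
        self.bias = Parameter(np.zeros(out_ch, dtype=dtype), "conv.bias") if bias else None
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride, self.padding = kernel, stride, padding
        self._cache = None

    def forward(self, x, train=False):
        k, s, p = self.kernel, self.stride, self.padding
        col, ho, wo = _im2col(x, k, k, s, s, p, p)
        wmat = self.weight.data.reshape(self.out_ch, -1)
        y = col @ wmat.T
        if self.bias is not None:
            y += self.bias.data
        n = x.shape[0]
        y = np.ascontiguousarray(
            y.reshape(n, ho, wo, self.out_ch).transpose(0, 3, 1, 2))
        self._cache = (col, x.shape) if train else None
        return y

    def backward(self, dy):
        col, x_shape = self._cache
        n, _, ho, wo = dy.shape
        dym = dy.transpose(0, 2, 3, 1).reshape(n * ho * wo, self.out_ch)
        wmat = self.weight.data.reshape(self.out_ch, -1)
        self.weight.grad += (dym.T @ col).reshape(self.weight.data.shape)
        if self.bias is not None:
            self.bias.grad += dym.sum(axis=0)
        dcol = dym @ wmat
        k, s, p = self.kernel, self.stride, self.padding
        self._cache = None
        return _col2im(dcol, x_shape, k, k, s, s, p, p)


class BatchNorm2d(Module):
    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5, *,
                 dtype=np.float32) -> None:
        self.gamma = Parameter(np.ones(ch, dtype=dtype), "bn.gamma")
        self.beta = Parameter(np.zeros(ch, dtype=dtype), "bn.beta")
        self.running_mean = np.zeros(ch, dtype=dtype)
        self.running_var = np.ones(ch, dtype=dtype)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def forward(self, x, train=False):
        c = x.shape[1]
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(x.dtype)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(x.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(1, c, 1, 1)) * invstd.reshape(1, c, 1, 1)
        y = self.gamma.data.reshape(1, c, 1, 1) * xhat + self.beta.data.reshape(1, c, 1, 1)
        self._cache = (xhat, invstd) if train else None
        return y

    def backward(self, dy):
        xhat, invstd = self._cache
        n, c, h, w = dy.shape
        m = n * h * w
        dbeta = dy.sum(axis=(0, 2, 3))
        dgamma = (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dbeta
        self.gamma.grad += dgamma
        g = self.gamma.data.reshape(1, c, 1, 1) * invstd.reshape(1, c, 1, 1)
        dx = g * (dy - (dbeta.reshape(1, c, 1, 1) + xhat * dgamma.reshape(1, c, 1, 1)) / m)
        self._cache = None
        return dx


class ReLU(Module):
    def __init__(self) -> None:
        self._mask = None

    def forward(self, x, train=False):
        y = np.maximum(x, 0.0)
        self._mask = x > 0 if train else None
        return y

    def backward(self, dy):
        dx = dy * self._mask
        self._mask = None
        return dx


class MaxPool2d(Module):
    def __init__(self, kernel: int, stride: int, padding: int = 0) -> None:
        self.kernel, self.stride, self.padding = kernel, stride, padding
        self._cache = None

    def forward(self, x, train=False):
        k, s, p = self.kernel, self.stride, self.padding
        col, ho, wo = _im2col(x, k, k, s, s, p, p, pad_value=-np.inf)
        n, c = x.shape[0], x.shape[1]
        # col rows are (n*ho*wo, c*k*k); regroup per channel before the max
        col = col.reshape(n * ho * wo, c, k * k)
        idx = col.argmax(axis=2)
        y = np.take_along_axis(col, idx[:, :, None], axis=2)[:, :, 0]
        y = np.ascontiguousarray(y.reshape(n, ho, wo, c).transpose(0, 3, 1, 2))
        self._cache = (idx, x.shape) if train else None
        return y

    def backward(self, dy):
        idx, x_shape = self._cache
        k, s, p = self.kernel, self.stride, self.padding
        n, c, ho, wo = dy.shape
        dcol = np.zeros((n * ho * wo, c, k * k), dtype=dy.dtype)
        dym = dy.transpose(0, 2, 3, 1).reshape(n * ho * wo, c)
        np.put_along_axis(dcol, idx[:, :, None], dym[:, :, None], axis=2)
        self._cache = None
        return _col2im(dcol.reshape(n * ho * wo, c * k * k), x_shape, k, k, s, s, p, p)


class AvgPool2d(Module):
    def __init__(self, kernel: int, stride: int) -> None:
        self.kernel, self.stride = kernel, stride
        self._cache = None

    def forward(self, x, train=False):
        k, s = self.kernel, self.stride
        win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        y = win.mean(axis=(4, 5))
        self._cache = x.shape if train else None
        return np.ascontiguousarray(y)

    def backward(self, dy):
        x_shape = self._cache
        k, s = self.kernel, self.stride
        n, c, ho, wo = dy.shape
        dcol = np.broadcast_to(
            (dy / (k * k)).transpose(0, 2, 3, 1).reshape(n * ho * wo, c, 1),
            (n * ho * wo, c, k * k)).reshape(n * ho * wo, c * k * k)
        self._cache = None
        return _col2im(np.ascontiguousarray(dcol), x_shape, k, k, s, s, 0, 0)


class GlobalAvgPool(Module):
    """Spatial mean over the full feature map -> flat (N, C) vector."""

    def __init__(self) -> None:
        self._shape = None

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None] / (h * w), (n, c, h, w)).astype(dy.dtype)


class Flatten(Module):
    def __init__(self) -> None:
        self._shape = None

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, *, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        std = np.sqrt(2.0 / in_dim)
        self.weight = Parameter(rng.normal(0.0, std, size=(out_dim, in_dim)).astype(dtype),
                                "linear.weight")
        self.bias = Parameter(np.zeros(out_dim, dtype=dtype), "linear.bias")
        self._x = None

    def forward(self, x, train=False):
        self._x = x if train else None
        return x @ self.weight.data.T + self.bias.data

    def backward(self, dy):
        self.weight.grad += dy.T @ self._x
        self.bias.grad += dy.sum(axis=0)
        dx = dy @ self.weight.data
        self._x = None
        return dx


class Sequential(Module):
    def __init__(self, *layers: Module) -> None:
        self.layers = list(layers)

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer(x, train=train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy
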