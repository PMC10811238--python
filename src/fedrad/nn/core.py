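"""Minimal reverse-mode neural-network engine on numpy.

Every layer is a :class:`Module` caching whatever its backward pass needs
during ``forward``.  ``backward(grad_out)`` accumulates parameter gradients
into ``module.grads`` and returns the gradient with respect to the input.
Shapes follow the NCHW convention for images.

The engine is deliberately small: only the layers required by the federated
pipeline (convolutions, linear maps, CBAM attention gates, pooling,
upsampling, the usual activations) are provided, and all randomness flows
through an explicit ``numpy.random.Generator``.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

__all__ = [
    "Module",
    "Sequential",
    "Conv2d",
    "Linear",
    "ReLU",
    "LeakyReLU",
    "Sigmoid",
    "Tanh",
    "GlobalAvgPool",
    "Flatten",
    "Reshape",
    "Upsample2x",
]


class Module:
    """Base class: a tree of named children plus named parameter arrays."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.children: dict[str, "Module"] = {}
        # When True, Conv2d stores `last_output` / `last_grad_out` so the
        # radiomics stage can harvest feature maps and class-attention maps.
        self.capture: bool = False

    # -- registration -----------------------------------------------------
    def add_param(self, name: str, value: np.ndarray) -> None:
        self.params[name] = value
        self.grads[name] = np.zeros_like(value)

    def add_child(self, name: str, module: "Module") -> "Module":
        self.children[name] = module
        return module

    # -- traversal --------------------------------------------------------
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name in self.params:
            yield (prefix + name, self.params[name])
        for cname, child in self.children.items():
            yield from child.named_parameters(prefix + cname + ".")

    def named_modules(self, prefix: str = "") -> Iterator[tuple[str, "Module"]]:
        yield (prefix.rstrip("."), self)
        for cname, child in self.children.items():
            yield from child.named_modules(prefix + cname + ".")

    def zero_grad(self) -> None:
        for name, g in self.grads.items():
            g[...] = 0.0
        for child in self.children.values():
            child.zero_grad()

    def set_capture(self, flag: bool) -> None:
        for _, m in self.named_modules():
            m.capture = flag

    def n_parameters(self) -> int:
        return sum(p.size for _, p in self.named_parameters())

    # -- compute ----------------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


class Sequential(Module):
    def __init__(self, *modules: Module) -> None:
        super().__init__()
        self.order: list[str] = []
        for i, m in enumerate(modules):
            name = f"m{i}"
            self.add_child(name, m)
            self.order.append(name)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for name in self.order:
            x = self.children[name].forward(x)
        return x

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        for name in reversed(self.order):
            grad_out = self.children[name].backward(grad_out)
        return grad_out


# ---------------------------------------------------------------------------
# im2col helpers


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (h + 2 * pad - k) // stride + 1
    ow = (w + 2 * pad - k) // stride + 1
    cols = np.empty((n, c, k, k, oh, ow), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = x[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride]
    return cols.reshape(n, c * k * k, oh * ow), (oh, ow)


def _col2im(cols: np.ndarray, x_shape, k: int, stride: int, pad: int, oh: int, ow: int) -> np.ndarray:
    n, c, h, w = x_shape
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    cols = cols.reshape(n, c, k, k, oh, ow)
    for i in range(k):
        for j in range(k):
            xp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += cols[:, :, i, j]
    if pad:
        return xp[:, :, pad : pad + h, pad : pad + w]
    return xp


class Conv2d(Module):
    """2-D convolution (cross-correlation), He-normal initialised."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        stride: int = 1,
        padding: int | None = None,
        init_scale: float | None = None,
    ) -> None:
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.k = kernel_size
        self.stride = stride
        self.padding = kernel_size // 2 if padding is None else padding
        fan_in = in_channels * kernel_size * kernel_size
        scale = init_scale if init_scale is not None else np.sqrt(2.0 / fan_in)
        w = rng.normal(0.0, scale, size=(out_channels, in_channels, kernel_size, kernel_size))
        self.add_param("weight", w.astype(np.float64))
        self.add_param("bias", np.zeros(out_channels))
        self.last_output: np.ndarray | None = None
        self.last_grad_out: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols, (oh, ow) = _im2col(x, self.k, self.stride, self.padding)
        self._cache = (cols, x.shape, oh, ow)
        wmat = self.params["weight"].reshape(self.out_channels, -1)
        out = np.matmul(wmat, cols)
        out += self.params["bias"][None, :, None]
        out = out.reshape(x.shape[0], self.out_channels, oh, ow)
        if self.capture:
            self.last_output = out
        return out

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        cols, x_shape, oh, ow = self._cache
        if self.capture:
            self.last_grad_out = grad_out
        n = grad_out.shape[0]
        g = grad_out.reshape(n, self.out_channels, oh * ow)
        wmat = self.params["weight"].reshape(self.out_channels, -1)
        g2 = g.transpose(1, 0, 2).reshape(self.out_channels, -1)
        c2 = cols.transpose(1, 0, 2).reshape(cols.shape[1], -1)
        self.grads["weight"] += (g2 @ c2.T).reshape(self.params["weight"].shape)
        self.grads["bias"] += g.sum(axis=(0, 2))
        dcols = np.matmul(wmat.T, g)
        return _col2im(dcols, x_shape, self.k, self.stride, self.padding, oh, ow)


class Linear(Module):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        rng: np.random.Generator,
        init_scale: float | None = None,
    ) -> None:
        super().__init__()
        scale = init_scale if init_scale is not None else np.sqrt(2.0 / in_features)
        self.add_param("weight", rng.normal(0.0, scale, size=(out_features, in_features)))
        self.add_param("bias", np.zeros(out_features))

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["weight"].T + self.params["bias"]

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        self.grads["weight"] += grad_out.T @ self._x
        self.grads["bias"] += grad_out.sum(axis=0)
        return grad_out @ self.params["weight"]


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return grad_out * self._mask


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2) -> None:
        super().__init__()
        self.slope = slope

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad_out, self.slope * grad_out)


class Sigmoid(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._y

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return grad_out * self._y * (1.0 - self._y)


class Tanh(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = np.tanh(x)
        return self._y

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return grad_out * (1.0 - self._y**2)


class GlobalAvgPool(Module):
    """(N, C, H, W) -> (N, C) spatial mean."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(grad_out[:, :, None, None], self._shape) / (h * w)


class Flatten(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return grad_out.reshape(self._shape)


class Reshape(Module):
    def __init__(self, shape: tuple[int, ...]) -> None:
        super().__init__()
        self.shape = shape

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return grad_out.reshape(self._in_shape)


class Upsample2x(Module):
    """Nearest-neighbour 2x spatial upsampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        n, c, h, w = grad_out.shape
        return grad_out.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))
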