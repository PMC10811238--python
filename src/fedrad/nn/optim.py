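"""Optimizers operating in place on a Module's parameter/gradient dicts."""

from __future__ import annotations

import numpy as np

from .core import Module

__all__ = ["SGD", "RMSprop"]


class _Optimizer:
    def __init__(self, model: Module) -> None:
        self.model = model
        self._slots: dict[int, dict[str, np.ndarray]] = {}

    def _slot(self, module: Module, name: str, like: np.ndarray) -> np.ndarray:
        key = id(module)
        d = self._slots.setdefault(key, {})
        if name not in d:
            d[name] = np.zeros_like(like)
        return d[name]

    def step(self) -> None:
        for _, module in self.model.named_modules():
            for name, p in module.params.items():
                self._update(module, name, p, module.grads[name])

    def _update(self, module, name, p, g) -> None:  # pragma: no cover
        raise NotImplementedError


class SGD(_Optimizer):
    def __init__(self, model: Module, lr: float, momentum: float = 0.9) -> None:
        super().__init__(model)
        self.lr = lr
        self.momentum = momentum

    def _update(self, module, name, p, g) -> None:
        v = self._slot(module, name, p)
        v *= self.momentum
        v += g
        p -= self.lr * v


class RMSprop(_Optimizer):
    """The optimizer recommended for weight-clipped Wasserstein critics."""

    def __init__(self, model: Module, lr: float, decay: float = 0.9, eps: float = 1e-8) -> None:
        super().__init__(model)
        self.lr = lr
        self.decay = decay
        self.eps = eps

    def _update(self, module, name, p, g) -> None:
        s = self._slot(module, name, p)
        s *= self.decay
        s += (1.0 - self.decay) * g * g
        p -= self.lr * g / (np.sqrt(s) + self.eps)
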