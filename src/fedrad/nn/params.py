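"""Flattened parameter vectors — the unit exchanged between federation clients."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Module

__all__ = ["ParameterVector", "pack_parameters", "unpack_parameters"]


@dataclass(frozen=True)
class ParameterVector:
    """All trainable parameters of a model, flattened in traversal order.

    ``layout`` maps each parameter's qualified name to ``(offset, size,
    shape)`` so that pack -> unpack -> pack is lossless and two clients built
    from the same configuration share an identical layout.
    """

    values: np.ndarray
    layout: tuple[tuple[str, int, int, tuple[int, ...]], ...]

    @property
    def size(self) -> int:
        return int(self.values.size)

    def segment(self, name: str) -> np.ndarray:
        for pname, off, size, shape in self.layout:
            if pname == name:
                return self.values[off : off + size].reshape(shape)
        raise KeyError(name)

    def same_layout(self, other: "ParameterVector") -> bool:
        return self.layout == other.layout

    def copy(self) -> "ParameterVector":
        return ParameterVector(self.values.copy(), self.layout)


def pack_parameters(model: Module) -> ParameterVector:
    chunks = []
    layout = []
    offset = 0
    for name, p in model.named_parameters():
        chunks.append(p.ravel())
        layout.append((name, offset, p.size, p.shape))
        offset += p.size
    values = np.concatenate(chunks) if chunks else np.empty(0)
    return ParameterVector(values, tuple(layout))


def unpack_parameters(model: Module, vector: ParameterVector) -> None:
    """Write ``vector`` back into ``model`` in place (layouts must match)."""
    expected = pack_parameters(model).layout
    if expected != vector.layout:
        raise ValueError("parameter layout mismatch between model and vector")
    by_name = {name: (off, size, shape) for name, off, size, shape in vector.layout}
    _assign(model, "", by_name, vector.values)


def _assign(module: Module, prefix: str, by_name, values: np.ndarray) -> None:
    for name in module.params:
        off, size, shape = by_name[prefix + name]
        module.params[name][...] = values[off : off + size].reshape(shape)
    for cname, child in module.children.items():
        _assign(child, prefix + cname + ".", by_name, values)
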