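"""Convolutional block attention (CBAM): channel gate then spatial gate.

The channel gate pools each feature map to average and max descriptors,
passes both through a shared two-layer MLP and sigmoids the sum into a
per-channel multiplier.  The spatial gate stacks the channel-wise mean and
max maps, convolves them to a single map and sigmoids it into a per-pixel
multiplier.  Both preserve the input shape exactly.
"""

from __future__ import annotations

import numpy as np

from .core import Conv2d, Linear, Module, ReLU

__all__ = ["ChannelAttention", "SpatialAttention", "CBAM"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class ChannelAttention(Module):
    def __init__(self, channels: int, reduction: int, rng: np.random.Generator) -> None:
        super().__init__()
        hidden = max(1, channels // reduction)
        self.channels = channels
        self.fc1 = self.add_child("fc1", Linear(channels, hidden, rng))
        self.relu = self.add_child("relu", ReLU())
        self.fc2 = self.add_child("fc2", Linear(hidden, channels, rng))

    def _mlp(self, s: np.ndarray) -> np.ndarray:
        return self.fc2.forward(self.relu.forward(self.fc1.forward(s)))

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        flat = x.reshape(n, c, h * w)
        s_avg = flat.mean(axis=2)
        idx = flat.argmax(axis=2)
        s_max = np.take_along_axis(flat, idx[:, :, None], axis=2)[:, :, 0]
        # shared MLP: run the two descriptors through the same weights in one
        # batch so the backward pass accumulates both contributions naturally
        stacked = np.concatenate([s_avg, s_max], axis=0)
        a = self._mlp(stacked)
        logits = a[:n] + a[n:]
        gate = _sigmoid(logits)
        self._cache = (x, idx, gate)
        return x * gate[:, :, None, None]

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        x, idx, gate = self._cache
        n, c, h, w = x.shape
        dx = grad_out * gate[:, :, None, None]
        dgate = (grad_out * x).sum(axis=(2, 3))
        dlogits = dgate * gate * (1.0 - gate)
        dstacked = np.concatenate([dlogits, dlogits], axis=0)
        ds = self.fc1.backward(self.relu.backward(self.fc2.backward(dstacked)))
        ds_avg, ds_max = ds[:n], ds[n:]
        dx += ds_avg[:, :, None, None] / (h * w)
        dflat = np.zeros((n, c, h * w))
        np.put_along_axis(dflat, idx[:, :, None], ds_max[:, :, None], axis=2)
        dx += dflat.reshape(n, c, h, w)
        return dx


class SpatialAttention(Module):
    def __init__(self, kernel_size: int, rng: np.random.Generator) -> None:
        super().__init__()
        if kernel_size % 2 != 1:
            raise ValueError(f"spatial attention kernel must be odd, got {kernel_size}")
        self.conv = self.add_child("conv", Conv2d(2, 1, kernel_size, rng))

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        mean_map = x.mean(axis=1, keepdims=True)
        idx = x.argmax(axis=1)
        max_map = np.take_along_axis(x, idx[:, None, :, :], axis=1)
        stats = np.concatenate([mean_map, max_map], axis=1)
        logits = self.conv.forward(stats)
        gate = _sigmoid(logits)
        self._cache = (x, idx, gate)
        return x * gate

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        x, idx, gate = self._cache
        n, c, h, w = x.shape
        dx = grad_out * gate
        dlogits = (grad_out * x).sum(axis=1, keepdims=True) * gate * (1.0 - gate)
        dstats = self.conv.backward(dlogits)
        dmean, dmax = dstats[:, :1], dstats[:, 1:]
        dx += dmean / c
        dmax_full = np.zeros_like(x)
        np.put_along_axis(dmax_full, idx[:, None, :, :], dmax, axis=1)
        dx += dmax_full
        return dx


class CBAM(Module):
    """Channel attention followed by spatial attention."""

    def __init__(self, channels: int, reduction: int, spatial_kernel: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.channel = self.add_child("channel", ChannelAttention(channels, reduction, rng))
        self.spatial = self.add_child("spatial", SpatialAttention(spatial_kernel, rng))

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.spatial.forward(self.channel.forward(x))

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return self.channel.backward(self.spatial.backward(grad_out))
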