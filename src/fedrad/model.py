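"""Per-centre CNN: residual backbone with optional CBAM attention.

The architecture is configurable (stage widths/depths, attention on/off, a
trailing 1x1 "feature head" convolution).  The canonical configuration uses
ResNet18-style stages (widths 64/128/256/512, two blocks each) with
parameter-free identity shortcuts, per-block CBAM, and a 537-channel feature
head, for a total of 4449 convolution kernels — each kernel later yields one
kernel-mean radiomic feature.

Training uses minibatch momentum SGD under the focal loss; all randomness is
seed-driven so two runs with the same seed are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .cohort import Cohort, crop_roi, normalize_patch
from .nn import CBAM, Conv2d, GlobalAvgPool, Linear, Module, ReLU

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "CANONICAL_CONFIG",
    "small_config",
    "build_local_model",
    "count_conv_kernels",
    "train_local",
    "predict_proba",
    "prepare_inputs",
    "LocalModel",
]


@dataclass(frozen=True)
class ModelConfig:
    stage_depths: tuple[int, ...] = (2, 2, 2, 2)
    stage_widths: tuple[int, ...] = (64, 128, 256, 512)
    input_channels: int = 1
    input_size: int = 64
    cbam_enabled: bool = True
    cbam_reduction: int = 16
    spatial_kernel: int = 7
    feature_head_channels: int = 537
    n_classes: int = 2

    def __post_init__(self) -> None:
        if len(self.stage_depths) != len(self.stage_widths):
            raise ValueError("stage_depths and stage_widths must have equal length")
        if any(w <= 0 for w in self.stage_widths) or any(d <= 0 for d in self.stage_depths):
            raise ValueError("stage widths and depths must be positive")
        if self.spatial_kernel % 2 != 1:
            raise ValueError("spatial_kernel must be odd")
        if self.feature_head_channels <= 0:
            raise ValueError("feature_head_channels must be positive")


#: Canonical configuration whose kernel count matches the published total:
#: 64 (stem) + 3840 (stage convs) + 8 (CBAM spatial convs) + 537 (head) = 4449.
CANONICAL_CONFIG = ModelConfig()


def small_config(cbam: bool = True) -> ModelConfig:
    """Desk-scale configuration used by the simulation experiments."""
    return ModelConfig(
        stage_depths=(1, 1),
        stage_widths=(8, 16),
        input_size=32,
        cbam_enabled=cbam,
        cbam_reduction=4,
        spatial_kernel=5,
        feature_head_channels=16,
    )


def count_conv_kernels(config: ModelConfig) -> int:
    """Total convolution output channels across the whole model.

    Counts the stem, every stage convolution, each CBAM spatial-attention
    convolution (1 kernel per block) and the feature head.  The channel
    attention gate is a pair of linear maps, not a convolution, and identity
    shortcuts are parameter-free, so neither contributes.
    """
    total = config.stage_widths[0]  # stem
    for depth, width in zip(config.stage_depths, config.stage_widths):
        total += depth * 2 * width
        if config.cbam_enabled:
            total += depth  # one single-channel spatial-attention conv per block
    total += config.feature_head_channels
    return total


class ResidualBlock(Module):
    """Two 3x3 convolutions with a parameter-free (option-A) shortcut:
    stride-2 blocks subsample the identity and zero-pad new channels."""

    def __init__(self, in_ch: int, out_ch: int, stride: int, config: ModelConfig, rng) -> None:
        super().__init__()
        self.in_ch, self.out_ch, self.stride = in_ch, out_ch, stride
        self.conv1 = self.add_child("conv1", Conv2d(in_ch, out_ch, 3, rng, stride=stride))
        self.relu1 = self.add_child("relu1", ReLU())
        self.conv2 = self.add_child("conv2", Conv2d(out_ch, out_ch, 3, rng))
        self.relu2 = self.add_child("relu2", ReLU())
        self.cbam = (
            self.add_child("cbam", CBAM(out_ch, config.cbam_reduction, config.spatial_kernel, rng))
            if config.cbam_enabled
            else None
        )

    def _shortcut(self, x: np.ndarray) -> np.ndarray:
        if self.stride > 1:
            x = x[:, :, :: self.stride, :: self.stride]
        if self.out_ch > self.in_ch:
            pad = self.out_ch - self.in_ch
            x = np.concatenate([x, np.zeros((x.shape[0], pad) + x.shape[2:])], axis=1)
        return x

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x_shape = x.shape
        h = self.conv2.forward(self.relu1.forward(self.conv1.forward(x)))
        if self.cbam is not None:
            # gate the residual branch only: the identity path stays unscaled,
            # which keeps signal propagation healthy through stacked blocks
            h = self.cbam.forward(h)
        return self.relu2.forward(h + self._shortcut(x))

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        g = self.relu2.backward(grad_out)
        gb = self.cbam.backward(g) if self.cbam is not None else g
        gx = self.conv1.backward(self.relu1.backward(self.conv2.backward(gb)))
        # shortcut branch
        gs = g[:, : self.in_ch]
        if self.stride > 1:
            full = np.zeros(self._x_shape)
            full[:, :, :: self.stride, :: self.stride] = gs
            gs = full
        return gx + gs


class LocalModel(Module):
    """Stem conv -> residual stages -> 1x1 feature head -> GAP -> linear logits."""

    def __init__(self, config: ModelConfig, seed: int = 0) -> None:
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        widths = config.stage_widths
        self.stem = self.add_child("stem", Conv2d(config.input_channels, widths[0], 3, rng))
        self.stem_relu = self.add_child("stem_relu", ReLU())
        self.block_order: list[str] = []
        in_ch = widths[0]
        for s, (depth, width) in enumerate(zip(config.stage_depths, widths)):
            for b in range(depth):
                stride = 2 if (s > 0 and b == 0) else 1
                name = f"stage{s}_block{b}"
                self.add_child(name, ResidualBlock(in_ch, width, stride, config, rng))
                self.block_order.append(name)
                in_ch = width
        self.head = self.add_child("head", Conv2d(in_ch, config.feature_head_channels, 1, rng))
        self.head_relu = self.add_child("head_relu", ReLU())
        self.pool = self.add_child("pool", GlobalAvgPool())
        self.fc = self.add_child("fc", Linear(config.feature_head_channels, config.n_classes, rng))
        # focal-loss companion: bias the head so training starts at the
        # minority-class prior instead of p = 0.5, keeping early gradients
        # focused on the rare class rather than uniformly attenuated
        prior = 0.25
        self.fc.params["bias"][1] = np.log(prior / (1 - prior))

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self.stem_relu.forward(self.stem.forward(x))
        for name in self.block_order:
            h = self.children[name].forward(h)
        self._last_stage = h
        h = self.head_relu.forward(self.head.forward(h))
        return self.fc.forward(self.pool.forward(h))

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        g = self.head.backward(self.head_relu.backward(self.pool.backward(self.fc.backward(grad_out))))
        for name in reversed(self.block_order):
            g = self.children[name].backward(g)
        return self.stem.backward(self.stem_relu.backward(g))

    def conv_modules(self) -> list[tuple[str, Conv2d]]:
        """Every convolution layer in forward order (stem, stages+attention, head)."""
        convs = [("stem", self.stem)]
        for bname in self.block_order:
            block = self.children[bname]
            convs.append((f"{bname}.conv1", block.conv1))
            convs.append((f"{bname}.conv2", block.conv2))
            if block.cbam is not None:
                convs.append((f"{bname}.cbam.spatial.conv", block.cbam.spatial.conv))
        convs.append(("head", self.head))
        return convs


def build_local_model(config: ModelConfig, seed: int = 0) -> LocalModel:
    return LocalModel(config, seed=seed)


def save_checkpoint(model: LocalModel, path, seed: int | None = None, epoch: int | None = None) -> None:
    """Write parameters (npz, one array per named segment) + a JSON sidecar
    describing the architecture, so a checkpoint is self-identifying."""
    import json
    from pathlib import Path

    path = Path(path)
    arrays = {name.replace(".", "/"): p for name, p in model.named_parameters()}
    np.savez(path.with_suffix(".npz"), **arrays)
    sidecar = {
        "config": {k: list(v) if isinstance(v, tuple) else v
                   for k, v in model.config.__dict__.items()},
        "seed": seed,
        "epoch": epoch,
        "n_parameters": model.n_parameters(),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path) -> LocalModel:
    import json
    from pathlib import Path

    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg_dict = dict(sidecar["config"])
    for key in ("stage_depths", "stage_widths"):
        cfg_dict[key] = tuple(cfg_dict[key])
    model = LocalModel(ModelConfig(**cfg_dict), seed=0)
    with np.load(path.with_suffix(".npz")) as data:
        for name, p in model.named_parameters():
            p[...] = data[name.replace(".", "/")]
    return model


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 5
    batch_size: int = 16
    learning_rate: float = 1e-3
    momentum: float = 0.9
    optimizer: str = "sgd"  # "sgd" (momentum) or "rmsprop"
    focal_alpha: float = 0.25
    focal_gamma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.optimizer not in ("sgd", "rmsprop"):
            raise ValueError("optimizer must be 'sgd' or 'rmsprop'")
        if self.focal_gamma < 0:
            raise ValueError("focal_gamma must be >= 0")
        if not (0 < self.focal_alpha <= 1):
            raise ValueError("focal_alpha must be in (0, 1]")


def prepare_inputs(cohort: Cohort, input_size: int, margin: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """ROI-crop, resize and z-score every patient image into model input."""
    xs = [
        normalize_patch(crop_roi(p.image, p.lesion_mask, margin), input_size)
        for p in cohort.patients
    ]
    return np.stack(xs)[:, None, :, :], cohort.labels


def _softmax_pos(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e[:, 1] / e.sum(axis=1)


def predict_proba(model: LocalModel, X: np.ndarray) -> np.ndarray:
    """Positive-class probability for preprocessed inputs (N, 1, S, S)."""
    return _softmax_pos(model.forward(np.asarray(X, dtype=float)))


def train_local(
    model: LocalModel,
    cohort: Cohort | tuple[np.ndarray, np.ndarray],
    train_config: TrainConfig,
) -> tuple[nn.ParameterVector, list[float]]:
    """Minibatch momentum-SGD training under the focal loss.

    Returns the final flattened parameters and the per-epoch mean loss
    trace.  Raises if the cohort contains a single class, where focal-loss
    evaluation (and any downstream AUC) is degenerate.
    """
    if isinstance(cohort, Cohort):
        X, y = prepare_inputs(cohort, model.config.input_size)
    else:
        X, y = cohort
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training cohort must contain both classes")

    cfg = train_config
    rng = np.random.default_rng(cfg.seed)
    if cfg.optimizer == "rmsprop":
        opt = nn.RMSprop(model, lr=cfg.learning_rate)
    else:
        opt = nn.SGD(model, lr=cfg.learning_rate, momentum=cfg.momentum)
    trace: list[float] = []
    n = len(y)
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = X[idx], y[idx]
            logits = model.forward(xb)
            p = _softmax_pos(logits)
            loss = nn.focal_loss(p, yb, cfg.focal_alpha, cfg.focal_gamma)
            dp = nn.focal_loss_grad(p, yb, cfg.focal_alpha, cfg.focal_gamma)
            dz = np.zeros_like(logits)
            dpdz = p * (1.0 - p)
            dz[:, 1] = dp * dpdz
            dz[:, 0] = -dp * dpdz
            model.zero_grad()
            model.backward(dz)
            opt.step()
            epoch_loss += loss * len(idx)
        trace.append(epoch_loss / n)
    return nn.pack_parameters(model), trace
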