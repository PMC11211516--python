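"""Residual convolutional encoder for the 3-channel density tensors.

Five stages of bottleneck residual units (1×1 reduce → 3×3 → 1×1 expand),
PReLU activations with learned negative slopes, batch normalization after
every convolution, and a global average pool feeding a linear head. The
full-scale preset stacks 3/4/6/3/3 units per stage (19 bottleneck units);
the ``tiny`` preset (one unit per stage, narrow channels) trains on a
single CPU and is the configuration the test and acceptance harnesses use.

The first unit of each stage halves the spatial resolution, so a G×G input
must satisfy G ≥ 32 for five downsampling stages.
"""

from __future__ import annotations

import numpy as np

from .kde_features import DKPETensor
from .nn.autodiff import Tensor
from .nn.modules import BatchNorm2d, Conv2d, Linear, Module, PReLU

__all__ = ["CellEncoderConfig", "CellEncoder", "count_residual_units", "encode_cell"]

_NUM_STAGES = 5

PRESETS = {
    "resnet54-paper": {
        "stage_units": (3, 4, 6, 3, 3),
        "stage_channels": (64, 128, 256, 512, 512),
        "stem_channels": 32,
        "expansion": 4,
    },
    "tiny": {
        "stage_units": (1, 1, 1, 1, 1),
        "stage_channels": (16, 32, 32, 64, 64),
        "stem_channels": 8,
        "expansion": 2,
    },
}


class CellEncoderConfig:
    def __init__(
        self,
        stage_units=(3, 4, 6, 3, 3),
        stage_channels=(64, 128, 256, 512, 512),
        stem_channels: int = 32,
        expansion: int = 4,
        out_dim: int = 100,
        batch_norm: bool = True,
    ):
        stage_units = tuple(stage_units)
        stage_channels = tuple(stage_channels)
        if len(stage_units) != _NUM_STAGES or len(stage_channels) != _NUM_STAGES:
            raise ValueError(f"exactly {_NUM_STAGES} stages are required")
        if any(u < 1 for u in stage_units):
            raise ValueError("every stage needs at least one residual unit")
        self.stage_units = stage_units
        self.stage_channels = stage_channels
        self.stem_channels = stem_channels
        self.expansion = expansion
        self.out_dim = out_dim
        self.batch_norm = batch_norm

    @classmethod
    def preset(cls, name: str, out_dim: int = 100) -> "CellEncoderConfig":
        if name not in PRESETS:
            raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
        return cls(out_dim=out_dim, **PRESETS[name])


def count_residual_units(config: CellEncoderConfig) -> int:
    return sum(config.stage_units)


class _Identity(Module):
    def __call__(self, x):
        return x


def _bn(ch: int, enabled: bool) -> Module:
    return BatchNorm2d(ch) if enabled else _Identity()


class _Bottleneck(Module):
    """1×1 reduce → 3×3 (stride on the stage's first unit) → 1×1 expand."""

    def __init__(self, in_ch: int, out_ch: int, mid_ch: int, stride: int, rng, bn: bool):
        super().__init__()
        self.conv1 = Conv2d(in_ch, mid_ch, 1, rng, bias=not bn)
        self.bn1 = _bn(mid_ch, bn)
        self.act1 = PReLU(mid_ch)
        self.conv2 = Conv2d(mid_ch, mid_ch, 3, rng, stride=stride, padding=1, bias=not bn)
        self.bn2 = _bn(mid_ch, bn)
        self.act2 = PReLU(mid_ch)
        self.conv3 = Conv2d(mid_ch, out_ch, 1, rng, bias=not bn)
        self.bn3 = _bn(out_ch, bn)
        if stride != 1 or in_ch != out_ch:
            self.proj = Conv2d(in_ch, out_ch, 1, rng, stride=stride, bias=not bn)
            self.bn_proj = _bn(out_ch, bn)
        else:
            self.proj = None
        self.act_out = PReLU(out_ch)

    def __call__(self, x: Tensor) -> Tensor:
        r = self.act1(self.bn1(self.conv1(x)))
        r = self.act2(self.bn2(self.conv2(r)))
        r = self.bn3(self.conv3(r))
        skip = x if self.proj is None else self.bn_proj(self.proj(x))
        return self.act_out(r + skip)


class CellEncoder(Module):
    """DKPE tensor → embedding ``z_e`` of length ``out_dim``."""

    def __init__(self, config: CellEncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        bn = config.batch_norm
        # 3×3 stride-1 stem: the inputs are small grids, a strided large
        # kernel would discard most of the map before the first stage
        self.stem = Conv2d(3, config.stem_channels, 3, rng, padding=1, bias=not bn)
        self.stem_bn = _bn(config.stem_channels, bn)
        self.stem_act = PReLU(config.stem_channels)
        self.stages: list[list[_Bottleneck]] = []
        in_ch = config.stem_channels
        for units, out_ch in zip(config.stage_units, config.stage_channels):
            mid = max(out_ch // config.expansion, 1)
            stage = []
            for u in range(units):
                stride = 2 if u == 0 else 1  # first unit of each stage downsamples
                stage.append(_Bottleneck(in_ch, out_ch, mid, stride, rng, bn))
                in_ch = out_ch
            self.stages.append(stage)
        self.head = Linear(in_ch, config.out_dim, rng)

    @property
    def min_input_size(self) -> int:
        return 2**_NUM_STAGES

    def forward_batch(self, x: np.ndarray | Tensor) -> Tensor:
        """Encode a (N, 3, G, G) batch of density tensors."""
        t = x if isinstance(x, Tensor) else Tensor(x)
        if t.ndim != 4 or t.shape[1] != 3:
            raise ValueError(f"expected (N, 3, G, G), got {t.shape}")
        G = t.shape[2]
        if G < self.min_input_size:
            raise ValueError(
                f"grid size {G} too small: five downsampling stages need at least "
                f"{self.min_input_size}×{self.min_input_size} input"
            )
        h = self.stem_act(self.stem_bn(self.stem(t)))
        for stage in self.stages:
            for unit in stage:
                h = unit(h)
        pooled = h.mean(axis=(2, 3))  # global average pool → (N, C)
        return self.head(pooled)

    def __call__(self, t: DKPETensor) -> Tensor:
        return self.forward_batch(t.channels[None]).reshape(self.config.out_dim)


def encode_cell(t: DKPETensor, model: CellEncoder) -> np.ndarray:
    """Embedding of one density tensor under the current parameters."""
    was_training = model.training
    model.eval()
    z = model(t).data
    if was_training:
        model.train()
    return z
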