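"""The attention-augmented residual classifier and its plain baseline.

Architecture: a 3x3 stem convolution lifts the 1-channel impedance
matrix (pairs x frequencies, treated as an image) to ``stem_channels``
feature maps, a stack of residual blocks refines them (each block gated
by channel-then-spatial attention when enabled), global average pooling
collapses space, and a linear head produces two class logits.  With
``use_attention=False`` the identical trunk without gates serves as the
ResNet baseline.

Defaults are deliberately small (16 channels, 3 blocks) — the cohorts
this model is built for have tens of subjects, not thousands.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .autodiff import Tensor
from .layers import Conv2d, InstanceNorm2d, Linear, Module, ResidualBlock

__all__ = ["NetworkConfig", "AttentionResNet", "build_model", "softmax"]


@dataclass(frozen=True)
class NetworkConfig:
    """Hyperparameters of the classifier; ``use_attention=False`` is the baseline."""

    in_shape: tuple[int, int] = (15, 30)
    stem_channels: int = 16
    n_blocks: int = 3
    reduction_ratio: int = 4
    spatial_kernel: int = 7
    use_attention: bool = True
    n_classes: int = 2
    init_seed: int = 0

    def __post_init__(self) -> None:
        if self.spatial_kernel % 2 != 1:
            raise ValueError("spatial_kernel must be odd")
        if self.reduction_ratio < 1 or self.stem_channels % self.reduction_ratio != 0:
            raise ValueError("reduction_ratio must be >= 1 and divide stem_channels")
        if self.n_classes != 2:
            raise ValueError("binary classifier: n_classes must be 2")
        if self.n_blocks < 1 or self.stem_channels < 1:
            raise ValueError("need at least one block and one channel")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["in_shape"] = list(self.in_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        d["in_shape"] = tuple(d["in_shape"])
        return cls(**d)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class AttentionResNet(Module):
    """Residual CNN for (pairs x frequencies) impedance matrices."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        rng = np.random.default_rng(config.init_seed)
        c = config.stem_channels
        self.stem = Conv2d(1, c, 3, rng)
        self.stem_norm = InstanceNorm2d(c)
        self.blocks = [
            ResidualBlock(
                c,
                c,
                rng,
                use_attention=config.use_attention,
                reduction_ratio=config.reduction_ratio,
                spatial_kernel=config.spatial_kernel,
            )
            for _ in range(config.n_blocks)
        ]
        self.head = Linear(c, config.n_classes, rng)

    def forward(self, x: Tensor) -> Tensor:
        """Logits for a batch ``x`` of shape (N, 1, H, W)."""
        if x.shape[2:] != tuple(self.config.in_shape):
            raise ValueError(f"expected spatial shape {self.config.in_shape}, got {x.shape[2:]}")
        h = self.stem_norm(self.stem(x)).relu()
        for block in self.blocks:
            h = block(h)
        pooled = h.mean(axis=(2, 3))  # global average pooling -> (N, C)
        return self.head(pooled)

    __call__ = forward

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Class probabilities for (N, H, W) or (N, 1, H, W) input."""
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 3:
            x = x[:, None]
        return softmax(self.forward(Tensor(x)).data)

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


def build_model(config: NetworkConfig) -> AttentionResNet:
    """Instantiate a classifier with reproducible initialisation."""
    return AttentionResNet(config)
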