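"""Network building blocks: convolutions, normalisation, attention, residual blocks.

The attention design follows the convolutional block attention pattern:
a channel gate computed from global average- and max-pooled descriptors
through a shared bottleneck MLP, followed by a spatial gate computed
from channel-wise mean and max maps through a single wide convolution.
Both gates are sigmoids, so each module is a pass-through scaling with
weights strictly inside (0, 1).

Normalisation is instance-style (per sample, per channel over space)
because the cohorts are tiny and batch statistics would be unreliable.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, conv2d, instance_norm

__all__ = [
    "Module",
    "Conv2d",
    "Linear",
    "InstanceNorm2d",
    "ChannelAttention",
    "SpatialAttention",
    "ResidualBlock",
]


class Module:
    """Base class: parameter collection and (de)serialisation by name."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        named: dict[str, Tensor] = {}
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                named[key] = value
            elif isinstance(value, Module):
                named.update(value.named_parameters(f"{key}."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        named.update(item.named_parameters(f"{key}.{i}."))
        return named

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        named = self.named_parameters()
        if set(named) != set(state):
            missing = set(named) ^ set(state)
            raise ValueError(f"state dict mismatch on keys: {sorted(missing)}")
        for k, v in named.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != v.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {v.data.shape}")
            v.data = arr.copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


def _he_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


class Conv2d(Module):
    """Stride-1 convolution with 'same' zero padding and He-normal init."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError(f"kernel size must be odd for same-padding, got {kernel}")
        self.kernel = kernel
        self.padding = kernel // 2
        fan_in = in_channels * kernel * kernel
        self.weight = Tensor(
            _he_normal(rng, (out_channels, in_channels, kernel, kernel), fan_in), requires_grad=True
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, padding=self.padding)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        self.weight = Tensor(_he_normal(rng, (in_features, out_features), in_features), requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class InstanceNorm2d(Module):
    """Per-(sample, channel) spatial normalisation with learnable affine."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.eps = eps
        self.gamma = Tensor(np.ones((1, channels, 1, 1)), requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1, 1)), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return instance_norm(x, self.eps) * self.gamma + self.beta


class ChannelAttention(Module):
    """Channel gate: sigmoid(MLP(avgpool) + MLP(maxpool)), shared MLP.

    The bottleneck MLP maps C -> C/r -> C with a rectifier in between;
    the same weights process both pooled descriptors.  Output is the
    input scaled channel-wise by the gate.
    """

    def __init__(self, channels: int, reduction_ratio: int, rng: np.random.Generator):
        if reduction_ratio < 1 or channels % reduction_ratio != 0:
            raise ValueError(
                f"reduction_ratio ({reduction_ratio}) must be >= 1 and divide channels ({channels})"
            )
        hidden = channels // reduction_ratio
        self.fc1 = Linear(channels, hidden, rng)
        self.fc2 = Linear(hidden, channels, rng)
        self.channels = channels

    def gate(self, x: Tensor) -> Tensor:
        avg = x.mean(axis=(2, 3))  # (N, C)
        mx = x.max(axis=(2, 3))
        z = self.fc2(self.fc1(avg).relu()) + self.fc2(self.fc1(mx).relu())
        return z.sigmoid()

    def __call__(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        return x * self.gate(x).reshape(n, c, 1, 1)


class SpatialAttention(Module):
    """Spatial gate: sigmoid(conv_k([channel-mean; channel-max])).

    A single k x k convolution over the 2-channel pooled map produces a
    one-channel gate of the same spatial size; output is the input
    scaled location-wise.
    """

    def __init__(self, kernel: int, rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError(f"spatial attention kernel must be odd, got {kernel}")
        self.conv = Conv2d(2, 1, kernel, rng)

    def gate(self, x: Tensor) -> Tensor:
        pooled = concat([x.mean(axis=1, keepdims=True), x.max(axis=1, keepdims=True)], axis=1)
        return self.conv(pooled).sigmoid()

    def __call__(self, x: Tensor) -> Tensor:
        return x * self.gate(x)


class ResidualBlock(Module):
    """conv3x3-norm-relu-conv1x1-norm residual unit, optionally gated.

    With attention enabled the branch output passes through the channel
    gate then the spatial gate before being added to the shortcut (an
    identity when channel counts match, a 1x1 convolution otherwise).
    The 1x1 second convolution keeps the parameter count small.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        rng: np.random.Generator,
        *,
        use_attention: bool = False,
        reduction_ratio: int = 4,
        spatial_kernel: int = 7,
    ):
        self.conv1 = Conv2d(in_channels, out_channels, 3, rng)
        self.norm1 = InstanceNorm2d(out_channels)
        self.conv2 = Conv2d(out_channels, out_channels, 1, rng)
        self.norm2 = InstanceNorm2d(out_channels)
        self.attention_channel = (
            ChannelAttention(out_channels, reduction_ratio, rng) if use_attention else None
        )
        self.attention_spatial = SpatialAttention(spatial_kernel, rng) if use_attention else None
        self.shortcut = Conv2d(in_channels, out_channels, 1, rng) if in_channels != out_channels else None

    def __call__(self, x: Tensor) -> Tensor:
        y = self.norm2(self.conv2(self.norm1(self.conv1(x)).relu()))
        if self.attention_channel is not None:
            y = self.attention_spatial(self.attention_channel(y))
        s = self.shortcut(x) if self.shortcut is not None else x
        return (y + s).relu()
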