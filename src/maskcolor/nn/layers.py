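"""Neural-network layers built on the autodiff tensor.

Modules follow the familiar container pattern: submodules and parameters
registered on attribute assignment, ``train()``/``eval()`` switch batch-norm
behaviour, and ``state_dict``/``load_state_dict`` round-trip all parameters
and running statistics as plain numpy arrays.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .tensor import Tensor, conv2d, upsample_nearest2d

__all__ = [
    "Module",
    "Sequential",
    "Conv2d",
    "BatchNorm2d",
    "Linear",
    "ReLU",
    "Tanh",
    "Sigmoid",
    "Upsample",
    "ResidualBlock",
    "param_checksum",
]


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        return [t for _, t in self.named_parameters()]

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, t in self._params.items():
            yield prefix + name, t
        for name, mod in self._modules.items():
            yield from mod.named_parameters(prefix + name + ".")

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name in self._buffers:
            yield prefix + name, getattr(self, name)
        for name, mod in self._modules.items():
            yield from mod.named_buffers(prefix + name + ".")

    def train(self, mode: bool = True) -> "Module":
        object.__setattr__(self, "training", mode)
        for mod in self._modules.values():
            mod.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: t.data.copy() for name, t in self.named_parameters()}
        state.update({name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, t in self.named_parameters():
            t.data[...] = state[name]
        for name, _ in self.named_buffers():
            parts = name.split(".")
            mod = self
            for part in parts[:-1]:
                mod = mod._modules[part]
            mod.register_buffer(parts[-1], np.array(state[name]))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        for i, layer in enumerate(layers):
            setattr(self, f"layer{i}", layer)
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Conv2d(Module):
    """He-initialized convolution; ``rng`` makes initialization reproducible."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        stride: int = 1,
        padding: int | None = None,
        bias: bool = True,
    ):
        super().__init__()
        k = kernel_size
        self.stride = stride
        self.padding = k // 2 if padding is None else padding
        scale = np.sqrt(2.0 / (in_channels * k * k))
        self.weight = Tensor(
            rng.normal(0.0, scale, size=(out_channels, in_channels, k, k)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class BatchNorm2d(Module):
    """Batch normalization over (N, H, W) per channel.

    With ``population_stats=True`` the normalizer uses the running
    (population) statistics during training as well, treating them as
    constants, while still updating them from each batch. At batch size 1
    the per-batch statistics are per-image statistics, which erase the
    absolute intensity level the colorization mapping depends on;
    population statistics keep the transform image-independent.
    """

    def __init__(
        self,
        channels: int,
        eps: float = 1e-5,
        momentum: float = 0.1,
        population_stats: bool = False,
    ):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.population_stats = population_stats
        self.gamma = Tensor(np.ones((1, channels, 1, 1)), requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1, 1)), requires_grad=True)
        self.register_buffer("running_mean", np.zeros((1, channels, 1, 1)))
        self.register_buffer("running_var", np.ones((1, channels, 1, 1)))

    def forward(self, x: Tensor) -> Tensor:
        from .tensor import batch_norm_2d

        if self.training:
            batch_mean = x.data.mean(axis=(0, 2, 3), keepdims=True)
            batch_var = x.data.var(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.register_buffer(
                "running_mean", (1 - m) * self.running_mean + m * batch_mean
            )
            self.register_buffer(
                "running_var", (1 - m) * self.running_var + m * batch_var
            )
            if self.population_stats:
                mean, var, batch_stats = self.running_mean, self.running_var, False
            else:
                mean, var, batch_stats = batch_mean, batch_var, True
        else:
            mean, var, batch_stats = self.running_mean, self.running_var, False
        return batch_norm_2d(x, self.gamma, self.beta, mean, var, self.eps, batch_stats)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / in_features)
        self.weight = Tensor(
            rng.normal(0.0, scale, size=(in_features, out_features)), requires_grad=True
        )
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Tanh(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.tanh()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class Upsample(Module):
    def __init__(self, factor: int = 2):
        super().__init__()
        self.factor = factor

    def forward(self, x: Tensor) -> Tensor:
        return upsample_nearest2d(x, self.factor)


class ResidualBlock(Module):
    """conv-bn-relu-conv-bn with identity skip (channel count preserved)."""

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv2d(channels, channels, 3, rng)
        self.bn1 = BatchNorm2d(channels)
        self.conv2 = Conv2d(channels, channels, 3, rng)
        self.bn2 = BatchNorm2d(channels)

    def forward(self, x: Tensor) -> Tensor:
        h = self.bn1(self.conv1(x)).relu()
        h = self.bn2(self.conv2(h))
        return x + h


def param_checksum(module: Module) -> float:
    """Order-independent fingerprint of all parameters (for isolation tests)."""
    return float(sum(np.abs(t.data).sum() for t in module.parameters()))
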