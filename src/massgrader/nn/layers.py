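"""Neural-network modules built on the autograd primitives.

The Module tree mirrors the familiar torch.nn surface at the scale this
package needs: parameter discovery by attribute walk, a train/eval flag that
switches batch-norm statistics, and named state export for checkpointing.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = [
    "Module",
    "ModuleList",
    "Sequential",
    "Conv2d",
    "BatchNorm2d",
    "Linear",
    "SiLU",
    "ReLU",
    "MaxPool2d",
    "GlobalAvgPool2d",
    "Flatten",
]


class Module:
    def __init__(self):
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    def children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, ModuleList):
                for i, m in enumerate(value):
                    yield f"{name}.{i}", m

    def parameters(self) -> list[Tensor]:
        return [t for _, t in self.named_parameters()]

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                yield prefix + name, value
        for name, child in self.children():
            yield from child.named_parameters(prefix + name + ".")

    def named_buffers(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, np.ndarray):
                yield prefix + name, value
        for name, child in self.children():
            yield from child.named_buffers(prefix + name + ".")

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self.children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {"param." + k: v.data for k, v in self.named_parameters()}
        state.update({"buffer." + k: v for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for key, value in state.items():
            kind, _, name = key.partition(".")
            if kind == "param":
                params[name].data = np.array(value, dtype=np.float32)
            elif kind == "buffer":
                buffers[name][...] = value
            else:
                raise KeyError(f"unrecognized state entry {key!r}")


class ModuleList(list):
    pass


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.layers = ModuleList(modules)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int | None = None,
        groups: int = 1,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        if in_channels % groups or out_channels % groups:
            raise ValueError("channel counts must be divisible by groups")
        k = kernel_size
        self.stride = stride
        self.padding = k // 2 if padding is None else padding
        self.groups = groups
        fan_in = (in_channels // groups) * k * k
        std = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            rng.standard_normal((out_channels, in_channels // groups, k, k)) * std,
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv2d(
            x, self.weight, self.bias, self.stride, self.padding, self.groups
        )


class BatchNorm2d(Module):
    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.gamma = Tensor(np.ones(num_features), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features), requires_grad=True)
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        return ag.batch_norm2d(
            x,
            self.gamma,
            self.beta,
            self.running_mean,
            self.running_var,
            self.training,
            self.momentum,
            self.eps,
        )


class Linear(Module):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / in_features)
        self.weight = Tensor(
            rng.standard_normal((out_features, in_features)) * std, requires_grad=True
        )
        self.bias = Tensor(np.zeros(out_features), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ag.linear(x, self.weight, self.bias)


class SiLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.silu(x)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.relu(x)


class MaxPool2d(Module):
    def __init__(self, kernel_size: int, stride: int | None = None, padding: int = 0):
        super().__init__()
        self.kernel_size = kernel_size
        self.stride = stride or kernel_size
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return ag.max_pool2d(x, self.kernel_size, self.stride, self.padding)


class GlobalAvgPool2d(Module):
    """Adaptive average pooling with a 1x1 target, emitting (N, C)."""

    def forward(self, x: Tensor) -> Tensor:
        return ag.global_avg_pool2d(x)


class Flatten(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.flatten(x)
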