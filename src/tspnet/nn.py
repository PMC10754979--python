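"""Neural-network building blocks on top of the autodiff engine.

Provides a ``Module`` hierarchy (parameter registry, train/eval mode,
state-dict serialisation) and the concrete layers the architecture uses:
axis-wise convolutions, batch normalisation, and a fully connected layer.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import _autograd as ag
from ._autograd import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)
        # parameters stay differentiable even when created under no_grad
        self.requires_grad = True


class Module:
    """Base class: registers parameters/submodules via attribute assignment."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for k, p in self._params.items():
            yield prefix + k, p
        for k, m in self._modules.items():
            yield from m.named_parameters(prefix + k + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for k, v in self._buffers.items():
            yield prefix + k, v
        for k, m in self._modules.items():
            yield from m.named_buffers(prefix + k + ".")

    def train(self, mode: bool = True):
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: p.data.copy() for k, p in self.named_parameters()}
        state.update({k: v.copy() for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, p in self.named_parameters():
            p.data = np.array(state[k], dtype=p.data.dtype)
        for k, v in self.named_buffers():
            v[...] = state[k]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv1dAxis(Module):
    """Convolution along a single axis of a [N, C, H, W] feature map.

    ``axis=3`` convolves over time (kernels written 1×k), ``axis=2`` over the
    spatial/electrode dimension (kernels k×1).  "Same" zero padding; odd k.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 axis: int, stride: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None,
                 dtype=np.float32):
        super().__init__()
        if kernel_size % 2 == 0:
            raise ValueError("kernel size must be odd")
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel_size
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU networks
        self.axis = axis
        self.stride = stride
        self.weight = Parameter(
            rng.normal(0.0, scale, (out_channels, in_channels, kernel_size)).astype(dtype))
        self.bias = Parameter(np.zeros(out_channels, dtype=dtype)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv1d_axis(x, self.weight, self.bias, self.axis, self.stride)


class BatchNorm(Module):
    """Per-feature-channel batch normalisation of [N, C, H, W] maps."""

    def __init__(self, num_channels: int, momentum: float = 0.1,
                 eps: float = 1e-5, dtype=np.float32):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.gamma = Parameter(np.ones(num_channels, dtype=dtype))
        self.beta = Parameter(np.zeros(num_channels, dtype=dtype))
        self.register_buffer("running_mean", np.zeros(num_channels, dtype=dtype))
        self.register_buffer("running_var", np.ones(num_channels, dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        return ag.batchnorm(x, self.gamma, self.beta, self.running_mean,
                            self.running_var, self.training, self.momentum,
                            self.eps)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng()
        scale = np.sqrt(1.0 / in_features)
        self.weight = Parameter(
            rng.uniform(-scale, scale, (out_features, in_features)).astype(dtype))
        self.bias = Parameter(np.zeros(out_features, dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        return ag.matmul(x, ag.transpose_last2(self.weight)) + self.bias
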