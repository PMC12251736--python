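"""Layer/module system and the SGD optimizer.

Mirrors the familiar torch-style API at the scale this package needs:
modules discover parameters and sub-modules through attribute assignment,
``train()``/``eval()`` toggle BatchNorm behaviour, and each ``Conv2d``
records the multiply-accumulate count of its last forward pass so model
statistics can be summed after a single tracing forward.
"""

from __future__ import annotations

import numpy as np

from . import functional as F
from .autograd import Tensor


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    # -- traversal -----------------------------------------------------------

    def parameters(self):
        for p in self._params.values():
            yield p
        for m in self._modules.values():
            yield from m.parameters()

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def num_params(self) -> int:
        """Exact count of trainable scalars."""
        return int(sum(p.size for p in self.parameters()))

    # -- mode ----------------------------------------------------------------

    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- state ---------------------------------------------------------------

    def state_dict(self, prefix: str = "") -> dict:
        state = {prefix + k: p.data.copy() for k, p in self._params.items()}
        for k, m in self._modules.items():
            state.update(m.state_dict(prefix + k + "."))
            if isinstance(m, BatchNorm2d):
                state[prefix + k + ".running_mean"] = m.running_mean.copy()
                state[prefix + k + ".running_var"] = m.running_var.copy()
        return state

    def load_state_dict(self, state: dict, prefix: str = ""):
        for k, p in self._params.items():
            p.data[...] = state[prefix + k]
        for k, m in self._modules.items():
            m.load_state_dict(state, prefix + k + ".")
            if isinstance(m, BatchNorm2d):
                m.running_mean[...] = state[prefix + k + ".running_mean"]
                m.running_var[...] = state[prefix + k + ".running_var"]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    """Plain convolution; bias off by default (a BatchNorm usually follows)."""

    def __init__(self, c_in, c_out, kernel, stride=1, padding=0, dilation=1,
                 bias=False, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * kernel * kernel
        bound = float(np.sqrt(2.0 / fan_in))  # He initialization
        self.weight = Parameter(rng.normal(0.0, bound, (c_out, c_in, kernel, kernel)))
        self.bias = Parameter(np.zeros(c_out)) if bias else None
        self.stride, self.padding, self.dilation = stride, padding, dilation
        self.last_macs = 0

    def forward(self, x: Tensor) -> Tensor:
        out = F.conv2d(x, self.weight, self.bias, stride=self.stride,
                       padding=self.padding, dilation=self.dilation)
        self.last_macs = F.conv2d.last_macs
        return out


class BatchNorm2d(Module):
    """Batch normalization over (N, H, W) per channel.

    eps/momentum follow the YOLOv8 convention (1e-3 / 0.03).  Running
    statistics are buffers, not trainable parameters.
    """

    def __init__(self, c, eps: float = 1e-3, momentum: float = 0.03):
        super().__init__()
        self.weight = Parameter(np.ones(c))
        self.bias = Parameter(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.eps, self.momentum = eps, momentum

    def forward(self, x: Tensor) -> Tensor:
        shape = (1, -1, 1, 1)
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
            xn = xc / (var + self.eps).sqrt()
        else:
            xn = (x - self.running_mean.reshape(shape)) / np.sqrt(
                self.running_var.reshape(shape) + self.eps
            )
        return xn * self.weight.reshape(shape) + self.bias.reshape(shape)


class SiLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.silu()


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class MaxPool2d(Module):
    def __init__(self, kernel, stride=1, padding=0):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return F.max_pool2d(x, self.kernel, stride=self.stride, padding=self.padding)


class Upsample2x(Module):
    def forward(self, x: Tensor) -> Tensor:
        return F.upsample_nearest2x(x)


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self._seq = list(mods)
        for i, m in enumerate(mods):
            setattr(self, f"m{i}", m)

    def __iter__(self):
        return iter(self._seq)

    def __getitem__(self, i):
        return self._seq[i]

    def forward(self, x):
        for m in self._seq:
            x = m(x)
        return x


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list = []
        for m in mods:
            self.append(m)

    def append(self, m: Module):
        setattr(self, f"m{len(self._list)}", m)
        self._list.append(m)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class SGD:
    """Stochastic gradient descent with momentum and decoupled weight decay."""

    def __init__(self, params, lr: float, momentum: float = 0.937,
                 weight_decay: float = 5e-4):
        self.params = list(params)
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self._vel = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self._vel):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.grad = None
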