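"""Layer and module abstractions over the autograd ops.

A ``Module`` auto-registers ``Tensor`` attributes as trainable parameters
and ``Module`` attributes as children (lists of modules go through
``ModuleList``). Non-trainable state (batch-norm moving statistics) is
registered as a named buffer so it is saved in checkpoints and counted in
parameter totals the way deep-learning frameworks report them.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_children", {})

    def __setattr__(self, name, value):
        if isinstance(value, Tensor):
            self._params[name] = value
        elif isinstance(value, Module):
            self._children[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, array: np.ndarray):
        self._buffers[name] = array
        object.__setattr__(self, name, array)

    # -- traversal -----------------------------------------------------
    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for child in self._children.values():
            out.extend(child.parameters())
        return out

    def named_state(self, prefix: str = "") -> dict[str, np.ndarray]:
        """Flat name -> array map of parameters and buffers (checkpointing)."""
        state: dict[str, np.ndarray] = {}
        for name, p in self._params.items():
            state[prefix + name] = p.data
        for name, b in self._buffers.items():
            state[prefix + name] = b
        for name, child in self._children.items():
            state.update(child.named_state(prefix + name + "."))
        return state

    def load_state(self, state: dict[str, np.ndarray], prefix: str = ""):
        for name, p in self._params.items():
            p.data = np.array(state[prefix + name], dtype=p.data.dtype)
        for name, b in self._buffers.items():
            b[...] = state[prefix + name]
        for name, child in self._children.items():
            child.load_state(state, prefix + name + ".")

    def param_count(self) -> int:
        """Total parameters: trainable weights plus buffered statistics."""
        total = sum(p.data.size for p in self._params.values())
        total += sum(b.size for b in self._buffers.values())
        for child in self._children.values():
            total += child.param_count()
        return total

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self._list: list[Module] = []
        for m in modules:
            self.append(m)

    def append(self, module: Module):
        self._children[str(len(self._list))] = module
        self._list.append(module)

    def __getitem__(self, i) -> Module:
        return self._list[i]

    def __len__(self):
        return len(self._list)

    def __iter__(self):
        return iter(self._list)


class Conv2d(Module):
    """Biased stride-1 'same' convolution with He-normal initialization."""

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator):
        super().__init__()
        fan_in = c_in * kernel * kernel
        std = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(rng.normal(0.0, std, (c_out, c_in, kernel, kernel))
                             .astype(np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(c_out, dtype=np.float32),
                           requires_grad=True)

    def forward(self, x, training: bool = False):
        return ag.conv2d(x, self.weight, self.bias)


class ConvTranspose2d(Module):
    """Biased 2x2 stride-2 transpose convolution (learned 2x upsampling)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        std = np.sqrt(2.0 / (c_in * 4))
        self.weight = Tensor(rng.normal(0.0, std, (c_in, c_out, 2, 2))
                             .astype(np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(c_out, dtype=np.float32),
                           requires_grad=True)

    def forward(self, x, training: bool = False):
        return ag.conv_transpose2d(x, self.weight, self.bias)


class BatchNorm2d(Module):
    """Per-channel batch normalization.

    Carries four values per channel: learned scale and shift plus moving
    mean and variance, so a C-channel layer contributes 4C parameters to
    the model total.
    """

    def __init__(self, channels: int, momentum: float = 0.1,
                 eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(channels, dtype=np.float32),
                            requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=np.float32),
                           requires_grad=True)
        self.register_buffer("running_mean", np.zeros(channels, np.float32))
        self.register_buffer("running_var", np.ones(channels, np.float32))
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, training: bool = False):
        return ag.batch_norm2d(x, self.gamma, self.beta, self.running_mean,
                               self.running_var, training,
                               momentum=self.momentum, eps=self.eps)
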