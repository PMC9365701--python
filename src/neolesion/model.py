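"""U-Net family for two-channel slice segmentation.

Four variants are built from one declarative :class:`NetworkConfig`:

* plain modified U-Net — per block two biased 3x3 convolutions, each
  followed by batch normalization and ReLU; 2x2 max-pool downsampling;
  biased 2x2 stride-2 transpose-convolution upsampling; final biased 1x1
  convolution with sigmoid;
* U-Net + attention gates on the skip connections;
* U-Net with full pre-activation residual units in place of plain blocks;
* the combined residual attention-gate U-Net.

Residual units compute ``h(x) + F(x)`` with ``F = [BN -> ReLU -> 3x3
conv] x 2`` and ``h`` the identity when input and output widths match,
otherwise a biased 1x1 projection. Attention gates normalize both the skip
feature ``x`` and the coarser gating signal ``g`` (BN + ReLU), project each
by a 1x1 convolution to an intermediate width, add them on the coarse grid,
and squash to per-pixel coefficients alpha in (0,1) that rescale ``x``.

Parameter totals follow the framework convention of counting four values
per batch-normalized channel (scale, shift, moving mean, moving variance);
:func:`count_parameters` computes the total analytically and is checked
against the instantiated model.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .errors import ConfigurationError
from .nn import (BatchNorm2d, Conv2d, ConvTranspose2d, Module, ModuleList,
                 Tensor)
from .nn import autograd as ag

DEFAULT_FILTERS = (32, 64, 128, 256, 512)


@dataclasses.dataclass(frozen=True)
class NetworkConfig:
    """Declarative architecture description; fixes the parameter count."""

    in_channels: int = 2
    input_size: int = 512
    filters: tuple[int, ...] = DEFAULT_FILTERS
    block: str = "plain"          # "plain" | "residual"
    attention: bool = False

    @property
    def levels(self) -> int:
        return len(self.filters)

    def validate(self) -> "NetworkConfig":
        if self.in_channels < 1:
            raise ConfigurationError("in_channels must be >= 1")
        if self.levels < 2:
            raise ConfigurationError("need at least 2 resolution levels")
        if any(b >= a for a, b in zip(self.filters[1:], self.filters)):
            raise ConfigurationError(
                f"filter widths must be strictly increasing: {self.filters}")
        if self.block not in ("plain", "residual"):
            raise ConfigurationError(f"unknown block type {self.block!r}")
        stride = 2 ** (self.levels - 1)
        if self.input_size % stride:
            raise ConfigurationError(
                f"input_size {self.input_size} not divisible by {stride}")
        return self

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["filters"] = list(self.filters)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        d["filters"] = tuple(d["filters"])
        return cls(**d).validate()


# -------------------------------------------------------------------- blocks

class PlainBlock(Module):
    """[3x3 conv -> BN -> ReLU] x 2."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv2d(c_in, c_out, 3, rng)
        self.bn1 = BatchNorm2d(c_out)
        self.conv2 = Conv2d(c_out, c_out, 3, rng)
        self.bn2 = BatchNorm2d(c_out)

    def forward(self, x, training: bool = False):
        h = ag.relu(self.bn1(self.conv1(x), training))
        return ag.relu(self.bn2(self.conv2(h), training))


class ResidualUnit(Module):
    """Full pre-activation residual unit: h(x) + [BN->ReLU->conv] x 2.

    With the residual branch zeroed the unit is exactly its shortcut, so
    signal propagates through depth without degradation.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        self.bn1 = BatchNorm2d(c_in)
        self.conv1 = Conv2d(c_in, c_out, 3, rng)
        self.bn2 = BatchNorm2d(c_out)
        self.conv2 = Conv2d(c_out, c_out, 3, rng)
        self.projection = None
        if c_in != c_out:
            self.projection = Conv2d(c_in, c_out, 1, rng)

    def forward(self, x, training: bool = False):
        f = self.conv1(ag.relu(self.bn1(x, training)))
        f = self.conv2(ag.relu(self.bn2(f, training)))
        shortcut = self.projection(x) if self.projection is not None else x
        return ag.add(shortcut, f)


class AttentionGate(Module):
    """Additive attention over a skip connection.

    ``x`` (skip feature, fine grid) and ``g`` (gating signal from the level
    below, half resolution) each pass through BN + ReLU and a biased 1x1
    convolution to ``inter_channels``. The x branch is average-pooled onto
    g's grid, the branches are summed, passed through ReLU, a 1x1
    convolution to one channel and a sigmoid, giving coefficients alpha in
    (0,1) that are upsampled back to x's grid and multiply x elementwise.
    """

    def __init__(self, x_channels: int, g_channels: int, inter_channels: int,
                 rng: np.random.Generator):
        super().__init__()
        self.bn_x = BatchNorm2d(x_channels)
        self.bn_g = BatchNorm2d(g_channels)
        self.theta_x = Conv2d(x_channels, inter_channels, 1, rng)
        self.phi_g = Conv2d(g_channels, inter_channels, 1, rng)
        self.psi = Conv2d(inter_channels, 1, 1, rng)

    def attention_coefficients(self, x, g, training: bool = False):
        xa = self.theta_x(ag.relu(self.bn_x(x, training)))
        xa = ag.avg_pool2d(xa)
        ga = self.phi_g(ag.relu(self.bn_g(g, training)))
        alpha = ag.sigmoid(self.psi(ag.relu(ag.add(xa, ga))))
        return ag.upsample_nearest2d(alpha)

    def forward(self, x, g, training: bool = False):
        return ag.mul(x, self.attention_coefficients(x, g, training))


def build_residual_unit(c_in: int, c_out: int,
                        rng: np.random.Generator | None = None) -> ResidualUnit:
    if c_in < 1 or c_out < 1:
        raise ConfigurationError("channel counts must be >= 1")
    return ResidualUnit(c_in, c_out, rng or np.random.default_rng(0))


def build_attention_gate(x_channels: int, g_channels: int,
                         inter_channels: int,
                         rng: np.random.Generator | None = None) -> AttentionGate:
    if min(x_channels, g_channels, inter_channels) < 1:
        raise ConfigurationError("channel counts must be >= 1")
    return AttentionGate(x_channels, g_channels, inter_channels,
                         rng or np.random.default_rng(0))


# ------------------------------------------------------------------- network

def _make_block(block: str, c_in: int, c_out: int,
                rng: np.random.Generator) -> Module:
    if block == "plain":
        return PlainBlock(c_in, c_out, rng)
    return ResidualUnit(c_in, c_out, rng)


class UNet(Module):
    """Encoder-bridge-decoder segmentation network per NetworkConfig."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        f = cfg.filters
        depth = cfg.levels - 1
        self.encoder = ModuleList(
            _make_block(cfg.block, cfg.in_channels if i == 0 else f[i - 1],
                        f[i], rng)
            for i in range(depth))
        self.bridge = _make_block(cfg.block, f[depth - 1], f[depth], rng)
        self.ups = ModuleList(
            ConvTranspose2d(f[i + 1], f[i], rng) for i in range(depth))
        if cfg.attention:
            self.gates = ModuleList(
                AttentionGate(f[i], f[i + 1], max(1, f[i] // 2), rng)
                for i in range(depth))
        else:
            self.gates = ModuleList()
        self.decoder = ModuleList(
            _make_block(cfg.block, 2 * f[i], f[i], rng) for i in range(depth))
        self.head = Conv2d(f[0], 1, 1, rng)
        # prior-probability bias init: start predictions near the foreground
        # rate instead of 0.5, standard for heavily imbalanced segmentation
        prior = 0.01
        self.head.bias.data[:] = np.log(prior / (1.0 - prior))

    def forward(self, x, training: bool = False) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        depth = self.cfg.levels - 1
        skips = []
        h = x
        for block in self.encoder:
            h = block(h, training)
            skips.append(h)
            h = ag.max_pool2d(h)
        h = self.bridge(h, training)
        for i in reversed(range(depth)):
            g = h
            up = self.ups[i](h)
            skip = skips[i]
            if self.cfg.attention:
                skip = self.gates[i](skip, g, training)
            h = self.decoder[i](ag.concat_channels(up, skip), training)
        return ag.sigmoid(self.head(h))

    def predict(self, x: np.ndarray, batch_size: int = 8) -> np.ndarray:
        """Inference on (N, C, H, W) arrays; returns (N, 1, H, W) probs."""
        outs = []
        for start in range(0, len(x), batch_size):
            outs.append(self.forward(x[start:start + batch_size],
                                     training=False).data)
        return np.concatenate(outs, axis=0)


def build_network(cfg: NetworkConfig,
                  rng: np.random.Generator | None = None) -> UNet:
    return UNet(cfg, rng or np.random.default_rng(0))


# ---------------------------------------------------------- parameter counts

def _conv_params(c_in: int, c_out: int, k: int) -> int:
    return k * k * c_in * c_out + c_out


def _bn_params(channels: int) -> int:
    return 4 * channels


def _block_params(block: str, c_in: int, c_out: int) -> int:
    if block == "plain":
        return (_conv_params(c_in, c_out, 3) + _bn_params(c_out)
                + _conv_params(c_out, c_out, 3) + _bn_params(c_out))
    total = (_bn_params(c_in) + _conv_params(c_in, c_out, 3)
             + _bn_params(c_out) + _conv_params(c_out, c_out, 3))
    if c_in != c_out:
        total += _conv_params(c_in, c_out, 1)
    return total


def _gate_params(x_channels: int, g_channels: int, inter: int) -> int:
    return (_bn_params(x_channels) + _bn_params(g_channels)
            + _conv_params(x_channels, inter, 1)
            + _conv_params(g_channels, inter, 1)
            + _conv_params(inter, 1, 1))


def count_parameters(cfg: NetworkConfig) -> int:
    """Analytic total parameter count of :func:`build_network`'s output.

    Counts convolution weights and biases plus four values per
    batch-normalized channel; equals ``build_network(cfg).param_count()``.
    The count does not depend on ``input_size`` (the network is fully
    convolutional).
    """
    cfg.validate()
    f = cfg.filters
    depth = cfg.levels - 1
    total = 0
    for i in range(depth):
        total += _block_params(cfg.block,
                               cfg.in_channels if i == 0 else f[i - 1], f[i])
    total += _block_params(cfg.block, f[depth - 1], f[depth])
    for i in range(depth):
        total += 4 * f[i + 1] * f[i] + f[i]          # transpose conv
        if cfg.attention:
            total += _gate_params(f[i], f[i + 1], max(1, f[i] // 2))
        total += _block_params(cfg.block, 2 * f[i], f[i])
    total += _conv_params(f[0], 1, 1)                # sigmoid head
    return total


# ---------------------------------------------------------------- checkpoint

def save_checkpoint(model: UNet, path) -> None:
    """Save weights plus the serialized NetworkConfig for reload safety."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.named_state()
    np.savez_compressed(path, __config__=json.dumps(model.cfg.to_dict()),
                        **state)


def load_checkpoint(path) -> UNet:
    archive = np.load(Path(path), allow_pickle=False)
    cfg = NetworkConfig.from_dict(json.loads(str(archive["__config__"])))
    model = build_network(cfg)
    state = {k: archive[k] for k in archive.files if k != "__config__"}
    model.load_state(state)
    return model
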