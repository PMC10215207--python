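"""Densely connected 3D encoder-decoder segmentation network.

Topology (for ``depth`` stages):

* input block: double-conv block at full resolution;
* encoder stage s: double-conv block, then 2x max pooling;
* decoder stage t: trilinear 2x upsampling, concatenation with ALL
  encoder/input feature maps living at the target resolution, then a
  double-conv block;
* output block: pointwise (1x1x1) convolution to ``out_channels``
  followed by an elementwise sigmoid.

At full resolution two maps exist (input block and first encoder block),
and the last decoder concatenates both — the characteristic "Z"-shaped
reuse of earlier features.  Each double-conv block is
[Conv3d(k3,s1,p1) -> BatchNorm3d -> ReLU] twice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import nn


@dataclass
class ZnetConfig:
    """Architecture hyper-parameters.

    ``base_width`` is the channel count of the input block and first
    encoder stage; widths grow by ``width_multiplier`` per stage.
    """

    in_channels: int = 4
    out_channels: int = 3
    depth: int = 4
    base_width: int = 32
    width_multiplier: int = 2
    input_size: Tuple[int, int, int] = (128, 128, 128)

    def __post_init__(self):
        self.input_size = tuple(int(s) for s in self.input_size)
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.in_channels < 1 or self.out_channels < 1:
            raise ValueError("channel counts must be >= 1")
        if self.base_width < 1 or self.width_multiplier < 1:
            raise ValueError("width parameters must be >= 1")
        self.validate_input_size(self.input_size)

    def validate_input_size(self, size) -> None:
        divisor = 2 ** self.depth
        for dim in size:
            if dim % divisor != 0:
                raise ValueError(
                    f"input size {tuple(size)} not divisible by 2^depth={divisor}"
                )

    def stage_width(self, stage: int) -> int:
        """Channels of encoder stage ``stage`` (0-based; stage 0 = base_width)."""
        return self.base_width * self.width_multiplier ** stage


class ConvBlock(nn.Module):
    """Double [conv3(k3,s1,p1) -> batchnorm -> ReLU] unit; spatial dims preserved."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.body = nn.Sequential(
            nn.Conv3d(in_channels, out_channels, 3, rng=rng),
            nn.BatchNorm3d(out_channels),
            nn.ReLU(),
            nn.Conv3d(out_channels, out_channels, 3, rng=rng),
            nn.BatchNorm3d(out_channels),
            nn.ReLU(),
        )

    def forward(self, x, train=True):
        return self.body.forward(x, train=train)

    def backward(self, gy):
        return self.body.backward(gy)


def conv_block(in_channels: int, out_channels: int, seed: int = 0) -> ConvBlock:
    """Build one standalone double-conv block (mainly for tests/ablations)."""
    return ConvBlock(in_channels, out_channels, np.random.default_rng(seed))


def conv_block_param_count(in_channels: int, out_channels: int) -> int:
    """Closed-form trainable-parameter count of a double-conv block."""
    conv1 = 27 * in_channels * out_channels + out_channels
    conv2 = 27 * out_channels * out_channels + out_channels
    bn = 2 * (2 * out_channels)
    return conv1 + conv2 + bn


class Znet(nn.Module):
    """The assembled network; see the module docstring for the wiring."""

    def __init__(self, config: ZnetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        depth = config.depth
        widths = [config.stage_width(s) for s in range(depth)]

        self.input_block = ConvBlock(config.in_channels, widths[0], rng)
        self.encoders: List[ConvBlock] = []
        self.pools: List[nn.MaxPool3d] = []
        prev = widths[0]
        for s in range(depth):
            self.encoders.append(ConvBlock(prev, widths[s], rng))
            self.pools.append(nn.MaxPool3d())
            prev = widths[s]

        # decoder t targets resolution level (depth-1-t); its conv block sees
        # the upsampled channels plus every same-resolution skip map
        self.ups: List[nn.Upsample3d] = []
        self.decoders: List[ConvBlock] = []
        up_ch = widths[depth - 1]  # bottleneck channels (pooled deepest encoder)
        for t in range(depth):
            level = depth - 1 - t
            skip_ch = widths[level] + (widths[0] if level == 0 else 0)
            self.ups.append(nn.Upsample3d())
            self.decoders.append(ConvBlock(up_ch + skip_ch, widths[level], rng))
            up_ch = widths[level]
        self.output_conv = nn.Conv3d(widths[0], config.out_channels, 1, rng=rng)
        # negative prior on the sigmoid logits: foreground voxels are rare,
        # so starting near p~0.12 keeps early gradients focused on the lesion
        self.output_conv.bias.data[:] = -2.0
        self.output_act = nn.Sigmoid()

        self._skip_channels = None  # set during forward, used to split gradients

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """Forward pass; returns per-channel probabilities in (0, 1)."""
        if x.ndim != 5:
            raise ValueError(f"expected (N, C, D, H, W) input, got ndim={x.ndim}")
        if x.shape[1] != self.config.in_channels:
            raise ValueError(
                f"expected {self.config.in_channels} channels, got {x.shape[1]}"
            )
        self.config.validate_input_size(x.shape[2:])
        x = np.ascontiguousarray(x, dtype=np.float32)

        depth = self.config.depth
        f0 = self.input_block.forward(x, train=train)
        enc_outs = []
        cur = f0
        for s in range(depth):
            e = self.encoders[s].forward(cur, train=train)
            enc_outs.append(e)
            cur = self.pools[s].forward(e, train=train)

        self._skip_channels = []
        for t in range(depth):
            level = depth - 1 - t
            up = self.ups[t].forward(cur, train=train)
            skips = [enc_outs[level]] + ([f0] if level == 0 else [])
            self._skip_channels.append(
                (up.shape[1], [s.shape[1] for s in skips])
            )
            cur = self.decoders[t].forward(
                np.concatenate([up] + skips, axis=1), train=train
            )

        logits = self.output_conv.forward(cur, train=train)
        return self.output_act.forward(logits, train=train)

    def backward(self, glogits: np.ndarray) -> None:
        """Backward pass from the gradient w.r.t. the pre-sigmoid logits.

        The training loop fuses sigmoid and binary cross-entropy, whose
        combined gradient is (p - t) / M, so the sigmoid layer itself is
        bypassed here.
        """
        depth = self.config.depth
        g = self.output_conv.backward(glogits)
        gskip_enc = [None] * depth
        gskip_f0 = None
        for t in reversed(range(depth)):
            level = depth - 1 - t
            gcat = self.decoders[t].backward(g)
            up_ch, skip_chs = self._skip_channels[t]
            pieces = np.split(gcat, np.cumsum([up_ch] + skip_chs)[:-1], axis=1)
            gup = pieces[0]
            genc = pieces[1]
            gskip_enc[level] = (
                genc if gskip_enc[level] is None else gskip_enc[level] + genc
            )
            if level == 0:
                gskip_f0 = pieces[2]
            g = self.ups[t].backward(np.ascontiguousarray(gup))
        for s in reversed(range(depth)):
            g = self.pools[s].backward(g)
            if gskip_enc[s] is not None:
                g = g + gskip_enc[s]
            g = self.encoders[s].backward(np.ascontiguousarray(g))
        if gskip_f0 is not None:
            g = g + gskip_f0
        self.input_block.backward(np.ascontiguousarray(g))
        self._skip_channels = None


def build_znet(config: ZnetConfig, seed: int = 0) -> Znet:
    """Construct a network with seeded, deterministic initialization."""
    return Znet(config, seed=seed)


# -- summary ----------------------------------------------------------------


@dataclass
class NetworkSummary:
    """Per-block output shapes (symbolic) and total trainable parameters."""

    block_shapes: Dict[str, Tuple[int, ...]] = field(default_factory=dict)
    total_parameters: int = 0

    def __str__(self) -> str:
        lines = [f"{name:24s} {shape}" for name, shape in self.block_shapes.items()]
        lines.append(f"total parameters: {self.total_parameters}")
        return "\n".join(lines)


def summarize(model: Znet, config: Optional[ZnetConfig] = None) -> NetworkSummary:
    """Walk the architecture symbolically and report shapes + parameter total."""
    config = config or model.config
    depth = config.depth
    d, h, w = config.input_size
    shapes: Dict[str, Tuple[int, ...]] = {}
    widths = [config.stage_width(s) for s in range(depth)]
    shapes["input_block"] = (widths[0], d, h, w)
    for s in range(depth):
        shapes[f"encoder_{s + 1}"] = (widths[s], d >> s, h >> s, w >> s)
        shapes[f"pool_{s + 1}"] = (widths[s], d >> (s + 1), h >> (s + 1), w >> (s + 1))
    for t in range(depth):
        level = depth - 1 - t
        shapes[f"decoder_{t + 1}"] = (widths[level], d >> level, h >> level, w >> level)
    shapes["output_block"] = (config.out_channels, d, h, w)
    return NetworkSummary(block_shapes=shapes, total_parameters=model.num_parameters())


# -- checkpointing ----------------------------------------------------------


def _named_parameters(model: Znet):
    return [(f"p{i}", p) for i, p in enumerate(model.parameters())]


def _named_bn_stats(model: Znet):
    out = []

    def visit(value):
        if isinstance(value, nn.BatchNorm3d):
            out.append((f"bn{len(out)}", value))
        elif isinstance(value, nn.Module):
            for child in vars(value).values():
                visit(child)
        elif isinstance(value, (list, tuple)):
            for item in value:
                visit(item)

    visit(model)
    return out


def save_checkpoint(model: Znet, path) -> None:
    """Serialize weights, batch-norm statistics and config to one .npz file."""
    arrays = {name: p.data for name, p in _named_parameters(model)}
    for name, bn in _named_bn_stats(model):
        arrays[f"{name}_mean"] = bn.running_mean
        arrays[f"{name}_var"] = bn.running_var
    arrays["config_json"] = np.frombuffer(
        json.dumps(asdict(model.config)).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path) -> Znet:
    with np.load(path) as data:
        cfg_dict = json.loads(bytes(data["config_json"]).decode())
        config = ZnetConfig(**cfg_dict)
        model = Znet(config, seed=0)
        for name, p in _named_parameters(model):
            p.data[...] = data[name]
        for name, bn in _named_bn_stats(model):
            bn.running_mean[...] = data[f"{name}_mean"]
            bn.running_var[...] = data[f"{name}_var"]
    return model
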