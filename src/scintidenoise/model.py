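"""Channel-attention convolutional autoencoder for scintigraphy denoising.

Architecture, per encoder stage: a multi-scale feature block (parallel
3x3 and 5x5 convolutions, channel-concatenated and fused by a 1x1
convolution, Group Normalization, ReLU), squeeze-style channel attention
(global average pooling -> bottlenecked fully connected pair -> sigmoid
gates), and a stride-2 3x3 convolution for downsampling. A 1x1
convolutional bottleneck halves the channel count (ReLU). Each decoder
stage is a transposed convolution (kernel 4, stride 2, padding 1 — exact
spatial doubling, no checkerboard) followed by efficient residual blocks
(depthwise 3x3 + pointwise 1x1 + Group Normalization + ReLU inside an
identity skip). A final 3x3 convolution produces the single-channel
output, mapped to [0, 1] by a sigmoid (or clamped, if configured).

Parameters live in a flat name->Tensor dictionary so the training loop,
checkpointing and parameter counting stay trivial.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .dataio import NormalizedImage
from .errors import ConfigurationError, ShapeError
from .nn import Tensor

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class ModelConfig:
    encoder_widths: tuple[int, ...] = (32, 64)
    n_downsamples: int = 2
    attention_reduction: int = 8
    gn_groups: int = 8
    erb_per_stage: int = 1
    msfb_kernels: tuple[int, int] = (3, 5)
    final_kernel: int = 3
    output_activation: str = "sigmoid"
    init_seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "encoder_widths",
                           tuple(int(w) for w in self.encoder_widths))
        if tuple(self.msfb_kernels) != (3, 5):
            raise ConfigurationError(
                "msfb_kernels is fixed to (3, 5); larger kernels oversmooth "
                "fine skeletal structures")
        if self.n_downsamples != len(self.encoder_widths):
            raise ConfigurationError(
                "n_downsamples must equal len(encoder_widths)")
        if self.output_activation not in ("sigmoid", "clamp"):
            raise ConfigurationError(
                f"unknown output_activation {self.output_activation!r}")
        if self.erb_per_stage < 1:
            raise ConfigurationError("erb_per_stage must be >= 1")
        for w in self.encoder_widths:
            if w % 2:
                raise ConfigurationError(f"encoder width {w} must be even "
                                         "(two equal MSFB branches)")
            if w % self.gn_groups:
                raise ConfigurationError(
                    f"width {w} not divisible by gn_groups {self.gn_groups}")
            if w % self.attention_reduction:
                raise ConfigurationError(
                    f"width {w} not divisible by attention_reduction "
                    f"{self.attention_reduction}")
        for w in self.decoder_widths:
            if w % self.gn_groups:
                raise ConfigurationError(
                    f"decoder width {w} not divisible by gn_groups "
                    f"{self.gn_groups}")

    @property
    def decoder_widths(self) -> tuple[int, ...]:
        """Mirror of the encoder at half width (post-bottleneck budget)."""
        return tuple(w // 2 for w in reversed(self.encoder_widths))

    @property
    def bottleneck_channels(self) -> int:
        return self.encoder_widths[-1] // 2

    @property
    def spatial_divisor(self) -> int:
        return 2 ** self.n_downsamples


@dataclass
class ModelParameters:
    """Flat named weight collection; shapes fixed by the configuration."""
    tensors: dict[str, Tensor]
    config: ModelConfig

    def sub(self, prefix: str) -> dict[str, Tensor]:
        pre = prefix + "."
        return {k[len(pre):]: v for k, v in self.tensors.items()
                if k.startswith(pre)}

    def copy_data(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.tensors.items()}

    def load_data(self, blobs: dict[str, np.ndarray]) -> None:
        for k, v in self.tensors.items():
            v.data = np.array(blobs[k], dtype=np.float64)


def count_parameters(params: ModelParameters) -> int:
    """Exact number of scalar learnables."""
    return int(sum(t.size for t in params.tensors.values()))


# --------------------------------------------------------------------------
# initialization

def _kaiming(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape)


def _conv_init(rng, c_out, c_in, kh, kw):
    return _kaiming(rng, (c_out, c_in, kh, kw), c_in * kh * kw)


def init_msfb(rng, c_in: int, c_out: int) -> dict[str, np.ndarray]:
    if c_out % 2:
        raise ConfigurationError(f"MSFB out_channels must be even, got {c_out}")
    half = c_out // 2
    return {
        "b3.w": _conv_init(rng, half, c_in, 3, 3), "b3.b": np.zeros(half),
        "b5.w": _conv_init(rng, half, c_in, 5, 5), "b5.b": np.zeros(half),
        "fuse.w": _conv_init(rng, c_out, c_out, 1, 1), "fuse.b": np.zeros(c_out),
        "gn.gamma": np.ones(c_out), "gn.beta": np.zeros(c_out),
    }


def init_attention(rng, channels: int, reduction: int) -> dict[str, np.ndarray]:
    if channels % reduction:
        raise ConfigurationError(
            f"channels {channels} not divisible by reduction {reduction}")
    hidden = channels // reduction
    return {
        "fc1.w": _kaiming(rng, (channels, hidden), channels),
        "fc1.b": np.zeros(hidden),
        "fc2.w": _kaiming(rng, (hidden, channels), hidden),
        "fc2.b": np.zeros(channels),
    }


def init_downsample(rng, channels: int) -> dict[str, np.ndarray]:
    return {"w": _conv_init(rng, channels, channels, 3, 3),
            "b": np.zeros(channels),
            "gn.gamma": np.ones(channels), "gn.beta": np.zeros(channels)}


def init_bottleneck(rng, c_in: int) -> dict[str, np.ndarray]:
    if c_in < 2:
        raise ConfigurationError("bottleneck needs at least 2 input channels")
    half = c_in // 2
    return {"w": _conv_init(rng, half, c_in, 1, 1), "b": np.zeros(half)}


def init_erb(rng, channels: int) -> dict[str, np.ndarray]:
    return {
        "dw.w": _conv_init(rng, channels, 1, 3, 3), "dw.b": np.zeros(channels),
        "pw.w": _conv_init(rng, channels, channels, 1, 1),
        "pw.b": np.zeros(channels),
        "gn.gamma": np.ones(channels), "gn.beta": np.zeros(channels),
    }


def init_upsample(rng, c_in: int, c_out: int) -> dict[str, np.ndarray]:
    # transposed-conv weight layout (C_in, C_out, 4, 4)
    return {"w": _kaiming(rng, (c_in, c_out, 4, 4), c_in * 16),
            "b": np.zeros(c_out),
            "gn.gamma": np.ones(c_out), "gn.beta": np.zeros(c_out)}


def init_parameters(config: ModelConfig) -> ModelParameters:
    """Seeded Kaiming-uniform (fan-in) initialization of all layers."""
    rng = np.random.default_rng(config.init_seed)
    blobs: dict[str, np.ndarray] = {}

    def add(prefix: str, d: dict[str, np.ndarray]) -> None:
        for k, v in d.items():
            blobs[f"{prefix}.{k}"] = v

    c_in = 1
    for i, width in enumerate(config.encoder_widths):
        add(f"enc{i}.msfb", init_msfb(rng, c_in, width))
        add(f"enc{i}.att", init_attention(rng, width,
                                          config.attention_reduction))
        add(f"enc{i}.down", init_downsample(rng, width))
        c_in = width
    add("bottleneck", init_bottleneck(rng, c_in))
    c_in = config.bottleneck_channels
    for i, width in enumerate(config.decoder_widths):
        add(f"dec{i}.up", init_upsample(rng, c_in, width))
        for j in range(config.erb_per_stage):
            add(f"dec{i}.erb{j}", init_erb(rng, width))
        c_in = width
    blobs["final.w"] = _conv_init(rng, 1, c_in,
                                  config.final_kernel, config.final_kernel)
    blobs["final.b"] = np.zeros(1)

    tensors = {k: Tensor(v, requires_grad=True) for k, v in blobs.items()}
    return ModelParameters(tensors=tensors, config=config)


# --------------------------------------------------------------------------
# blocks (functional; p is the block's local parameter dict)

def msfb(x: Tensor, p: dict[str, Tensor], gn_groups: int) -> Tensor:
    """Multi-scale feature block: parallel 3x3/5x5, concat, 1x1 fuse, GN, ReLU."""
    y3 = nn.conv2d(x, p["b3.w"], p["b3.b"], padding=1)
    y5 = nn.conv2d(x, p["b5.w"], p["b5.b"], padding=2)
    y = nn.conv2d(nn.concat([y3, y5], axis=1), p["fuse.w"], p["fuse.b"])
    y = nn.group_norm(y, p["gn.gamma"], p["gn.beta"], groups=gn_groups)
    return y.relu()


def channel_attention(x: Tensor, p: dict[str, Tensor]) -> Tensor:
    """GAP -> FC (reduce) -> ReLU -> FC (expand) -> sigmoid gates, applied per channel."""
    n, c = x.shape[0], x.shape[1]
    if p["fc1.w"].shape[0] != c:
        raise ConfigurationError(
            f"attention expects {p['fc1.w'].shape[0]} channels, got {c}")
    desc = nn.global_avg_pool(x)                       # (N, C)
    hid = nn.linear(desc, p["fc1.w"], p["fc1.b"]).relu()
    gates = nn.linear(hid, p["fc2.w"], p["fc2.b"]).sigmoid()
    return x * gates.reshape(n, c, 1, 1)


def downsample(x: Tensor, p: dict[str, Tensor], gn_groups: int) -> Tensor:
    """Stride-2 3x3 convolution halving each spatial dimension, GN, ReLU."""
    if x.shape[2] % 2 or x.shape[3] % 2:
        raise ShapeError(f"downsample requires even spatial dims, "
                         f"got {x.shape[2]}x{x.shape[3]}")
    y = nn.conv2d(x, p["w"], p["b"], stride=2, padding=1)
    y = nn.group_norm(y, p["gn.gamma"], p["gn.beta"], groups=gn_groups)
    return y.relu()


def bottleneck(x: Tensor, p: dict[str, Tensor]) -> Tensor:
    """1x1 convolution halving the channel count, then ReLU."""
    if x.shape[1] < 2:
        raise ConfigurationError("bottleneck needs at least 2 channels")
    return nn.conv2d(x, p["w"], p["b"]).relu()


def erb(x: Tensor, p: dict[str, Tensor], gn_groups: int) -> Tensor:
    """Efficient residual block: depthwise 3x3 + pointwise 1x1 + GN + ReLU, skip-added."""
    c = x.shape[1]
    y = nn.conv2d(x, p["dw.w"], p["dw.b"], padding=1, groups=c)
    y = nn.conv2d(y, p["pw.w"], p["pw.b"])
    y = nn.group_norm(y, p["gn.gamma"], p["gn.beta"], groups=gn_groups)
    return x + y.relu()


def upsample(x: Tensor, p: dict[str, Tensor], gn_groups: int) -> Tensor:
    """Transposed convolution (k=4, s=2, p=1) exactly doubling spatial dims."""
    y = nn.conv_transpose2d(x, p["w"], p["b"], stride=2, padding=1)
    y = nn.group_norm(y, p["gn.gamma"], p["gn.beta"], groups=gn_groups)
    return y.relu()


# --------------------------------------------------------------------------
# full forward pass

def forward_batch(params: ModelParameters, x: Tensor) -> Tensor:
    """Forward an (N, 1, H, W) tensor; returns (N, 1, H, W) in [0, 1]."""
    cfg = params.config
    div = cfg.spatial_divisor
    if x.shape[2] % div or x.shape[3] % div:
        raise ShapeError(
            f"input {x.shape[2]}x{x.shape[3]} must be divisible by {div} "
            f"({cfg.n_downsamples} downsampling stages)")
    y = x
    for i in range(cfg.n_downsamples):
        y = msfb(y, params.sub(f"enc{i}.msfb"), cfg.gn_groups)
        y = channel_attention(y, params.sub(f"enc{i}.att"))
        y = downsample(y, params.sub(f"enc{i}.down"), cfg.gn_groups)
    y = bottleneck(y, params.sub("bottleneck"))
    for i in range(len(cfg.decoder_widths)):
        y = upsample(y, params.sub(f"dec{i}.up"), cfg.gn_groups)
        for j in range(cfg.erb_per_stage):
            y = erb(y, params.sub(f"dec{i}.erb{j}"), cfg.gn_groups)
    pad = cfg.final_kernel // 2
    y = nn.conv2d(y, params.tensors["final.w"], params.tensors["final.b"],
                  padding=pad)
    if cfg.output_activation == "sigmoid":
        return y.sigmoid()
    data = np.clip(y.data, 0.0, 1.0)
    mask = (y.data > 0.0) & (y.data < 1.0)
    return nn.tensor.from_op(data, (y,), lambda g: (g * mask,))


def forward(params: ModelParameters, config: ModelConfig,
            image: NormalizedImage) -> NormalizedImage:
    """Denoise a single normalized image (deterministic given params)."""
    if config is not params.config and config != params.config:
        raise ConfigurationError("config does not match parameters")
    x = Tensor(image.values[None, None, :, :])
    with nn.no_grad():
        y = forward_batch(params, x)
    return NormalizedImage(np.clip(y.data[0, 0], 0.0, 1.0),
                           dose_fraction=image.dose_fraction)


# --------------------------------------------------------------------------
# checkpointing

def save_checkpoint(path: str | Path, params: ModelParameters, *,
                    train_seed: int | None = None,
                    history: dict | None = None) -> None:
    meta = {"version": CHECKPOINT_VERSION,
            "config": asdict(params.config),
            "train_seed": train_seed,
            "history": history}
    arrays = {f"param::{k}": v.data for k, v in params.tensors.items()}
    np.savez(Path(path), __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> tuple[ModelParameters, dict]:
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if "version" not in meta:
            raise ConfigurationError("checkpoint missing version field")
        cfg_d = meta["config"]
        for key in ("encoder_widths", "msfb_kernels"):
            cfg_d[key] = tuple(cfg_d[key])
        config = ModelConfig(**cfg_d)
        params = init_parameters(config)
        params.load_data({k[len("param::"):]: data[k]
                          for k in data.files if k.startswith("param::")})
    return params, meta
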