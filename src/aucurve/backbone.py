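"""3D-ResNet-18 spatiotemporal encoder.

The encoder consumes fixed-size clips (default 16 frames at 112x112) and
produces one feature vector per clip via global average pooling. Layout:

* conv1: 3x7x7, stride 1x2x2 (temporal length preserved, spatial halved),
  batch norm + ReLU, no max-pool (the first residual stage operates at the
  conv1 resolution).
* four residual stages of two blocks each; every block is two 3x3x3
  convolutions with batch normalisation and ReLU and an identity shortcut.
  Stages 2-4 downsample time and space by 2 using a stride-2 first block
  with a 1x1x1 projection shortcut.
* global average pooling over (T, H, W) yields the clip feature (512-dim
  at the default widths).

For a 16x112x112 input the per-stage output sizes are 16x56x56, 16x56x56,
8x28x28, 4x14x14 and 2x7x7.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .nn.layers import (
    BatchNorm3d,
    Conv3d,
    GlobalAvgPool3d,
    Param,
    ReLU,
    ResBlock3d,
    Sequential,
)
from .preprocess import FrameClip

__all__ = ["BackboneConfig", "Backbone3D", "build_backbone", "backbone_forward", "clip_to_batch"]


@dataclass(frozen=True)
class BackboneConfig:
    input_len: int = 16
    input_size: int = 112
    in_channels: int = 3
    #: conv1 width followed by the four residual-stage widths.
    channels: tuple[int, int, int, int, int] = (64, 64, 128, 256, 512)
    conv1_kernel: tuple[int, int, int] = (3, 7, 7)
    conv1_stride: tuple[int, int, int] = (1, 2, 2)
    #: stride of the first block of each residual stage (applied to T, H, W).
    stage_strides: tuple[int, int, int, int] = (1, 2, 2, 2)
    blocks_per_stage: int = 2

    def __post_init__(self):
        if len(self.channels) != 5:
            raise ValueError("channels must list conv1 plus 4 residual stages")
        if len(self.stage_strides) != 4:
            raise ValueError("stage_strides must have 4 entries")
        if any(c < 1 for c in self.channels) or any(s < 1 for s in self.stage_strides):
            raise ValueError("channels and strides must be positive")

    @property
    def feature_dim(self) -> int:
        return self.channels[-1]

    def to_json(self) -> str:
        return json.dumps({
            "input_len": self.input_len, "input_size": self.input_size,
            "in_channels": self.in_channels, "channels": list(self.channels),
            "conv1_kernel": list(self.conv1_kernel),
            "conv1_stride": list(self.conv1_stride),
            "stage_strides": list(self.stage_strides),
            "blocks_per_stage": self.blocks_per_stage,
        })

    @classmethod
    def from_json(cls, s: str) -> "BackboneConfig":
        d = json.loads(s)
        return cls(
            input_len=d["input_len"], input_size=d["input_size"],
            in_channels=d["in_channels"], channels=tuple(d["channels"]),
            conv1_kernel=tuple(d["conv1_kernel"]),
            conv1_stride=tuple(d["conv1_stride"]),
            stage_strides=tuple(d["stage_strides"]),
            blocks_per_stage=d["blocks_per_stage"],
        )


class Backbone3D:
    """The residual spatiotemporal encoder; see module docstring."""

    def __init__(self, config: BackboneConfig | None = None, seed: int = 42):
        self.config = config or BackboneConfig()
        rng = np.random.default_rng(seed)
        c = self.config
        k = c.conv1_kernel
        pad = tuple(x // 2 for x in k)
        self.stem = Sequential(
            Conv3d(c.in_channels, c.channels[0], k, stride=c.conv1_stride,
                   padding=pad, rng=rng),
            BatchNorm3d(c.channels[0]),
            ReLU(),
        )
        self.stages: list[Sequential] = []
        in_ch = c.channels[0]
        for s in range(4):
            out_ch = c.channels[s + 1]
            blocks = [ResBlock3d(in_ch, out_ch, stride=c.stage_strides[s], rng=rng)]
            for _ in range(c.blocks_per_stage - 1):
                blocks.append(ResBlock3d(out_ch, out_ch, stride=1, rng=rng))
            self.stages.append(Sequential(*blocks))
            in_ch = out_ch
        self.pool = GlobalAvgPool3d()

    # -- parameters and persistent state -----------------------------------
    def params(self) -> list[Param]:
        ps = self.stem.params()
        for st in self.stages:
            ps += st.params()
        return ps

    def _bn_layers(self):
        def walk(layer):
            if isinstance(layer, BatchNorm3d):
                yield layer
            elif isinstance(layer, Sequential):
                for l in layer.layers:
                    yield from walk(l)
            elif isinstance(layer, ResBlock3d):
                yield layer.bn1
                yield layer.bn2
                if layer.proj is not None:
                    yield from walk(layer.proj)
        yield from walk(self.stem)
        for st in self.stages:
            yield from walk(st)

    # -- forward / backward --------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Encode a batch (N, C, T, H, W) into (N, feature_dim) features."""
        c = self.config
        if x.ndim != 5 or x.shape[1] != c.in_channels:
            raise ValueError(
                f"expected (N,{c.in_channels},T,H,W) input, got shape {x.shape}")
        x = self.stem.forward(x.astype(np.float32), train)
        for st in self.stages:
            x = st.forward(x, train)
        return self.pool.forward(x, train)

    def backward(self, dfeat: np.ndarray) -> np.ndarray:
        d = self.pool.backward(dfeat)
        for st in reversed(self.stages):
            d = st.backward(d)
        return self.stem.backward(d)

    def forward_trace(self, x: np.ndarray) -> list[tuple[int, ...]]:
        """Shapes (C, T, H, W) after conv1 and after each residual stage."""
        shapes = []
        x = self.stem.forward(x.astype(np.float32))
        shapes.append(tuple(x.shape[1:]))
        for st in self.stages:
            x = st.forward(x)
            shapes.append(tuple(x.shape[1:]))
        return shapes

    # -- checkpointing -------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {f"param_{i:04d}": p.data for i, p in enumerate(self.params())}
        for i, bn in enumerate(self._bn_layers()):
            state[f"bn_mean_{i:04d}"] = bn.running_mean
            state[f"bn_var_{i:04d}"] = bn.running_var
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            arr = state[f"param_{i:04d}"]
            if arr.shape != p.data.shape:
                raise ValueError(f"checkpoint shape mismatch at param {i}: "
                                 f"{arr.shape} vs {p.data.shape}")
            p.data = arr.astype(np.float32)
        for i, bn in enumerate(self._bn_layers()):
            bn.running_mean = state[f"bn_mean_{i:04d}"].astype(np.float32)
            bn.running_var = state[f"bn_var_{i:04d}"].astype(np.float32)

    def save(self, path) -> None:
        np.savez(path, config_json=np.array(self.config.to_json()), **self.state_arrays())

    @classmethod
    def load(cls, path) -> "Backbone3D":
        with np.load(path) as z:
            config = BackboneConfig.from_json(str(z["config_json"]))
            model = cls(config)
            model.load_state_arrays({k: z[k] for k in z.files if k != "config_json"})
        return model


def build_backbone(config: BackboneConfig | None = None, seed: int = 42) -> Backbone3D:
    """Build a seeded backbone (two builds with one seed share all weights)."""
    return Backbone3D(config, seed=seed)


def clip_to_batch(clip: FrameClip, in_channels: int = 3) -> np.ndarray:
    """Convert a FrameClip to a (1, C, T, H, W) batch, replicating grayscale
    frames across channels when the backbone expects RGB."""
    arr = clip.frames.transpose(3, 0, 1, 2)[None]  # (1, C, T, H, W)
    if arr.shape[1] == 1 and in_channels == 3:
        arr = np.repeat(arr, 3, axis=1)
    if arr.shape[1] != in_channels:
        raise ValueError(f"clip has {arr.shape[1]} channels, backbone expects {in_channels}")
    return arr.astype(np.float32)


def backbone_forward(model: Backbone3D, clip: FrameClip) -> np.ndarray:
    """Inference-mode feature for one preprocessed clip (length feature_dim)."""
    c = model.config
    if clip.n_frames != c.input_len or clip.shape[1] != c.input_size or clip.shape[2] != c.input_size:
        raise ValueError(
            f"expected clip of shape ({c.input_len},{c.input_size},{c.input_size}), "
            f"got ({clip.n_frames},{clip.shape[1]},{clip.shape[2]})")
    return model.forward(clip_to_batch(clip, c.in_channels))[0]
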