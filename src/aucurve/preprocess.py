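"""Clip loading and normalisation to the fixed size the backbone expects.

A clip is a stack of frames (T, H, W, C) with intensities in [0, 1]. Two
normalisation steps bring heterogeneous input videos onto the backbone's
input grid: temporal resampling to a fixed frame count (linear interpolation
at uniformly spaced positions, standing in for manifold-based temporal
interpolation models) and spatial resizing plus per-clip standardisation.
Spatial resizing happens before temporal resampling purely for
reproducibility; the two per-pixel linear operations commute.

Frame indexing is 0-based; frame ``f`` of a ``T``-frame clip sits at
normalized time ``f / (T - 1)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["FrameClip", "load_clip", "tim_resample", "spatial_normalize"]

_FRAME_RE = re.compile(r"(\d+)\.(png|jpg|jpeg)$", re.IGNORECASE)


@dataclass
class FrameClip:
    """A T*H*W*C stack of frames.

    ``normalized`` marks clips that went through :func:`spatial_normalize`
    (zero mean / unit variance, so no longer confined to [0, 1]).
    """

    frames: np.ndarray
    fps: float = 200.0
    normalized: bool = field(default=False, compare=False)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float32)
        if self.frames.ndim == 3:  # (T, H, W) grayscale
            self.frames = self.frames[..., None]
        if self.frames.ndim != 4:
            raise ValueError(f"frames must be (T,H,W,C), got shape {self.frames.shape}")
        T, H, W, C = self.frames.shape
        if T < 1:
            raise ValueError("clip needs at least one frame")
        if C not in (1, 3):
            raise ValueError(f"channel count must be 1 or 3, got {C}")
        if not self.normalized:
            lo, hi = float(self.frames.min()), float(self.frames.max())
            if lo < -1e-6 or hi > 1 + 1e-6:
                raise ValueError(f"frame values outside [0,1]: range [{lo}, {hi}]")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.frames.shape


def load_clip(path, fps: float = 200.0) -> FrameClip:
    """Load a clip from a frame directory (``frame_0000.png`` ...) or an
    ``.npy``/``.npz`` array file; values are scaled to [0, 1]."""
    import imageio.v3 as iio

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_file():
        if path.suffix == ".npy":
            arr = np.load(path)
        elif path.suffix == ".npz":
            with np.load(path) as z:
                arr = z[z.files[0]]
        else:
            raise ValueError(f"unsupported clip file format: {path.suffix}")
        arr = np.asarray(arr, dtype=np.float32)
        if arr.max() > 1.0 + 1e-6:
            arr = arr / 255.0
        return FrameClip(arr, fps=fps)

    entries = []
    for p in path.iterdir():
        m = _FRAME_RE.search(p.name)
        if m:
            entries.append((int(m.group(1)), p))
    if not entries:
        raise ValueError(f"no frame images found in {path}")
    entries.sort(key=lambda e: e[0])
    frames = []
    shape = None
    for _, p in entries:
        img = iio.imread(p)
        if shape is None:
            shape = img.shape
        elif img.shape != shape:
            raise ValueError(f"mixed frame shapes in {path}: {shape} vs {img.shape} ({p.name})")
        frames.append(img)
    raw = np.stack(frames)
    if np.issubdtype(raw.dtype, np.integer):
        stack = raw.astype(np.float32) / np.float32(np.iinfo(raw.dtype).max)
    else:
        stack = raw.astype(np.float32)
        if stack.max() > 1.0 + 1e-6:
            stack = stack / 255.0
    return FrameClip(stack, fps=fps)


def tim_resample(clip: FrameClip, target_len: int) -> FrameClip:
    """Resample a clip to exactly ``target_len`` frames.

    Each output frame is a convex combination of the two temporally nearest
    input frames at uniformly spaced positions; the first and last output
    frames equal the first and last input frames.
    """
    if target_len < 1:
        raise ValueError(f"target_len must be >= 1, got {target_len}")
    T = clip.n_frames
    if T == 1:
        if target_len != 1:
            raise ValueError("cannot resample a single-frame clip to more frames")
        return FrameClip(clip.frames.copy(), fps=clip.fps, normalized=clip.normalized)
    if target_len == 1:
        pos = np.array([(T - 1) / 2.0])
    else:
        pos = np.linspace(0.0, T - 1, target_len)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, T - 1)
    w = (pos - lo).astype(np.float32)[:, None, None, None]
    out = (1.0 - w) * clip.frames[lo] + w * clip.frames[hi]
    return FrameClip(out, fps=clip.fps, normalized=clip.normalized)


def spatial_normalize(clip: FrameClip, size: int = 112, eps: float = 1e-8) -> FrameClip:
    """Resize frames to ``size`` x ``size`` and standardise the clip to zero
    mean and unit variance (constant clips map to all-zeros)."""
    from skimage.transform import resize

    if size < 8:
        raise ValueError(f"size must be >= 8, got {size}")
    T, H, W, C = clip.shape
    if (H, W) == (size, size):
        frames = clip.frames.astype(np.float64)
    else:
        frames = resize(
            clip.frames.astype(np.float64), (T, size, size, C),
            order=1, mode="edge", anti_aliasing=(H > size), preserve_range=True,
        )
    mean = frames.mean()
    std = frames.std()
    if std < eps:
        out = np.zeros_like(frames)
    else:
        out = (frames - mean) / std
    return FrameClip(out.astype(np.float32), fps=clip.fps, normalized=True)
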