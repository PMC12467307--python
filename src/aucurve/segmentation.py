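"""Temporal segmentation heads and the combined spotting loss.

Two parallel linear maps sit on the clip feature: a timestamp head whose
output is squashed through a sigmoid into [0, 1] (predicted normalized onset
and offset), and a category head producing expression-class logits. The
training objective combines three terms,

    L = L_cls + lambda1 * L_reg + lambda2 * L_order,

with L_cls the categorical cross-entropy on the class logits, L_reg the
squared error on both timestamps, and L_order = max(0, y_start - y_end), a
hinge that penalises predictions whose onset falls after their offset.
Defaults lambda1 = 0.5, lambda2 = 0.1. The category term can be switched off
(cls_weight = 0) for purely temporal spotting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn.tensor import Tensor

__all__ = [
    "SegmentationLabel",
    "SegmentationPrediction",
    "SegLossConfig",
    "SegmentationHead",
    "predict_timestamps",
    "segmentation_loss",
    "segmentation_loss_t",
    "timestamps_to_frames",
]


@dataclass(frozen=True)
class SegmentationLabel:
    t_start: float
    t_end: float
    category: int

    def __post_init__(self):
        if not (0.0 <= self.t_start <= 1.0 and 0.0 <= self.t_end <= 1.0):
            raise ValueError(f"timestamps must lie in [0,1], got ({self.t_start}, {self.t_end})")
        if self.t_start > self.t_end:
            raise ValueError("ground-truth onset must not exceed offset")


@dataclass
class SegmentationPrediction:
    y_start: float
    y_end: float
    class_logits: np.ndarray

    def __post_init__(self):
        self.class_logits = np.asarray(self.class_logits, dtype=np.float64)
        for v in (self.y_start, self.y_end):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"predicted timestamp outside [0,1]: {v}")

    @property
    def class_probs(self) -> np.ndarray:
        z = self.class_logits - self.class_logits.max()
        e = np.exp(z)
        return e / e.sum()


@dataclass(frozen=True)
class SegLossConfig:
    lambda1: float = 0.5   # regression weight
    lambda2: float = 0.1   # order-constraint weight
    cls_weight: float = 1.0

    def __post_init__(self):
        if self.lambda1 < 0 or self.lambda2 < 0 or self.cls_weight < 0:
            raise ValueError("loss weights must be non-negative")


class SegmentationHead:
    """Timestamp regression + category classification heads on one feature."""

    def __init__(self, feature_dim: int, n_classes: int, seed: int = 42):
        rng = np.random.default_rng(seed)
        s = 1.0 / np.sqrt(feature_dim)
        self.W_ts = Tensor(rng.normal(0, s, (feature_dim, 2)), requires_grad=True)
        self.b_ts = Tensor(np.zeros((1, 2)), requires_grad=True)
        self.W_cls = Tensor(rng.normal(0, s, (feature_dim, n_classes)), requires_grad=True)
        self.b_cls = Tensor(np.zeros((1, n_classes)), requires_grad=True)
        self.feature_dim = feature_dim
        self.n_classes = n_classes

    def params(self) -> list[Tensor]:
        return [self.W_ts, self.b_ts, self.W_cls, self.b_cls]

    def forward(self, features: Tensor) -> tuple[Tensor, Tensor]:
        """(B, F) features -> sigmoid timestamps (B, 2) and logits (B, K)."""
        if features.shape[-1] != self.feature_dim:
            raise ValueError(
                f"feature dim mismatch: head expects {self.feature_dim}, got {features.shape[-1]}")
        ts = (features @ self.W_ts + self.b_ts).sigmoid()
        logits = features @ self.W_cls + self.b_cls
        return ts, logits


def predict_timestamps(feature: np.ndarray, head: SegmentationHead) -> SegmentationPrediction:
    """Run the heads on one clip feature."""
    f = np.asarray(feature, dtype=np.float64).reshape(1, -1)
    ts, logits = head.forward(Tensor(f))
    return SegmentationPrediction(
        y_start=float(ts.data[0, 0]), y_end=float(ts.data[0, 1]),
        class_logits=logits.data[0])


def segmentation_loss_t(ts: Tensor, logits: Tensor, labels: list[SegmentationLabel],
                        config: SegLossConfig = SegLossConfig()) -> tuple[Tensor, dict[str, float]]:
    """Tape version of the combined loss over a batch.

    ``ts`` is (B, 2) sigmoid timestamps, ``logits`` (B, K); all three terms
    are averaged over the batch. Returns the scalar loss tensor plus the
    per-term breakdown for logging.
    """
    B = ts.shape[0]
    t_true = np.array([[lab.t_start, lab.t_end] for lab in labels])
    cats = np.array([lab.category for lab in labels])
    reg = ((ts - Tensor(t_true)) ** 2).sum(axis=1).mean()
    order = (ts @ Tensor(np.array([[1.0], [-1.0]]))).maximum(0.0).mean()
    logp = logits.log_softmax(axis=1)
    pick = np.zeros((B, logits.shape[1]))
    pick[np.arange(B), cats] = 1.0
    cls = -(logp * Tensor(pick)).sum(axis=1).mean()
    loss = config.cls_weight * cls + config.lambda1 * reg + config.lambda2 * order
    breakdown = {"cls": float(cls.data), "reg": float(reg.data), "order": float(order.data)}
    return loss, breakdown


def segmentation_loss(pred: SegmentationPrediction, truth: SegmentationLabel,
                      config: SegLossConfig = SegLossConfig()) -> tuple[float, dict[str, float]]:
    """Combined loss for a single prediction; returns (loss, breakdown)."""
    ts = Tensor(np.array([[pred.y_start, pred.y_end]]))
    logits = Tensor(pred.class_logits.reshape(1, -1))
    loss, breakdown = segmentation_loss_t(ts, logits, [truth], config)
    return float(loss.data), breakdown


def timestamps_to_frames(y_start: float, y_end: float, n_frames: int) -> tuple[int, int]:
    """Map normalized timestamps to 0-based frame indices.

    Frames are ``round(y * (n_frames - 1))`` with round-half-to-even,
    clamped to the valid range; if rounding inverts the order the pair
    collapses to its midpoint.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    for v in (y_start, y_end):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"timestamp outside [0,1]: {v}")
    hi = n_frames - 1
    fs = int(np.clip(np.round(y_start * hi), 0, hi))
    fe = int(np.clip(np.round(y_end * hi), 0, hi))
    if fs > fe:
        mid = int(np.round((fs + fe) / 2.0))
        fs = fe = mid
    return fs, fe
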