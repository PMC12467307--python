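"""End-to-end training and inference orchestration.

The pipeline couples the spatiotemporal backbone with two output branches:
the segmentation heads (normalized onset/offset plus expression category,
combined loss L_cls + lambda1 L_reg + lambda2 L_order) and the AU graph
network over the co-occurrence adjacency estimated from the training AU
sets (loss alpha L_AU + (1 - alpha) L_emotion).

Training is staged (see docs/methods.md): a joint phase fits the backbone
with the segmentation loss and a deep-supervision AU head on the clip
feature, then a graph phase freezes the backbone, standardises its cached
features, and fits the graph layers with the weighted graph loss plus
score supervision on the pooling scores. Optimisation is Adam throughout.

The default :class:`TrainConfig` is the reduced CPU recovery configuration
used by the synthetic experiments (32x32 frames, 8-frame clips, narrow
channel widths); the full-width backbone is available through
:class:`~aucurve.backbone.BackboneConfig` for architecture checks and
larger runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .au_graph import (
    AdjacencyMatrix,
    AUGraphNet,
    GraphLossConfig,
    adjacency_symmetric,
    count_cooccurrence,
    graph_loss_t,
)
from .backbone import Backbone3D, BackboneConfig, clip_to_batch
from .fixtures import SyntheticClipRecord, render_clip
from .inventory import AU_INVENTORY, EMOTIONS
from .nn.optim import Adam
from .nn.tensor import Tensor
from .preprocess import FrameClip, spatial_normalize, tim_resample
from .segmentation import (
    SegLossConfig,
    SegmentationHead,
    SegmentationLabel,
    segmentation_loss_t,
    timestamps_to_frames,
)

__all__ = ["TrainConfig", "PipelineModel", "prepare_clip", "train_pipeline",
           "evaluate_timestamp_mae", "evaluate_au_f1", "small_backbone_config"]


def small_backbone_config(input_len: int = 8, input_size: int = 32) -> BackboneConfig:
    """Narrow backbone for CPU-scale recovery experiments."""
    return BackboneConfig(
        input_len=input_len, input_size=input_size, in_channels=1,
        channels=(8, 8, 16, 24, 32))


@dataclass
class TrainConfig:
    epochs: int = 30
    batch_size: int = 16
    lr: float = 3e-3
    seed: int = 42
    render_size: int = 32
    backbone: BackboneConfig = field(default_factory=small_backbone_config)
    seg_loss: SegLossConfig = field(default_factory=SegLossConfig)
    graph_loss: GraphLossConfig = field(default_factory=GraphLossConfig)
    graph_hidden: tuple[int, int] = (256, 128)
    graph_proj: int = 16
    use_graph: bool = True
    seg_weight: float = 1.0
    #: weight of the graph loss during the joint phase. The default staged
    #: schedule keeps it at 0 and trains the graph exclusively on frozen
    #: features (graph_epochs): early graph gradients through the dense
    #: propagation destabilise backbone feature learning.
    graph_weight: float = 0.0
    #: weight of the deep-supervision AU head on the clip feature during the
    #: joint phase (0 disables it); inference never uses this head.
    aux_weight: float = 1.0
    #: extra graph-only epochs on frozen, cached clip features after the
    #: joint phase (the backbone stops moving, so the graph layers converge
    #: at a fraction of the per-epoch cost).
    graph_epochs: int = 0
    #: multiply the learning rate by this factor after 70% of the epochs of
    #: each phase (1.0 disables the decay).
    lr_decay: float = 0.3
    #: weight of the score-supervision term in the graph phase: the pooling
    #: scores receive the AU labels as an auxiliary target so that top-k
    #: node selection aligns with actually active units (a dropped node's
    #: zero output carries no gradient, so selection cannot be learned from
    #: the AU loss alone).
    score_weight: float = 0.5
    au_ids: tuple[str, ...] = AU_INVENTORY
    emotions: tuple[str, ...] = EMOTIONS


class PipelineModel:
    """Backbone + segmentation heads + AU graph net, trained jointly."""

    def __init__(self, config: TrainConfig, adjacency: AdjacencyMatrix):
        self.config = config
        self.backbone = Backbone3D(config.backbone, seed=config.seed)
        fd = config.backbone.feature_dim
        self.seg_head = SegmentationHead(fd, len(config.emotions), seed=config.seed + 1)
        self.graph = AUGraphNet(
            adjacency, feature_dim=fd, hidden_dims=config.graph_hidden,
            proj_dim=config.graph_proj, n_emotions=len(config.emotions),
            seed=config.seed + 2) if config.use_graph else None
        self.adjacency = adjacency
        # deep-supervision AU head on the clip feature (training only)
        rng = np.random.default_rng(config.seed + 3)
        n_au = len(config.au_ids)
        self.W_aux = Tensor(rng.normal(0, 0.1, (fd, n_au)), requires_grad=True)
        self.b_aux = Tensor(np.zeros((1, n_au)), requires_grad=True)
        # per-dimension feature standardisation in front of the graph net:
        # pooled ReLU features carry large constant offsets that would
        # otherwise swamp the clip-dependent variation the graph reads.
        # Statistics are estimated on the training set when the graph is
        # fitted and then frozen into the model.
        self.feat_mean = np.zeros(fd, dtype=np.float64)
        self.feat_std = np.ones(fd, dtype=np.float64)

    def graph_features(self, feats: np.ndarray) -> np.ndarray:
        return (np.asarray(feats, dtype=np.float64) - self.feat_mean) / self.feat_std

    def trainable_params(self):
        ps = list(self.backbone.params()) + self.seg_head.params()
        ps += [self.W_aux, self.b_aux]
        if self.graph is not None:
            ps += self.graph.params()
        return ps

    # -- inference ---------------------------------------------------------
    def encode(self, clips: list[FrameClip], train: bool = False) -> np.ndarray:
        batch = np.concatenate(
            [clip_to_batch(c, self.config.backbone.in_channels) for c in clips])
        return self.backbone.forward(batch, train=train)

    def infer(self, clip: FrameClip, n_frames: int | None = None) -> dict:
        feat = self.encode([clip])
        ft = Tensor(feat.astype(np.float64))
        ts, logits = self.seg_head.forward(ft)
        y_start, y_end = float(ts.data[0, 0]), float(ts.data[0, 1])
        out = {
            "y_start": y_start,
            "y_end": y_end,
            "class_probs": _softmax(logits.data[0]).tolist(),
            "emotion": self.config.emotions[int(np.argmax(logits.data[0]))],
        }
        if n_frames is not None:
            fs, fe = timestamps_to_frames(y_start, y_end, n_frames)
            out["frame_start"], out["frame_end"] = fs, fe
        if self.graph is not None:
            gf = Tensor(self.graph_features(feat))
            au_vals, emo_logits = self.graph.forward_sample(gf)
            out["au_values"] = {au: float(v) for au, v in
                                zip(self.graph.au_ids, au_vals.data[0])}
            out["graph_emotion"] = self.config.emotions[int(np.argmax(emo_logits.data[0]))]
        return out

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        state = self.backbone.state_arrays()
        for i, p in enumerate(self.seg_head.params()):
            state[f"seg_param_{i:04d}"] = p.data
        state["aux_W"] = self.W_aux.data
        state["aux_b"] = self.b_aux.data
        state["feat_mean"] = self.feat_mean
        state["feat_std"] = self.feat_std
        if self.graph is not None:
            state.update(self.graph.state_arrays())
        state["backbone_config_json"] = np.array(self.config.backbone.to_json())
        state["emotions"] = np.array(list(self.config.emotions))
        state["au_ids"] = np.array(list(self.adjacency.au_ids))
        np.savez(path, **state)

    @classmethod
    def load(cls, path, config: TrainConfig) -> "PipelineModel":
        with np.load(path, allow_pickle=False) as z:
            state = {k: z[k] for k in z.files}
        adjacency = AdjacencyMatrix(
            state["graph_adjacency"], symmetric=bool(
                np.array_equal(state["graph_adjacency"], state["graph_adjacency"].T)),
            au_ids=tuple(str(a) for a in state["au_ids"]))
        model = cls(config, adjacency)
        model.backbone.load_state_arrays(state)
        for i, p in enumerate(model.seg_head.params()):
            p.data = state[f"seg_param_{i:04d}"].astype(np.float64)
        model.W_aux.data = state["aux_W"].astype(np.float64)
        model.b_aux.data = state["aux_b"].astype(np.float64)
        model.feat_mean = state["feat_mean"].astype(np.float64)
        model.feat_std = state["feat_std"].astype(np.float64)
        if model.graph is not None:
            model.graph.load_state_arrays(state)
        return model


def _softmax(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max())
    return e / e.sum()


def prepare_clip(record: SyntheticClipRecord, config: TrainConfig) -> FrameClip:
    """Render, spatially normalise and temporally resample one record."""
    clip = render_clip(record, config.render_size, config.render_size,
                       au_ids=config.au_ids)
    clip = spatial_normalize(clip, config.backbone.input_size)
    return tim_resample(clip, config.backbone.input_len)


def _labels_for(records: list[SyntheticClipRecord], config: TrainConfig):
    emo_index = {e: i for i, e in enumerate(config.emotions)}
    seg = [SegmentationLabel(r.t_start, r.t_end, emo_index[r.emotion]) for r in records]
    au = np.array([[1.0 if au in r.au_set else 0.0 for au in config.au_ids]
                   for r in records])
    emo = np.array([emo_index[r.emotion] for r in records])
    return seg, au, emo


def train_pipeline(train_records: list[SyntheticClipRecord],
                   config: TrainConfig | None = None,
                   log=None, model: PipelineModel | None = None) -> PipelineModel:
    """Fit the pipeline on synthetic records; returns the trained model.

    The co-occurrence adjacency is estimated from the training AU sets
    before optimisation and then held fixed. Pass an existing ``model`` to
    continue training it (the optimiser state restarts).
    """
    config = config or TrainConfig()
    if model is None:
        counts = count_cooccurrence([r.au_set for r in train_records], config.au_ids)
        adjacency = adjacency_symmetric(counts)
        model = PipelineModel(config, adjacency)
    opt = Adam(model.trainable_params(), lr=config.lr)
    rng = np.random.default_rng(config.seed)

    clips = [clip_to_batch(prepare_clip(r, config), config.backbone.in_channels)[0]
             for r in train_records]
    data = np.stack(clips)
    seg_labels, au_truth, emo_truth = _labels_for(train_records, config)

    n = len(train_records)
    order = np.arange(n)
    decay_at = int(0.7 * config.epochs)
    for epoch in range(config.epochs):
        if epoch == decay_at and config.lr_decay != 1.0:
            opt.lr *= config.lr_decay
        rng.shuffle(order)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            batch = data[idx]
            feats = model.backbone.forward(batch, train=True)
            ft = Tensor(feats.astype(np.float64), requires_grad=True)
            ts, logits = model.seg_head.forward(ft)
            seg_l, _ = segmentation_loss_t(ts, logits, [seg_labels[i] for i in idx],
                                           config.seg_loss)
            total = config.seg_weight * seg_l
            if model.graph is not None:
                au_pred, emo_logits = model.graph.forward_batch(ft)
                g_l, _ = graph_loss_t(au_pred, au_truth[idx], emo_logits,
                                      emo_truth[idx], config.graph_loss)
                total = total + config.graph_weight * g_l
            if config.aux_weight > 0:
                total = total + config.aux_weight * _aux_bce(model, ft, au_truth[idx])
            opt.zero_grad()
            total.backward()
            model.backbone.backward(ft.grad.astype(np.float32))
            opt.step()
            epoch_loss += float(total.data) * len(idx)
        if log is not None:
            log(f"epoch {epoch + 1}/{config.epochs} loss {epoch_loss / n:.4f}")

    if model.graph is not None and config.graph_epochs > 0:
        _fit_graph_on_frozen_features(model, data, au_truth, emo_truth, config, log)
    return model


def _aux_bce(model: PipelineModel, ft: Tensor, au_truth: np.ndarray) -> Tensor:
    p = (ft @ model.W_aux + model.b_aux).sigmoid().clip(1e-7, 1.0 - 1e-7)
    y = Tensor(au_truth)
    return -(y * p.log() + (1.0 - y) * (1.0 - p).log()).mean(axis=1).mean()


def _fit_graph_on_frozen_features(model: PipelineModel, data: np.ndarray,
                                  au_truth: np.ndarray, emo_truth: np.ndarray,
                                  config: TrainConfig, log=None) -> None:
    """Graph-refinement phase: the backbone is frozen in inference mode and
    its features cached once, so the graph layers see a stationary input
    distribution and train at a fraction of the joint-phase cost."""
    raw = np.concatenate([
        model.backbone.forward(data[s:s + 32])
        for s in range(0, len(data), 32)])
    model.feat_mean = raw.mean(axis=0).astype(np.float64)
    model.feat_std = (raw.std(axis=0) + 1e-6).astype(np.float64)
    feats = model.graph_features(raw)
    opt = Adam(model.graph.params(), lr=config.lr)
    rng = np.random.default_rng(config.seed + 5)
    n = len(data)
    order = np.arange(n)
    bs = max(config.batch_size, 32)
    decay_at = int(0.7 * config.graph_epochs)
    for epoch in range(config.graph_epochs):
        if epoch == decay_at and config.lr_decay != 1.0:
            opt.lr *= config.lr_decay
        rng.shuffle(order)
        epoch_loss = 0.0
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            au_pred, emo_logits, scores = model.graph.forward_batch(
                Tensor(feats[idx].astype(np.float64)), return_scores=True)
            loss, _ = graph_loss_t(au_pred, au_truth[idx], emo_logits,
                                   emo_truth[idx], config.graph_loss)
            if config.score_weight > 0:
                z = scores.sigmoid().clip(1e-7, 1.0 - 1e-7)
                y = Tensor(au_truth[idx])
                sup = -(y * z.log() + (1.0 - y) * (1.0 - z).log()).mean(axis=1).mean()
                loss = loss + config.score_weight * sup
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
        if log is not None and (epoch + 1) % 25 == 0:
            log(f"graph epoch {epoch + 1}/{config.graph_epochs} loss {epoch_loss / n:.4f}")


def evaluate_timestamp_mae(model: PipelineModel, records: list[SyntheticClipRecord]
                           ) -> float:
    """Mean absolute error of predicted normalized onset/offset timestamps."""
    errs = []
    for r in records:
        pred = model.infer(prepare_clip(r, model.config))
        errs.append(abs(pred["y_start"] - r.t_start))
        errs.append(abs(pred["y_end"] - r.t_end))
    return float(np.mean(errs))


def evaluate_au_f1(model: PipelineModel, records: list[SyntheticClipRecord],
                   threshold: float = 0.5) -> float:
    """Micro-averaged detection F1 of thresholded AU intensities."""
    tp = fp = fn = 0
    for r in records:
        pred = model.infer(prepare_clip(r, model.config))
        for au in model.config.au_ids:
            hit = pred["au_values"][au] >= threshold
            present = au in r.au_set
            tp += hit and present
            fp += hit and not present
            fn += present and not hit
    if tp == 0:
        return 0.0
    prec = tp / (tp + fp)
    rec = tp / (tp + fn)
    return 2 * prec * rec / (prec + rec)
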