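"""AU co-occurrence graphs, graph convolutions and self-attention pooling.

Action units are nodes of a small graph whose edge weights are estimated
from how often pairs of AUs activate together across a corpus. Two
estimators are provided:

* conditional: ``A[i, j] = P(U_i | U_j) = N_ij / N_j`` (asymmetric);
* symmetric (the default): ``A[i, j] = 2 N_ij / (N_i + N_j)``, motivated by
  the bilateral symmetry of facial anatomy and the undirected nature of
  co-occurrence.

Node features propagate through renormalised graph convolutions
``H' = ReLU(D^{-1/2} (A + I) D^{-1/2} H W)`` (a plain ``ReLU(A H W)``
variant is available), and a self-attention pooling step keeps the
top-``ceil(p * n)`` nodes scored by a single-channel graph convolution,
gating the survivors with ``tanh`` of their scores.

The trainable :class:`AUGraphNet` initialises node features as the one-hot
node identity concatenated with a learned per-node projection of the clip
feature — each AU node owns its projection weights, so node features carry
node-specific evidence from the clip encoding — optionally plus a 7-dim
emotion context vector. Two graph convolutions follow (widths 1024 and 512
by default), then self-attention pooling at ratio 0.5, a shared per-node
sigmoid head for AU intensities (pooled-away nodes report 0), and emotion
logits from a mean readout over the kept nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .inventory import AU_INVENTORY, EMOTIONS
from .nn.tensor import Tensor, concat

__all__ = [
    "CooccurrenceCounts",
    "AdjacencyMatrix",
    "GraphLossConfig",
    "count_cooccurrence",
    "adjacency_conditional",
    "adjacency_symmetric",
    "renorm_propagation",
    "gcn_layer",
    "sag_pool",
    "graph_loss",
    "graph_loss_t",
    "AUGraphNet",
    "au_gcn_forward",
    "write_adjacency_csv",
    "read_adjacency_csv",
]


@dataclass
class CooccurrenceCounts:
    au_ids: tuple[str, ...]
    N: np.ndarray          # per-AU occurrence counts
    N_pair: np.ndarray     # joint occurrence counts, symmetric

    def __post_init__(self):
        self.au_ids = tuple(self.au_ids)
        self.N = np.asarray(self.N, dtype=np.int64)
        self.N_pair = np.asarray(self.N_pair, dtype=np.int64)
        n = len(self.au_ids)
        if self.N.shape != (n,) or self.N_pair.shape != (n, n):
            raise ValueError("count shapes do not match the AU id list")
        if (self.N_pair != self.N_pair.T).any():
            raise ValueError("N_pair must be symmetric")
        if (np.diag(self.N_pair) != self.N).any():
            raise ValueError("diagonal of N_pair must equal N")
        if (self.N_pair > np.minimum(self.N[:, None], self.N[None, :])).any():
            raise ValueError("joint counts cannot exceed marginal counts")


@dataclass
class AdjacencyMatrix:
    values: np.ndarray
    symmetric: bool
    au_ids: tuple[str, ...] = AU_INVENTORY

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("adjacency must be square")
        if self.values.min() < 0 or self.values.max() > 1 + 1e-12:
            raise ValueError("adjacency entries must lie in [0,1]")
        if self.symmetric and not np.array_equal(self.values, self.values.T):
            raise ValueError("symmetric flag set but matrix is not symmetric")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def count_cooccurrence(corpus: list[frozenset[str] | set[str]],
                       au_ids: tuple[str, ...] = AU_INVENTORY) -> CooccurrenceCounts:
    """Exact integer occurrence and joint-occurrence counts over a corpus."""
    pos = {au: i for i, au in enumerate(au_ids)}
    n = len(au_ids)
    N = np.zeros(n, dtype=np.int64)
    N_pair = np.zeros((n, n), dtype=np.int64)
    for s in corpus:
        unknown = [au for au in s if au not in pos]
        if unknown:
            raise ValueError(f"unknown AU ids in corpus: {sorted(unknown)}")
        idx = sorted(pos[au] for au in s)
        for i in idx:
            N[i] += 1
            for j in idx:
                N_pair[i, j] += 1
    return CooccurrenceCounts(au_ids, N, N_pair)


def adjacency_conditional(counts: CooccurrenceCounts) -> AdjacencyMatrix:
    """Conditional-probability edges A[i, j] = N_ij / N_j (0 when N_j = 0)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.where(counts.N[None, :] > 0,
                        counts.N_pair / np.maximum(counts.N[None, :], 1), 0.0)
    return AdjacencyMatrix(vals, symmetric=False, au_ids=counts.au_ids)


def adjacency_symmetric(counts: CooccurrenceCounts) -> AdjacencyMatrix:
    """Symmetric co-occurrence edges A[i, j] = 2 N_ij / (N_i + N_j)."""
    denom = counts.N[:, None] + counts.N[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.where(denom > 0, 2.0 * counts.N_pair / np.maximum(denom, 1), 0.0)
    vals = (vals + vals.T) / 2.0  # exact symmetry despite float rounding
    return AdjacencyMatrix(vals, symmetric=True, au_ids=counts.au_ids)


def renorm_propagation(A: np.ndarray) -> np.ndarray:
    """Renormalised propagation matrix D^{-1/2} (A + I) D^{-1/2} with D the
    degree matrix of A + I (self-loops guarantee positive degrees)."""
    A = np.asarray(A, dtype=np.float64)
    At = A + np.eye(A.shape[0])
    dinv = 1.0 / np.sqrt(At.sum(axis=1))
    return dinv[:, None] * At * dinv[None, :]


def gcn_layer(H: np.ndarray, A: np.ndarray | AdjacencyMatrix, W: np.ndarray,
              renormalize: bool = True) -> np.ndarray:
    """One graph convolution: ReLU(P H W) with P the renormalised propagation
    matrix (or P = A for the plain variant)."""
    if isinstance(A, AdjacencyMatrix):
        A = A.values
    A = np.asarray(A, dtype=np.float64)
    H = np.asarray(H, dtype=np.float64)
    W = np.asarray(W, dtype=np.float64)
    if A.min() < 0:
        raise ValueError("adjacency entries must be non-negative")
    if H.shape[0] != A.shape[0] or H.shape[1] != W.shape[0]:
        raise ValueError(
            f"shape mismatch: A {A.shape}, H {H.shape}, W {W.shape}")
    P = renorm_propagation(A) if renormalize else A
    return np.maximum(P @ H @ W, 0.0)


def sag_pool(H: np.ndarray, A: np.ndarray | AdjacencyMatrix, score_weights: np.ndarray,
             p: float = 0.5) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Self-attention graph pooling.

    Scores ``Z = P H w`` come from a single-channel renormalised graph
    convolution; the top ``k = ceil(p * n)`` nodes are kept (ties broken by
    ascending node index), their features gated by ``tanh(Z)``, and the
    adjacency restricted to the kept rows/columns. Returns
    ``(H_kept, A_kept, kept_indices)`` with indices in original order.
    """
    if isinstance(A, AdjacencyMatrix):
        A = A.values
    if not (0.0 < p <= 1.0):
        raise ValueError(f"pool ratio must lie in (0, 1], got {p}")
    H = np.asarray(H, dtype=np.float64)
    n = H.shape[0]
    if n == 0:
        raise ValueError("cannot pool an empty graph")
    P = renorm_propagation(np.asarray(A, dtype=np.float64))
    Z = P @ H @ np.asarray(score_weights, dtype=np.float64).reshape(-1)
    k = int(np.ceil(p * n))
    order = np.lexsort((np.arange(n), -Z))  # descending score, ascending index on ties
    kept = np.sort(order[:k])
    H_kept = H[kept] * np.tanh(Z[kept])[:, None]
    A_kept = np.asarray(A, dtype=np.float64)[np.ix_(kept, kept)]
    return H_kept, A_kept, kept


@dataclass(frozen=True)
class GraphLossConfig:
    alpha: float = 0.7

    def __post_init__(self):
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must lie in [0,1], got {self.alpha}")


def graph_loss_t(au_pred: Tensor, au_truth: np.ndarray, emo_logits: Tensor,
                 emo_truth: np.ndarray,
                 config: GraphLossConfig = GraphLossConfig(),
                 eps: float = 1e-7) -> tuple[Tensor, dict[str, float]]:
    """Tape version: alpha * meanBCE(AU) + (1 - alpha) * CE(emotion) over a
    batch. ``au_pred`` is (B, n) probabilities, ``emo_logits`` (B, K)."""
    au_truth = np.asarray(au_truth, dtype=np.float64)
    emo_truth = np.asarray(emo_truth)
    if au_pred.shape != au_truth.shape:
        raise ValueError(f"AU shape mismatch: {au_pred.shape} vs {au_truth.shape}")
    B, K = emo_logits.shape
    if emo_truth.shape != (B,):
        raise ValueError(f"emotion truth must be (B,), got {emo_truth.shape}")
    pc = au_pred.clip(eps, 1.0 - eps)
    bce = -(Tensor(au_truth) * pc.log() + Tensor(1.0 - au_truth) * (1.0 - pc).log())
    l_au = bce.mean(axis=1).mean()
    pick = np.zeros((B, K))
    pick[np.arange(B), emo_truth] = 1.0
    l_emo = -(emo_logits.log_softmax(axis=1) * Tensor(pick)).sum(axis=1).mean()
    loss = config.alpha * l_au + (1.0 - config.alpha) * l_emo
    return loss, {"au": float(l_au.data), "emotion": float(l_emo.data)}


def graph_loss(au_pred: np.ndarray, au_truth: np.ndarray, emo_logits: np.ndarray,
               emo_truth: int, config: GraphLossConfig = GraphLossConfig()
               ) -> tuple[float, dict[str, float]]:
    """Weighted graph loss for a single sample; returns (loss, breakdown)."""
    loss, breakdown = graph_loss_t(
        Tensor(np.asarray(au_pred, dtype=np.float64).reshape(1, -1)),
        np.asarray(au_truth, dtype=np.float64).reshape(1, -1),
        Tensor(np.asarray(emo_logits, dtype=np.float64).reshape(1, -1)),
        np.array([emo_truth]), config)
    return float(loss.data), breakdown


class AUGraphNet:
    """Trainable AU graph model over a fixed co-occurrence adjacency."""

    def __init__(self, adjacency: AdjacencyMatrix, feature_dim: int = 512,
                 hidden_dims: tuple[int, int] = (1024, 512), proj_dim: int = 32,
                 pool_ratio: float = 0.5, n_emotions: int = len(EMOTIONS),
                 emotion_context: bool = False, seed: int = 42):
        self.adjacency = adjacency
        self.au_ids = adjacency.au_ids
        n = adjacency.n
        self.n = n
        self.pool_ratio = pool_ratio
        self.emotion_context = emotion_context
        self.n_emotions = n_emotions
        self.P = renorm_propagation(adjacency.values)
        d0 = n + proj_dim + (n_emotions if emotion_context else 0)
        rng = np.random.default_rng(seed)

        def glorot(din, dout):
            s = np.sqrt(2.0 / (din + dout))
            return Tensor(rng.normal(0, s, (din, dout)), requires_grad=True)

        # one projection per node: (n, feature_dim, proj_dim)
        s_proj = np.sqrt(2.0 / (feature_dim + proj_dim))
        self.W_proj = Tensor(rng.normal(0, s_proj, (n, feature_dim, proj_dim)),
                             requires_grad=True)
        self.W1 = glorot(d0, hidden_dims[0])
        self.W2 = glorot(hidden_dims[0], hidden_dims[1])
        # unit-scale score weights keep the tanh pooling gates open at
        # initialisation; a glorot-scale init leaves tanh(Z) ~ 0, which
        # blocks gradient flow through the gated features early in training
        self.w_score = Tensor(rng.normal(0, 1.0 / np.sqrt(hidden_dims[1]) * 4.0,
                                         (hidden_dims[1], 1)), requires_grad=True)
        self.W_au = glorot(hidden_dims[1], 1)
        self.b_au = Tensor(np.zeros((1, 1)), requires_grad=True)
        self.W_emo = glorot(hidden_dims[1], n_emotions)
        self.b_emo = Tensor(np.zeros((1, n_emotions)), requires_grad=True)
        self.hidden_dims = tuple(hidden_dims)
        self.feature_dim = feature_dim
        self.proj_dim = proj_dim

    def params(self) -> list[Tensor]:
        return [self.W_proj, self.W1, self.W2, self.w_score,
                self.W_au, self.b_au, self.W_emo, self.b_emo]

    def forward_batch(self, features: Tensor, emotion_context: np.ndarray | None = None,
                      return_scores: bool = False):
        """Clip features (B, F) -> (AU intensities (B, n), emotion logits (B, K)).

        Pooling keeps the top-``ceil(p * n)`` nodes per sample by score
        (ties to the lower node index); dropped nodes contribute neither to
        the AU output (reported as exactly 0) nor to the emotion readout.
        With ``return_scores`` the raw pooling scores (B, n) are appended to
        the return tuple (used for score supervision during training).
        """
        if features.data.ndim != 2 or features.shape[1] != self.feature_dim:
            raise ValueError(
                f"expected features (B, {self.feature_dim}), got {features.shape}")
        B = features.shape[0]
        n = self.n
        parts = [Tensor(np.broadcast_to(np.eye(n), (B, n, n)).copy())]
        proj = (features.reshape(B, 1, 1, -1) @ self.W_proj).reshape(B, n, -1)
        parts.append(proj)
        if self.emotion_context:
            ctx = np.zeros((B, self.n_emotions)) if emotion_context is None \
                else np.asarray(emotion_context, dtype=np.float64).reshape(B, -1)
            parts.append(Tensor(np.broadcast_to(ctx[:, None, :], (B, n, ctx.shape[1])).copy()))
        X = concat(parts, axis=2)                         # (B, n, d0)
        P = Tensor(self.P)
        H1 = (P @ X @ self.W1).relu()
        H2 = (P @ H1 @ self.W2).relu()
        Zt = (P @ H2 @ self.w_score)                      # (B, n, 1)
        # top-k selection per sample on the raw scores
        Z = Zt.data[:, :, 0]
        k = int(np.ceil(self.pool_ratio * n))
        mask = np.zeros((B, n))
        for b in range(B):
            order = np.lexsort((np.arange(n), -Z[b]))
            mask[b, np.sort(order[:k])] = 1.0
        gated = H2 * Zt.tanh()                            # (B, n, d)
        au_all = (gated @ self.W_au + self.b_au).sigmoid().reshape(B, n)
        au_values = au_all * Tensor(mask)
        readout = (Tensor(mask[:, None, :] / k) @ gated).reshape(B, -1)
        emo_logits = readout @ self.W_emo + self.b_emo
        if return_scores:
            return au_values, emo_logits, Zt.reshape(B, n)
        return au_values, emo_logits

    def forward_sample(self, feature: Tensor, emotion_context: np.ndarray | None = None
                       ) -> tuple[Tensor, Tensor]:
        """One clip feature (1, F) -> (AU intensities (1, n), emotion logits (1, K))."""
        return self.forward_batch(feature, emotion_context)

    # -- persistence -------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {f"graph_param_{i:04d}": p.data for i, p in enumerate(self.params())}
        state["graph_adjacency"] = self.adjacency.values
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            arr = state[f"graph_param_{i:04d}"]
            if arr.shape != p.data.shape:
                raise ValueError(f"checkpoint shape mismatch at graph param {i}")
            p.data = arr.astype(np.float64)


def au_gcn_forward(feature: np.ndarray, A: AdjacencyMatrix, model: AUGraphNet
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Run the graph model on one clip feature; returns (au_values, emo_logits)."""
    if A.n != model.n:
        raise ValueError(f"adjacency has {A.n} nodes but model was built with {model.n}")
    f = Tensor(np.asarray(feature, dtype=np.float64).reshape(1, -1))
    au_values, emo_logits = model.forward_sample(f)
    return au_values.data[0], emo_logits.data[0]


# ---------------------------------------------------------------------------
# Adjacency CSV round trip
# ---------------------------------------------------------------------------

def write_adjacency_csv(adj: AdjacencyMatrix, path) -> None:
    import csv as _csv

    with open(path, "w", newline="") as fh:
        w = _csv.writer(fh, lineterminator="\n")
        w.writerow(["au_id", *adj.au_ids])
        for au, row in zip(adj.au_ids, adj.values):
            w.writerow([au, *(repr(float(v)) for v in row)])


def read_adjacency_csv(path) -> AdjacencyMatrix:
    import csv as _csv

    with open(path, newline="") as fh:
        rows = list(_csv.reader(fh))
    au_ids = tuple(rows[0][1:])
    vals = np.array([[float(v) for v in r[1:]] for r in rows[1:]])
    symmetric = np.array_equal(vals, vals.T)
    return AdjacencyMatrix(vals, symmetric=symmetric, au_ids=au_ids)
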