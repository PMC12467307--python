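# Methods

This note describes the models and procedures implemented in `aucurve`, the
assumptions behind them, and the choices made where the design was open.

## Problem setting

Micro-expressions are brief (under half a second), low-amplitude,
involuntary facial movements. Animating them on a digital character
requires three things that ordinary expression pipelines do not provide:
(i) precise temporal localisation — the onset, apex and offset of the event
inside a clip; (ii) knowledge of *which* facial action units (AUs, the FACS
muscle-movement descriptors) are active and how strongly, respecting their
anatomical co-activation structure; and (iii) a conversion of those
discrete detections into smooth animation curves on named rig controls.
`aucurve` implements this as a closed loop: video clip → spatiotemporal
feature → (timestamps, AU intensities) → modulated B-spline curve tracks →
keyframe export.

## Spatiotemporal encoder

An 18-layer 3D residual network encodes a fixed-size clip (default 16
frames at 112×112 after preprocessing) into a single feature vector:

* `conv1`: 3×7×7 kernel, stride 1×2×2 — the temporal length is preserved
  while the spatial resolution halves (no max-pool follows).
* Four residual stages of two blocks (two 3×3×3 convolutions with batch
  normalisation and ReLU each, identity shortcuts). Stages 2–4 open with a
  stride-2 block and a 1×1×1 projection shortcut, halving time and space.
* Global average pooling over (T, H, W) yields the clip feature; with the
  default widths (64, 64, 128, 256, 512) it is 512-dimensional. For a
  16×112×112 input the per-stage sizes are 16×56×56, 16×56×56, 8×28×28,
  4×14×14 and 2×7×7.

Preprocessing resizes frames (bilinear, per-clip standardisation to zero
mean and unit variance with a 1e-8 variance floor so constant clips map to
zeros) and resamples time to the fixed length by linear interpolation at
uniformly spaced positions — endpoints map to endpoints, every output frame
is a convex combination of its two temporally nearest input frames. This
linear scheme stands in for manifold-based temporal interpolation methods;
it is deterministic and exactly testable. Resizing precedes resampling
(the two linear per-pixel operations commute; the order is fixed for
reproducibility). Frame indexing is 0-based; frame `f` of a `T`-frame clip
corresponds to normalized time `f/(T-1)`.

All neural components — convolutions (im2col + BLAS), batch normalisation,
the dense heads and graph layers (a small reverse-mode tape), and Adam —
are implemented in NumPy inside the package (`aucurve.nn`). Gradient
correctness is pinned by finite-difference tests.

## Temporal segmentation

Two heads sit on the clip feature: a linear map squashed through a sigmoid
producing normalized onset/offset timestamps in [0, 1], and a linear
category head. The sigmoid guarantees the stated codomain of the timestamp
regression. The training loss is

    L = L_cls + λ1 · L_reg + λ2 · L_order,   λ1 = 0.5, λ2 = 0.1,

with `L_cls` categorical cross-entropy, `L_reg` the squared error of both
timestamps, and `L_order = max(0, ŷ_start − ŷ_end)` a hinge enforcing
temporal order. All terms are batch means (scale-invariant to batch size).
The category term can be disabled (`cls_weight = 0`) for purely temporal
spotting. Timestamps map back to frames by `round(y · (T − 1))` with
round-half-to-even; if rounding inverts the pair it collapses to its
midpoint. Both conventions are fixed for bit-exact reproducibility.

## AU co-occurrence graph

AUs are nodes of a graph whose edges are estimated from co-occurrence
counts over a corpus of AU sets. Two estimators are first-class:

* conditional (asymmetric): `A[i,j] = P(U_i | U_j) = N_ij / N_j`;
* symmetric (default): `A[i,j] = 2 N_ij / (N_i + N_j)`, reflecting the
  bilateral symmetry of facial anatomy and the undirected nature of
  co-occurrence. Zero-count AUs contribute zero edges.

Features propagate by the renormalised rule
`H' = ReLU(D̃^{-1/2}(A+I)D̃^{-1/2} H W)` (self-loops guarantee positive
degrees); a plain `ReLU(A H W)` variant exists behind a flag. Self-attention
pooling scores nodes with a single-channel graph convolution, keeps the
top `k = ceil(p·n)` (ties to the lower node index), gates the survivors
with `tanh` of their scores and restricts the adjacency to the kept
rows/columns.

The inference model (`AUGraphNet` / `au_gcn_forward`) initialises node
features as the one-hot node identity concatenated with a per-node learned
projection of the clip feature — each node owns its projection weights, so
its features carry node-specific evidence; with a single shared projection
the nodes are indistinguishable up to the one-hot block and per-AU recovery
empirically saturates well below usable accuracy. Two graph convolutions
(default widths 1024 then 512) are followed by pooling at ratio 0.5, a
shared per-node sigmoid head (pooled-away nodes report intensity 0, so the
curve stage always receives a full-length AU vector), and an emotion head
on the mean readout of the kept nodes. The graph loss is
`α·BCE(AU) + (1−α)·CE(emotion)` with α = 0.7. An optional 7-dimensional
emotion-context vector can augment the node features (off by default: at
inference no trustworthy emotion input exists).

## Training procedure

Training is staged; the inference path is unaffected.

1. **Joint phase.** Backbone + segmentation heads train with the combined
   segmentation loss plus a *deep-supervision* linear AU head on the clip
   feature (binary cross-entropy, weight 1). This auxiliary head exists
   because the graph's gradient — filtered through two dense propagation
   steps, the ReLUs and the pooling gate — is too diffuse to shape an
   untrained encoder; a direct per-AU error signal makes the feature
   AU-informative. The graph loss does not backpropagate into the backbone
   during this phase (weight 0 by default): its early gradients are
   effectively noise and measurably destabilise feature learning.
2. **Graph phase.** The backbone is frozen in inference mode, its features
   for the training set are computed once and standardised per dimension
   (pooled ReLU features carry large constant offsets that would otherwise
   dwarf the clip-dependent variation; the statistics are stored in the
   model and applied at inference). The graph then trains with the weighted
   graph loss plus a *score-supervision* term: the AU labels applied as a
   BCE target to the raw pooling scores. A dropped node's output is the
   constant 0 and carries no gradient, so top-k selection cannot be learned
   from the AU loss alone; supervising the scores aligns selection with
   truly active units. The auxiliary and score heads are training-only.

Both phases use Adam (lr 3e-3, decayed ×0.3 after 70% of the epochs of the
phase). All weight initialisation and data order is seeded.

## Curve synthesis

Each detected AU event (intensity `v`, onset/apex/offset seconds) becomes a
clamped uniform cubic B-spline over control values `(0, 0, v, 0, 0)`: the
curve interpolates zero at both ends of the event span, stays within the
convex hull of its control values (so it never exceeds `v`), and peaks at
the middle parameter. A piecewise-linear time warp maps the spline
parameter onto seconds with the peak at the apex; the warp is C⁰ at the
apex (the spline itself is C²) — a deliberate trade for exact apex
placement. Since the timestamp heads predict only onset and offset, the
apex defaults to the span midpoint (configurable fraction).

Curves are modulated per emotion, `c'(t) = c(t)·m_e·i_v`, with `m_e > 0` an
emotion gain (defaults chosen per category: larger for high-arousal
positive emotions such as happiness, smaller for restrained negative ones
such as fear; configurable) and `i_v ∈ [0, 1]` an intensity-variation
factor (default 1). Each AU's curve is duplicated onto all rig channels of
the bundled AU-to-rig table (bilateral left/right pairs, e.g. AU12 → the
two `mouth_cornerPull` controls), and exported as CSV/JSON keyframes with
`frame = round(time·fps)` and `cubic` / `auto` interpolation-tangent
metadata. Exports are byte-stable for fixed inputs.

## Synthetic data generator

Real spontaneous micro-expression corpora with AU and onset/apex/offset
annotation are access-restricted, so the test bed is synthetic with fully
known ground truth:

* **AU sets** are drawn per emotion category from independent Bernoulli
  marginals with optional pairwise co-occurrence boosts applied by
  rejection sampling; empty sets are rejected. The resulting joint is known
  in closed form by enumeration over the 12-AU inventory, giving analytic
  conditional and symmetric adjacencies as recovery targets. Default
  category specs follow classic FACS signatures (AU6+AU12 for happiness,
  AU1/2/5 for surprise, AU9/10 for disgust, ...), six Ekman emotions plus
  neutral. A separate densely active `recovery_spec` (marginals 0.55–0.9)
  is used for estimator-consistency checks so that the conditional
  estimator's binomial standard error at 5000 samples stays near 0.01.
* **Clips** are a deterministic grayscale base face (landmark blobs on a
  flat background) in which each active AU perturbs its own fixed,
  disjoint rectangular region, with a distinct base intensity per region.
  The temporal envelope is a quadratic ease-in/ease-out: exactly zero
  outside (onset, offset), 1 at the apex. The quadratic shape (rather than
  a linear ramp) makes the largest inter-frame step occur adjacent to the
  apex, so motion-energy scans localise the apex, while support assertions
  remain exact. Frames are exported as zero-padded PNGs with a CSV manifest
  and JSON labels; corpora are byte-stable per seed.

What the generator does *not* emulate: head pose, illumination change,
identity variation, camera noise, AU region overlap, or the subtle
amplitudes of real spontaneous expressions. Passing the recovery
experiments therefore shows that the pipeline recovers structure it is
pointed at under controlled conditions, not that it attains any particular
accuracy on real footage.

## Problem sizes and experiment design

The recovery experiments run a reduced configuration chosen as the
package's standard CPU test bed: 32×32 rendered frames, 8-frame temporal
length, backbone widths (8, 8, 16, 24, 32) giving a 32-dimensional
feature, graph widths (256, 128). The timestamp experiment trains on 64
clips (16 epochs) and evaluates mean absolute timestamp error on 16
held-out clips; the AU experiment trains on 128 clips (50 joint epochs +
120 graph epochs) and evaluates detection F1 (threshold 0.5) on 32
held-out clips. The full-width encoder and graph (Table widths 64–512,
1024/512) are exercised forward-only in the architecture-conformance
checks. Cross-validation utilities provide stratified k-fold (default
k = 5; per-label shuffling with a single rotating fold counter, so fold
sizes differ by at most one) and leave-one-subject-out splitting; F1 is
macro-averaged over the classes present in either vector — the convention
in this literature for imbalanced classes, stated here because it affects
comparability with other reports.

## Numerical conventions

* Round-half-to-even for timestamp→frame mapping; inverted pairs collapse
  to their midpoint.
* Pooling ties break toward the lower node index; `k = ceil(p·n)`.
* Adjacency division by zero (never-observed AUs) yields zero edges; the
  symmetric estimator is symmetrised exactly after the division.
* B-spline evaluation uses a clamped uniform knot vector; control lists
  shorter than four are endpoint-duplicated.
* The per-clip standardisation variance floor is 1e-8; the graph feature
  standardisation adds 1e-6 to the per-dimension standard deviation.
* All randomness flows through seeded `numpy.random.Generator` instances;
  checkpoints are single `.npz` files with an embedded JSON config header.

## Known limitations

* The encoder pools over time before the timestamp heads, so temporal
  localisation relies on boundary effects and envelope shape rather than
  explicit temporal attention; accuracy on real, less stereotyped events
  would be weaker.
* The exported track is C² inside the span except for a curvature kink at
  the apex introduced by the time warp.
* The co-occurrence adjacency is estimated once from the training corpus
  and held fixed; no learned or attention-derived adjacency is provided.
* Training at the full 112×112/16-frame configuration is out of CPU scope;
  the implementation supports it, but all fitted results in this package
  are at the reduced sizes above.
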