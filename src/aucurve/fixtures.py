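"""Synthetic micro-expression corpora with known ground truth.

Real spontaneous micro-expression footage with AU and onset/apex/offset
annotation is scarce and access-restricted, so every downstream stage is
exercised on synthetic clips whose generative process is fully known:

* AU label sets are drawn per emotion from independent Bernoulli marginals
  with optional pairwise co-occurrence boosts (applied by rejection
  sampling), so the exact joint distribution — and hence the analytic
  conditional and symmetric co-occurrence adjacencies — can be computed by
  enumeration and used as recovery targets.
* Clips are a deterministic grayscale base face (landmark blobs over a flat
  background) on which each active AU perturbs its own fixed rectangular
  region, with a quadratic ease-in/ease-out temporal envelope that is
  exactly zero outside (onset, offset) and peaks at the apex frame. The
  quadratic ramp (rather than a linear one) makes the largest inter-frame
  intensity step occur adjacent to the apex, so motion-energy scans localise
  the apex, while support assertions stay exact. Each AU region carries a
  distinct base intensity so region activity is identifiable from
  appearance statistics alone.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .inventory import AU_INVENTORY, EMOTIONS
from .preprocess import FrameClip

__all__ = [
    "EmotionSpec",
    "SyntheticClipRecord",
    "default_emotion_specs",
    "recovery_spec",
    "sample_au_corpus",
    "analytic_joint",
    "analytic_adjacencies",
    "base_face",
    "au_region",
    "render_clip",
    "make_records",
    "make_corpus",
    "load_corpus",
]

#: Additive brightness gained by an AU region at full intensity and apex.
PERTURB_AMPLITUDE = 0.35


@dataclass
class EmotionSpec:
    """Generative description of one emotion category.

    ``au_probs`` are marginal activation probabilities over the canonical AU
    inventory; ``pair_boost`` multiplies the joint weight of a sample for
    every boosted AU pair that is co-active; ``modulator_me`` is the
    emotion-specific curve modulator (high for joy, low for fear).
    """

    name: str
    au_probs: dict[str, float]
    pair_boost: dict[tuple[str, str], float] = field(default_factory=dict)
    modulator_me: float = 1.0
    au_ids: tuple[str, ...] = AU_INVENTORY

    def __post_init__(self):
        for au, p in self.au_probs.items():
            if au not in self.au_ids:
                raise ValueError(f"unknown AU id {au!r} in au_probs")
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability for {au} outside [0,1]: {p}")
        for (a, b), f in self.pair_boost.items():
            if a not in self.au_ids or b not in self.au_ids:
                raise ValueError(f"unknown AU pair ({a}, {b}) in pair_boost")
            if f < 0:
                raise ValueError(f"pair boost must be >= 0, got {f}")
        if self.modulator_me <= 0:
            raise ValueError(f"modulator_me must be > 0, got {self.modulator_me}")

    def prob(self, au: str) -> float:
        return float(self.au_probs.get(au, 0.0))


def default_emotion_specs() -> dict[str, EmotionSpec]:
    """FACS-informed default generative specs for the 7 emotion categories.

    Marginals follow the classic AU signatures (e.g. cheek raiser AU6 with
    lip corner puller AU12 for happiness; brow raisers AU1/AU2 with lid
    raiser AU5 for surprise), with a small background rate for all other
    units. Modulators are larger for high-arousal positive emotions and
    smaller for restrained negative ones.
    """
    bg = 0.05
    sig = {
        "anger": ({"AU4": 0.9, "AU5": 0.6, "AU7": 0.7, "AU23": 0.65}, {("AU4", "AU7"): 1.3}, 1.0),
        "disgust": ({"AU9": 0.9, "AU10": 0.7, "AU4": 0.4}, {("AU9", "AU10"): 1.3}, 0.8),
        "fear": ({"AU1": 0.7, "AU2": 0.6, "AU4": 0.7, "AU5": 0.65, "AU20": 0.7}, {}, 0.7),
        "happiness": ({"AU6": 0.85, "AU12": 0.95}, {("AU6", "AU12"): 1.3}, 1.2),
        "sadness": ({"AU1": 0.75, "AU4": 0.6, "AU15": 0.85}, {}, 0.75),
        "surprise": ({"AU1": 0.85, "AU2": 0.8, "AU5": 0.7}, {("AU1", "AU2"): 1.4}, 1.1),
        "neutral": ({}, {}, 0.6),
    }
    specs = {}
    for emo in EMOTIONS:
        probs_sig, boosts, me = sig[emo]
        probs = {au: probs_sig.get(au, bg) for au in AU_INVENTORY}
        specs[emo] = EmotionSpec(emo, probs, boosts, me)
    return specs


def recovery_spec() -> EmotionSpec:
    """Densely active AU distribution for estimator-consistency checks.

    Conditional-probability estimates P(U_i | U_j) carry binomial standard
    error ~ sqrt(p (1 - p) / N_j); with every marginal at 0.55 or above, a
    5000-set corpus yields at least ~2700 conditioning samples per AU and a
    worst-case standard error near 0.01, so estimates are expected within
    +-0.03 of the analytic joint. (Sparse emotion specs such as the default
    categories leave too few conditioning samples for that bound.)
    """
    probs = {au: p for au, p in zip(
        AU_INVENTORY,
        (0.55, 0.60, 0.65, 0.70, 0.75, 0.80, 0.85, 0.90, 0.60, 0.70, 0.80, 0.90))}
    return EmotionSpec("recovery", probs,
                       pair_boost={("AU1", "AU2"): 1.5, ("AU6", "AU12"): 0.5})


# ---------------------------------------------------------------------------
# AU label-set sampling and its analytic joint
# ---------------------------------------------------------------------------

def sample_au_corpus(spec: EmotionSpec, n: int, seed: int) -> list[frozenset[str]]:
    """Draw ``n`` non-empty AU sets from the spec's joint distribution.

    Sampling is Bernoulli per AU followed by rejection against the pairwise
    boost weights (and against the empty set), which leaves the exact joint
    proportional to ``prod p_i^{x_i}(1-p_i)^{1-x_i} * prod boost^{x_i x_j}``
    restricted to non-empty sets. Deterministic for fixed (spec, n, seed).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    ids = spec.au_ids
    probs = np.array([spec.prob(au) for au in ids])
    pos = {au: i for i, au in enumerate(ids)}
    boosts = [(pos[a], pos[b], f) for (a, b), f in spec.pair_boost.items()]
    wmax = float(np.prod([max(f, 1.0) for _, _, f in boosts])) if boosts else 1.0
    out: list[frozenset[str]] = []
    while len(out) < n:
        x = rng.random(len(ids)) < probs
        if not x.any():
            continue
        if boosts:
            w = 1.0
            for i, j, f in boosts:
                if x[i] and x[j]:
                    w *= f
            if rng.random() >= w / wmax:
                continue
        out.append(frozenset(ids[i] for i in np.flatnonzero(x)))
    return out


def analytic_joint(spec: EmotionSpec) -> tuple[np.ndarray, np.ndarray]:
    """Exact marginal and pairwise activation probabilities under the spec.

    Enumerates all subsets of the inventory (requires n <= 20), applies the
    pair-boost weights, drops the empty set, and renormalises. Returns
    ``(marginal, pair)`` with ``pair[i, j] = P(AU_i and AU_j)`` and
    ``pair[i, i] = marginal[i]``.
    """
    ids = spec.au_ids
    n = len(ids)
    if n > 20:
        raise ValueError("analytic enumeration limited to <= 20 AUs")
    probs = np.array([spec.prob(au) for au in ids])
    pos = {au: i for i, au in enumerate(ids)}
    boosts = [(pos[a], pos[b], f) for (a, b), f in spec.pair_boost.items()]
    masks = np.arange(1, 2**n, dtype=np.int64)  # skip the empty set
    bits = ((masks[:, None] >> np.arange(n)) & 1).astype(bool)
    w = np.where(bits, probs, 1.0 - probs).prod(axis=1)
    for i, j, f in boosts:
        w = np.where(bits[:, i] & bits[:, j], w * f, w)
    total = w.sum()
    if total <= 0:
        raise ValueError("spec assigns zero mass to every non-empty set")
    w = w / total
    marginal = (w[:, None] * bits).sum(axis=0)
    pair = (bits.astype(float) * w[:, None]).T @ bits.astype(float)
    np.fill_diagonal(pair, marginal)
    return marginal, pair


def analytic_adjacencies(spec: EmotionSpec) -> tuple[np.ndarray, np.ndarray]:
    """Analytic conditional P(AU_i | AU_j) and symmetric co-occurrence
    adjacency implied by the spec's joint (the recovery targets for the
    empirical estimators)."""
    marginal, pair = analytic_joint(spec)
    with np.errstate(divide="ignore", invalid="ignore"):
        cond = np.where(marginal[None, :] > 0, pair / marginal[None, :], 0.0)
        denom = marginal[:, None] + marginal[None, :]
        sym = np.where(denom > 0, 2.0 * pair / denom, 0.0)
    return cond, sym


# ---------------------------------------------------------------------------
# Clip rendering
# ---------------------------------------------------------------------------

@dataclass
class SyntheticClipRecord:
    """Ground truth for one synthetic clip."""

    clip_id: str
    subject_id: str
    emotion: str
    au_set: frozenset[str]
    au_values: dict[str, float]
    onset_frame: int
    apex_frame: int
    offset_frame: int
    n_frames: int
    seed: int = 0

    def __post_init__(self):
        self.au_set = frozenset(self.au_set)
        if self.n_frames < 4:
            raise ValueError(f"n_frames must be >= 4, got {self.n_frames}")
        if not (0 <= self.onset_frame < self.apex_frame < self.offset_frame <= self.n_frames - 1):
            raise ValueError(
                "need 0 <= onset < apex < offset <= n_frames-1, got "
                f"({self.onset_frame}, {self.apex_frame}, {self.offset_frame}) "
                f"with n_frames={self.n_frames}")
        if not self.au_set:
            raise ValueError("au_set must be non-empty")
        for au in self.au_set:
            if au not in self.au_values:
                raise ValueError(f"missing intensity for active AU {au}")
            v = self.au_values[au]
            if not (0.0 < v <= 1.0):
                raise ValueError(f"intensity for {au} outside (0,1]: {v}")

    @property
    def t_start(self) -> float:
        """Normalized onset timestamp in [0, 1]."""
        return self.onset_frame / (self.n_frames - 1)

    @property
    def t_end(self) -> float:
        """Normalized offset timestamp in [0, 1]."""
        return self.offset_frame / (self.n_frames - 1)


#: Fractional (row0, col0, row1, col1) bounds of the 12 AU regions: a 4x3
#: grid of disjoint rectangles covering the face area.
def _region_bounds(index: int) -> tuple[float, float, float, float]:
    row, col = divmod(index, 3)
    r0 = 0.06 + row * 0.23
    c0 = 0.06 + col * 0.32
    return (r0, c0, r0 + 0.17, c0 + 0.24)


def au_region(au_id: str, height: int, width: int,
              au_ids: tuple[str, ...] = AU_INVENTORY) -> tuple[slice, slice]:
    """Pixel slices of the fixed rectangular region perturbed by ``au_id``."""
    idx = au_ids.index(au_id)
    r0, c0, r1, c1 = _region_bounds(idx)
    return (slice(int(r0 * height), max(int(r1 * height), int(r0 * height) + 2)),
            slice(int(c0 * width), max(int(c1 * width), int(c0 * width) + 2)))


def base_face(height: int, width: int,
              au_ids: tuple[str, ...] = AU_INVENTORY) -> np.ndarray:
    """Deterministic grayscale base face: flat background, bright landmark
    blobs, and one distinct base intensity per AU region."""
    img = np.full((height, width), 0.60, dtype=np.float64)
    yy, xx = np.mgrid[0:height, 0:width]
    for (fy, fx) in ((0.30, 0.30), (0.30, 0.70), (0.55, 0.50), (0.78, 0.50)):
        d2 = ((yy - fy * height) / (0.05 * height)) ** 2 + ((xx - fx * width) / (0.05 * width)) ** 2
        img = np.maximum(img, 0.92 * np.exp(-0.5 * d2))
    for i, au in enumerate(au_ids):
        rs, cs = au_region(au, height, width, au_ids)
        img[rs, cs] = 0.08 + 0.04 * i
    return img


def _envelope(t: np.ndarray, onset: int, apex: int, offset: int) -> np.ndarray:
    """Quadratic ease-in/out: 0 outside (onset, offset), 1 at the apex."""
    t = np.asarray(t, dtype=np.float64)
    rise = ((t - onset) / (apex - onset)) ** 2
    fall = ((offset - t) / (offset - apex)) ** 2
    env = np.where(t <= apex, rise, fall)
    return np.where((t <= onset) | (t >= offset), 0.0, env)


def render_clip(record: SyntheticClipRecord, height: int = 64, width: int = 64,
                fps: float = 200.0,
                au_ids: tuple[str, ...] = AU_INVENTORY) -> FrameClip:
    """Render a synthetic clip for a record.

    Frames outside (onset, offset) equal the static base face exactly; each
    active AU adds ``PERTURB_AMPLITUDE * intensity * envelope(t)`` to its
    region, so inter-frame motion energy has support exactly inside
    [onset, offset] and peaks adjacent to the apex.
    """
    if height < 32 or width < 32:
        raise ValueError("height and width must be >= 32")
    base = base_face(height, width, au_ids)
    env = _envelope(np.arange(record.n_frames), record.onset_frame,
                    record.apex_frame, record.offset_frame)
    frames = np.repeat(base[None, :, :], record.n_frames, axis=0)
    for au in sorted(record.au_set):
        rs, cs = au_region(au, height, width, au_ids)
        amp = PERTURB_AMPLITUDE * record.au_values[au]
        frames[:, rs, cs] += (amp * env)[:, None, None]
    return FrameClip(np.clip(frames, 0.0, 1.0)[..., None], fps=fps)


# ---------------------------------------------------------------------------
# Corpus construction and on-disk format
# ---------------------------------------------------------------------------

def make_records(n_clips: int, n_subjects: int,
                 emotion_specs: dict[str, EmotionSpec] | None = None,
                 seed: int = 42,
                 n_frames_range: tuple[int, int] = (32, 64)) -> list[SyntheticClipRecord]:
    """Sample ground-truth records (no rendering).

    Subjects are assigned round-robin so every subject id appears at least
    once (requires ``n_clips >= n_subjects``); emotions cycle through the
    spec dictionary. Onsets fall in the first quarter of the clip and
    offsets in the last quarter, mimicking a pre-cut event clip with
    baseline frames on both sides.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if n_clips < n_subjects:
        raise ValueError("n_clips must be >= n_subjects")
    specs = emotion_specs or default_emotion_specs()
    emo_names = list(specs)
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_clips):
        emo = emo_names[i % len(emo_names)]
        spec = specs[emo]
        clip_seed = int(rng.integers(0, 2**31 - 1))
        crng = np.random.default_rng(clip_seed)
        n_frames = int(crng.integers(n_frames_range[0], n_frames_range[1] + 1))
        onset = int(crng.integers(2, max(n_frames // 4, 3)))
        offset = int(crng.integers((3 * n_frames) // 4, n_frames - 2))
        apex = int(crng.integers(onset + 1, offset))
        au_set = sample_au_corpus(spec, 1, clip_seed)[0]
        au_values = {au: float(np.round(crng.uniform(0.5, 1.0), 6)) for au in sorted(au_set)}
        records.append(SyntheticClipRecord(
            clip_id=f"clip_{i:04d}",
            subject_id=f"subj_{i % n_subjects:03d}",
            emotion=emo,
            au_set=au_set,
            au_values=au_values,
            onset_frame=onset,
            apex_frame=apex,
            offset_frame=offset,
            n_frames=n_frames,
            seed=clip_seed,
        ))
    return records


_MANIFEST_COLS = ["clip_id", "subject_id", "emotion", "n_frames",
                  "onset_frame", "apex_frame", "offset_frame"]


def make_corpus(out_dir, n_clips: int, n_subjects: int,
                emotion_specs: dict[str, EmotionSpec] | None = None,
                seed: int = 42, height: int = 64, width: int = 64,
                write_frames: bool = True) -> list[SyntheticClipRecord]:
    """Write a synthetic corpus to disk: PNG frame directories, a CSV
    manifest and a JSON label file. Byte-stable for a fixed seed."""
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = make_records(n_clips, n_subjects, emotion_specs, seed)
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(_MANIFEST_COLS)
    labels: dict[str, dict] = {}
    for rec in records:
        writer.writerow([rec.clip_id, rec.subject_id, rec.emotion, rec.n_frames,
                         rec.onset_frame, rec.apex_frame, rec.offset_frame])
        labels[rec.clip_id] = {
            "au_set": sorted(rec.au_set),
            "au_values": {au: rec.au_values[au] for au in sorted(rec.au_set)},
            "seed": rec.seed,
        }
        if write_frames:
            clip_dir = out_dir / rec.clip_id
            clip_dir.mkdir(exist_ok=True)
            clip = render_clip(rec, height, width)
            for f in range(rec.n_frames):
                frame8 = (clip.frames[f, :, :, 0] * 255).round().astype(np.uint8)
                iio.imwrite(clip_dir / f"frame_{f:04d}.png", frame8)
    (out_dir / "manifest.csv").write_text(buf.getvalue())
    (out_dir / "labels.json").write_text(json.dumps(labels, indent=1, sort_keys=True))
    return records


def load_corpus(corpus_dir) -> list[SyntheticClipRecord]:
    """Reload the records of a corpus written by :func:`make_corpus`."""
    corpus_dir = Path(corpus_dir)
    labels = json.loads((corpus_dir / "labels.json").read_text())
    records = []
    with open(corpus_dir / "manifest.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            lab = labels[row["clip_id"]]
            records.append(SyntheticClipRecord(
                clip_id=row["clip_id"],
                subject_id=row["subject_id"],
                emotion=row["emotion"],
                au_set=frozenset(lab["au_set"]),
                au_values={k: float(v) for k, v in lab["au_values"].items()},
                onset_frame=int(row["onset_frame"]),
                apex_frame=int(row["apex_frame"]),
                offset_frame=int(row["offset_frame"]),
                n_frames=int(row["n_frames"]),
                seed=int(lab.get("seed", 0)),
            ))
    return records
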