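"""Cross-validation splitters and classification metrics.

Two protocols: stratified k-fold (default k = 5) and leave-one-subject-out
(LOSO), the standard protocols for small micro-expression corpora where
subject identity leaks easily into appearance features. F1 is
macro-averaged — the unweighted mean of per-class F1 over the classes
present in either the predictions or the truth — which is the convention in
the micro-expression literature for imbalanced class distributions; this
choice matters when comparing against published numbers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import accuracy_score, f1_score

__all__ = [
    "CorpusIndex",
    "kfold_split",
    "loso_split",
    "classification_metrics",
]


@dataclass
class CorpusIndex:
    """Clip index for splitting: (clip_id, subject_id, label) triples."""

    records: list[tuple[str, str, str]]
    scheme: str = "kfold"
    k: int = 5
    seed: int = 42

    def __post_init__(self):
        ids = [r[0] for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("clip ids must be unique")
        if self.scheme not in ("kfold", "loso"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.scheme == "kfold" and self.k < 2:
            raise ValueError("k must be >= 2")
        if self.scheme == "loso" and len({r[1] for r in self.records}) < 2:
            raise ValueError("LOSO needs at least 2 distinct subjects")


def kfold_split(index: CorpusIndex) -> list[tuple[list[str], list[str]]]:
    """Stratified k-fold partition.

    Clips are shuffled within each label and dealt across folds with a
    single global rotating counter, so validation sets are disjoint,
    jointly exhaustive, label-stratified where possible, and their sizes
    differ by at most one. Deterministic for a fixed seed.
    """
    k = index.k
    if k > len(index.records):
        raise ValueError(f"k={k} exceeds number of records ({len(index.records)})")
    rng = np.random.default_rng(index.seed)
    by_label: dict[str, list[str]] = {}
    for clip_id, _, label in index.records:
        by_label.setdefault(label, []).append(clip_id)
    folds: list[list[str]] = [[] for _ in range(k)]
    counter = 0
    for label in sorted(by_label):
        ids = sorted(by_label[label])
        rng.shuffle(ids)
        for cid in ids:
            folds[counter % k].append(cid)
            counter += 1
    out = []
    for i in range(k):
        val = sorted(folds[i])
        train = sorted(cid for j in range(k) if j != i for cid in folds[j])
        out.append((train, val))
    return out


def loso_split(index: CorpusIndex) -> list[tuple[list[str], list[str]]]:
    """Leave-one-subject-out: one fold per subject, holding out all of that
    subject's clips."""
    subjects: dict[str, list[str]] = {}
    for clip_id, subject_id, _ in index.records:
        subjects.setdefault(subject_id, []).append(clip_id)
    if len(subjects) < 2:
        raise ValueError("LOSO needs at least 2 distinct subjects")
    out = []
    for subj in sorted(subjects):
        val = sorted(subjects[subj])
        train = sorted(cid for s, ids in subjects.items() if s != subj for cid in ids)
        out.append((train, val))
    return out


def classification_metrics(pred, true) -> tuple[float, float, dict[str, float]]:
    """Accuracy, macro F1 and per-class F1.

    Classes absent from both the predictions and the truth are excluded
    from the macro average.
    """
    pred = list(pred)
    true = list(true)
    if not pred or len(pred) != len(true):
        raise ValueError("predictions and truth must be equal-length and non-empty")
    labels = sorted(set(pred) | set(true))
    acc = float(accuracy_score(true, pred))
    per = f1_score(true, pred, labels=labels, average=None, zero_division=0)
    per_class = {str(l): float(f) for l, f in zip(labels, per)}
    macro = float(np.mean(per))
    return acc, macro, per_class
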