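"""Evaluation suite: EDRM, triplet mean average precision, Spearman rank
correlation and rating-distribution reporting.

EDRM scores graded similarity predictions on a bounded scale: each pair
contributes ``1 - |h - r| / d_max(r)`` where ``d_max(r)`` is the largest
distance any legal prediction could have from the reference r, i.e.
``max(r - lo, hi - r)``.  Predictions are clamped to the scale bounds
first, which keeps the metric inside [0, 1] for arbitrary raw scores.

The triplet task asks which of three candidate targets parallels a
source sentence; with a single correct answer per group, average
precision reduces to the reciprocal rank of the correct candidate and
MAP to its mean over groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .encoder import encode_corpus
from .errors import ValidationError

__all__ = ["SimilarityGold", "TripletGroup", "edrm", "map_triplets",
           "map_from_ranks", "average_precision", "spearman",
           "rating_distribution"]


@dataclass
class SimilarityGold:
    """Predicted values h against reference values r on a [lo, hi] scale."""

    h: np.ndarray
    r: np.ndarray
    lo: float = 0.0
    hi: float = 5.0

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        if self.h.shape != self.r.shape:
            raise ValidationError("h and r must have equal length")
        if self.h.size == 0:
            raise ValidationError("need at least one prediction")
        if np.any(self.r < self.lo) or np.any(self.r > self.hi):
            raise ValidationError("references must lie within [lo, hi]")

    @property
    def n(self) -> int:
        return int(self.h.size)


@dataclass(frozen=True)
class TripletGroup:
    """One source sentence with exactly three candidate targets and the
    index (0-2) of the correct one."""

    group_id: str
    source: str
    targets: tuple[str, ...]
    label: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "targets", tuple(self.targets))
        if len(self.targets) != 3:
            raise ValidationError("a triplet group needs exactly 3 targets")
        if self.label not in (0, 1, 2):
            raise ValidationError("label must index one of the 3 targets")


def edrm(gold: SimilarityGold) -> float:
    """Mean of 1 minus the relative distance to the reference.

    Predictions are clamped into [lo, hi] before scoring.  Where
    ``d_max = 0`` (reference exactly at the scale midpoint) the pair
    contributes 1 iff the prediction hits the reference exactly.
    """
    h = np.clip(gold.h, gold.lo, gold.hi)
    d = np.abs(h - gold.r)
    d_max = np.maximum(gold.r - gold.lo, gold.hi - gold.r)
    terms = np.where(d_max > 0, 1.0 - d / np.where(d_max > 0, d_max, 1.0),
                     (d == 0).astype(float))
    return float(terms.mean())


def average_precision(relevance) -> float:
    """Non-interpolated average precision of a ranked relevance list.

    Supports any number of correct answers; with a single one this is
    the reciprocal rank.
    """
    relevance = np.asarray(relevance, dtype=bool)
    n_rel = int(relevance.sum())
    if n_rel == 0:
        raise ValidationError("relevance list has no correct answer")
    positions = np.flatnonzero(relevance) + 1
    hits = np.arange(1, n_rel + 1)
    return float((hits / positions).mean())


def _rank_of_label(sims: np.ndarray, label: int) -> int:
    # descending similarity, ties -> smaller target index first
    order = sorted(range(len(sims)), key=lambda j: (-sims[j], j))
    return order.index(label) + 1


def map_triplets(groups, model, batch_size: int = 10) -> float:
    """Encode each group's source and targets, rank targets by cosine to
    the source, and average the per-group precisions."""
    groups = list(groups)
    if not groups:
        raise ValidationError("need at least one triplet group")
    src = encode_corpus([g.source for g in groups], model, batch_size).e
    tgt = encode_corpus([t for g in groups for t in g.targets],
                        model, batch_size).e
    src_n = src / np.linalg.norm(src, axis=1, keepdims=True)
    tgt_n = tgt / np.linalg.norm(tgt, axis=1, keepdims=True)
    ranks = []
    for i, g in enumerate(groups):
        sims = tgt_n[3 * i:3 * i + 3] @ src_n[i]
        ranks.append(_rank_of_label(sims, g.label))
    return map_from_ranks(ranks)


def map_from_ranks(ranks) -> float:
    """MAP from precomputed 1-based ranks of the single correct answer."""
    ranks = np.asarray(ranks, dtype=float)
    if ranks.size == 0:
        raise ValidationError("need at least one rank")
    if np.any(ranks < 1):
        raise ValidationError("ranks are 1-based")
    return float((1.0 / ranks).mean())


def spearman(x, y) -> float:
    """Spearman rank correlation with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValidationError("need two equal-length vectors of size >= 2")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValidationError("correlation undefined for constant input")
    return float(sps.spearmanr(x, y).statistic)


def rating_distribution(alignments) -> np.ndarray:
    """Counts of manual ratings 0-5, zero counts reported explicitly."""
    ratings = np.asarray([a.rating for a in alignments], dtype=int)
    if ratings.size and (ratings.min() < 0 or ratings.max() > 5):
        raise ValidationError("ratings must lie in 0-5")
    return np.bincount(ratings, minlength=6)[:6] if ratings.size \
        else np.zeros(6, dtype=int)
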