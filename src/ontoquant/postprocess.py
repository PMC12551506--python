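"""Score calibration, complementarity merging and the constraint-filtered
Pareto search over quantization configurations.

Min-max rescaling corrects over-confident raw cosine scores onto the
0-5 annotation scale.  Complementarity merging combines two models'
rated alignments in descending rating order, so each source keeps its
highest-confidence alignment and the union of sources is covered.  The
configuration search evaluates every quantization candidate against the
FP32 reference, filters by a degradation cap and a minimum size
reduction, and reports the Pareto frontier in the (quality, cost) plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .aligner import align_corpora
from .errors import ValidationError
from .quantcore import (QuantScheme, SmoothingConfig, per_channel,
                        quantize_encoder)

__all__ = ["RatedAlignment", "QuantCandidate", "EvalPoint", "Constraints",
           "SearchReport", "minmax_rescale", "complementarity_merge",
           "pareto_frontier", "search_quant_configs"]


@dataclass(frozen=True)
class RatedAlignment:
    """A manually rated alignment: lexicon source key, ontology target
    key (CUI), raw score, 0-5 rating, and the producing model's tag."""

    source_key: str
    target_key: str
    score: float
    rating: int
    model_tag: str

    def __post_init__(self) -> None:
        if self.rating not in range(6):
            raise ValidationError(f"rating {self.rating!r} outside 0-5 scale")


@dataclass(frozen=True)
class QuantCandidate:
    """One point of the quantization search space: weight granularity
    plus an optional smoothing factor (None = no smoothing)."""

    scheme: QuantScheme
    alpha: float | None
    label: str

    def __post_init__(self) -> None:
        if self.alpha is not None and not 0.0 <= self.alpha <= 1.0:
            raise ValidationError("alpha must lie in [0, 1]")


@dataclass(frozen=True)
class EvalPoint:
    """A candidate with its measured quality (argmax agreement with the
    FP32 reference, in [0, 1]) and cost (serialized weight bytes)."""

    candidate: QuantCandidate
    quality: float
    cost: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.quality <= 1.0:
            raise ValidationError("quality must lie in [0, 1]")
        if self.cost <= 0:
            raise ValidationError("cost must be positive")


@dataclass(frozen=True)
class Constraints:
    """Feasibility thresholds: at most ``max_degradation`` quality loss
    (default 0.01%) and at least ``min_cost_reduction`` size reduction
    versus FP32 (default 20%)."""

    max_degradation: float = 0.0001
    min_cost_reduction: float = 0.20

    def __post_init__(self) -> None:
        for name in ("max_degradation", "min_cost_reduction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")


def minmax_rescale(scores, lo: float = 0.0, hi: float = 5.0) -> np.ndarray:
    """Affinely map scores so their min hits ``lo`` and max hits ``hi``.

    Order-preserving; a constant input maps entirely to ``lo`` (no
    similarity evidence puts everything at the bottom of the scale).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValidationError("scores must be non-empty")
    if hi <= lo:
        raise ValidationError("hi must exceed lo")
    mn, mx = scores.min(), scores.max()
    if mx == mn:
        return np.full_like(scores, lo)
    return lo + (scores - mn) * (hi - lo) / (mx - mn)


def complementarity_merge(primary_set, secondary_set) -> list[RatedAlignment]:
    """Merge two models' alignments in descending rating order.

    Walking ratings 5 down to 0, first admit the primary model's
    alignments at that rating whose source is not yet covered, then the
    secondary model's.  The output covers exactly the union of source
    keys, with at most one alignment per source, and every primary
    rating-5 alignment retained verbatim.
    """
    primary_set = list(primary_set)
    secondary_set = list(secondary_set)
    for name, group in (("primary", primary_set), ("secondary", secondary_set)):
        keys = [a.source_key for a in group]
        if len(keys) != len(set(keys)):
            raise ValidationError(f"duplicate source_key in {name} input")
    merged: list[RatedAlignment] = []
    covered: set[str] = set()
    for rating in range(5, -1, -1):
        for group in (primary_set, secondary_set):
            for a in group:
                if a.rating == rating and a.source_key not in covered:
                    merged.append(a)
                    covered.add(a.source_key)
    return merged


def _pareto_mask(qualities, costs) -> np.ndarray:
    """Non-dominated mask via a cost-ascending sweep.  A point is
    dominated iff another has quality >= and cost <=, one strictly."""
    n = len(qualities)
    order = sorted(range(n), key=lambda i: (costs[i], -qualities[i]))
    mask = np.ones(n, dtype=bool)
    best_q_lower_cost = -np.inf
    i = 0
    while i < n:
        j = i
        while j < n and costs[order[j]] == costs[order[i]]:
            j += 1
        group = order[i:j]
        group_max = max(qualities[k] for k in group)
        for k in group:
            if best_q_lower_cost >= qualities[k] or group_max > qualities[k]:
                mask[k] = False
        best_q_lower_cost = max(best_q_lower_cost, group_max)
        i = j
    return mask


def pareto_frontier(points) -> list[EvalPoint]:
    """All points not strictly dominated in the (quality, cost) plane,
    in input order.  Exact duplicates of a frontier point are retained
    (no strict domination between ties)."""
    points = list(points)
    if not points:
        raise ValidationError("points must be non-empty")
    mask = _pareto_mask([p.quality for p in points], [p.cost for p in points])
    return [p for p, keep in zip(points, mask) if keep]


@dataclass
class SearchReport:
    """Outcome of the configuration search."""

    points: list[EvalPoint]
    feasible: list[bool]
    frontier_indices: list[int]
    best_index: int | None
    fp_cost: float

    def to_dict(self) -> dict:
        return {
            "fp32_cost_bytes": self.fp_cost,
            "candidates": [
                {
                    "label": p.candidate.label,
                    "granularity": p.candidate.scheme.granularity,
                    "alpha": p.candidate.alpha,
                    "quality": p.quality,
                    "cost_bytes": p.cost,
                    "cost_reduction": 1.0 - p.cost / self.fp_cost,
                    "feasible": bool(f),
                    "on_frontier": i in self.frontier_indices,
                }
                for i, (p, f) in enumerate(zip(self.points, self.feasible))
            ],
            "frontier_indices": self.frontier_indices,
            "best": (self.points[self.best_index].candidate.label
                     if self.best_index is not None else None),
        }


def _unpack_corpus(eval_corpus):
    if hasattr(eval_corpus, "lexicon") and hasattr(eval_corpus, "ontology"):
        return list(eval_corpus.lexicon), list(eval_corpus.ontology)
    lex, onto = eval_corpus
    return list(lex), list(onto)


def search_quant_configs(candidates, fp_reference, eval_corpus,
                         constraints: Constraints = Constraints(),
                         batch_size: int = 10) -> SearchReport:
    """Exhaustively evaluate quantization candidates against FP32.

    Quality is the fraction of lexicon rows whose argmax target matches
    the FP32 alignment; cost is the serialized weight payload in bytes.
    Feasible candidates respect both constraints; the best is the
    feasible frontier point of highest quality (ties: lowest cost).
    An empty feasible set is reported, not raised.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValidationError("candidate list must be non-empty")
    lexicon, ontology = _unpack_corpus(eval_corpus)
    fp_targets = [a.target_index
                  for a in align_corpora(lexicon, ontology, fp_reference,
                                         batch_size)]
    # calibration must represent everything the quantized model encodes
    calibration = ([e.concat_text for e in lexicon]
                   + [r.str_text for r in ontology])
    fp_cost = float(fp_reference.weight_payload_bytes())
    points: list[EvalPoint] = []
    feasible: list[bool] = []
    for cand in candidates:
        smoothing = (SmoothingConfig(alpha=cand.alpha)
                     if cand.alpha is not None else None)
        qenc = quantize_encoder(fp_reference, calibration,
                                scheme=cand.scheme, smoothing=smoothing)
        q_targets = [a.target_index
                     for a in align_corpora(lexicon, ontology, qenc,
                                            batch_size)]
        quality = float(np.mean([a == b for a, b
                                 in zip(fp_targets, q_targets)]))
        cost = float(qenc.weight_payload_bytes())
        points.append(EvalPoint(candidate=cand, quality=quality, cost=cost))
        feasible.append(
            (1.0 - quality) <= constraints.max_degradation
            and (fp_cost - cost) / fp_cost >= constraints.min_cost_reduction)
    mask = _pareto_mask([p.quality for p in points], [p.cost for p in points])
    frontier_indices = [i for i, keep in enumerate(mask) if keep]
    eligible = [i for i in frontier_indices if feasible[i]]
    best_index = None
    if eligible:
        best_index = min(eligible,
                         key=lambda i: (-points[i].quality, points[i].cost))
    return SearchReport(points=points, feasible=feasible,
                        frontier_indices=frontier_indices,
                        best_index=best_index, fp_cost=fp_cost)
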