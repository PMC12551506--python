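"""Cosine-similarity matrix construction and argmax alignment.

Two corpora — a lexicon of term+explanation texts and an ontology string
table — are encoded into embedding matrices; a dense N_L x N_M cosine
matrix is built in one pass (the naive O(n^2) formulation, kept exact on
purpose); each lexicon row maps to the ontology row maximizing its
cosine.  Alignment is many-to-one: every source maps independently, and
ties break to the smallest target index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoder import EmbeddingMatrix, encode_corpus
from .errors import ValidationError

__all__ = ["SimilarityMatrix", "AlignmentResult", "cosine_similarity_matrix",
           "align_argmax", "align_corpora"]


@dataclass
class SimilarityMatrix:
    """Dense cosine matrix; entry (i, j) compares lexicon row i with
    ontology row j.  All entries lie in [-1, 1] up to float epsilon."""

    s: np.ndarray


@dataclass(frozen=True)
class AlignmentResult:
    """One source row aligned to its best target: ``score`` is the
    cosine at (source_index, target_index), read as the mapping value
    P(c = c')."""

    source_index: int
    target_index: int
    score: float


def _normalized_rows(m: EmbeddingMatrix | np.ndarray, side: str) -> np.ndarray:
    e = m.e if isinstance(m, EmbeddingMatrix) else np.asarray(m, dtype=float)
    norms = np.linalg.norm(e, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise ValidationError(
            f"zero-norm embedding row {int(zero[0])} on the {side} side: "
            "cosine similarity is undefined")
    return e / norms[:, None]


def cosine_similarity_matrix(a, b) -> SimilarityMatrix:
    """s[i, j] = <a_i, b_j> / (||a_i|| ||b_j||)."""
    an = _normalized_rows(a, "left")
    bn = _normalized_rows(b, "right")
    if an.shape[1] != bn.shape[1]:
        raise ValidationError(
            f"embedding dimensions disagree: {an.shape[1]} vs {bn.shape[1]}")
    return SimilarityMatrix(s=an @ bn.T)


def align_argmax(sim: SimilarityMatrix) -> list[AlignmentResult]:
    """Row-wise argmax with ties broken to the smallest target index.

    Equals the exhaustive per-row scan on every input.
    """
    s = sim.s
    if s.size == 0:
        raise ValidationError("similarity matrix must be non-empty")
    j_star = np.argmax(s, axis=1)  # first maximal index per row
    return [AlignmentResult(source_index=i, target_index=int(j),
                            score=float(s[i, j]))
            for i, j in enumerate(j_star)]


def align_corpora(lexicon, ontology, model, batch_size: int = 10
                  ) -> list[AlignmentResult]:
    """Encode both corpora and return the argmax alignment of every
    lexicon entry (its term+explanation concatenation) against the
    ontology surface strings."""
    lexicon = list(lexicon)
    ontology = list(ontology)
    if not lexicon or not ontology:
        raise ValidationError("both corpora must be non-empty")
    e_lex = encode_corpus([e.concat_text for e in lexicon], model,
                          batch_size, provenance="LEX")
    e_ont = encode_corpus([r.str_text for r in ontology], model,
                          batch_size, provenance="ONT")
    return align_argmax(cosine_similarity_matrix(e_lex, e_ont))
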