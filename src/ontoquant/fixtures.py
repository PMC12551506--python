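"""Seeded synthetic-data generators with known ground truth.

Every generator emulates the shape of the real study inputs — a layman
lexicon paired with an ontology string table, scored sentence pairs, and
grouped triplets with one correct target — without any licensed data.
Each synthetic concept owns a disjoint set of base tokens; noise tokens
come from a separate pool so the noise rate controls task difficulty
monotonically.  All draws flow from one named generator per call, so
outputs are byte-identical per seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .evaluation import TripletGroup
from .io_formats import (ColumnSpec, GoldPair, LexiconEntry, OntologyRecord,
                         write_gold_pairs, write_gold_triplets,
                         write_lexicon, write_rrf)

__all__ = ["SynthConfig", "SynthCorpora", "gen_aligned_corpora",
           "gen_similarity_pairs", "gen_triplets", "BASE_TOKENS_PER_CONCEPT"]

# Tokens per concept base sequence: two feed the term, the rest the
# explanation, mirroring short dictionary-style entries.
BASE_TOKENS_PER_CONCEPT = 6


@dataclass(frozen=True)
class SynthConfig:
    """Conditions of the synthetic alignment corpus.

    ``noise_rate`` is the probability that any emitted token is replaced
    by a pool token; ``synonyms_per_side`` is the number of surface
    variants each concept gets in the lexicon and in the ontology table.
    """

    n_concepts: int = 50
    synonyms_per_side: int = 2
    noise_rate: float = 0.1
    pool_size: int = 100
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_concepts < 2:
            raise ValidationError("need at least 2 concepts")
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ValidationError("noise_rate must lie in [0, 1]")
        if self.synonyms_per_side < 1 or self.pool_size < 1:
            raise ValidationError("synonyms_per_side and pool_size must be >= 1")


@dataclass
class SynthCorpora:
    """Generated lexicon + ontology with their ground-truth mapping.

    ``truth[i]`` is the CUI every alignment of lexicon row i should hit.
    """

    lexicon: list[LexiconEntry]
    ontology: list[OntologyRecord]
    truth: list[str]
    lexicon_path: Path | None = None
    ontology_path: Path | None = None


def _cui(k: int) -> str:
    return f"C{k:07d}"


def _noisify(tokens: list[str], pool: list[str], rate: float,
             rng: np.random.Generator) -> list[str]:
    return [pool[int(rng.integers(len(pool)))] if rng.random() < rate else t
            for t in tokens]


def gen_aligned_corpora(cfg: SynthConfig = SynthConfig(),
                        out_dir: str | Path | None = None) -> SynthCorpora:
    """Generate an aligned lexicon/ontology pair with ground truth.

    Concept k owns base tokens c{k}t0..c{k}t5.  Lexicon variants emit a
    term (first two base tokens) and explanation (the rest plus a
    variant affix); ontology variants emit all base tokens plus an
    affix, under one synthetic CUI per concept.  Every emitted base
    token is independently replaced by a pool token with probability
    ``noise_rate``.  With ``out_dir`` set, a lexicon TSV and ontology
    RRF are written in the exact dialects the readers consume.
    """
    rng = np.random.default_rng(cfg.seed)
    pool = [f"zz{j:03d}" for j in range(cfg.pool_size)]
    spec = ColumnSpec()
    lexicon: list[LexiconEntry] = []
    ontology: list[OntologyRecord] = []
    truth: list[str] = []
    for k in range(cfg.n_concepts):
        base = [f"c{k:03d}t{i}" for i in range(BASE_TOKENS_PER_CONCEPT)]
        cui = _cui(k)
        for v in range(cfg.synonyms_per_side):
            term = " ".join(_noisify(base[:2], pool, cfg.noise_rate, rng))
            expl_tokens = _noisify(base[2:], pool, cfg.noise_rate, rng)
            explanation = " ".join(expl_tokens + [f"lay{v}"])
            lexicon.append(LexiconEntry.build(term, explanation))
            truth.append(cui)
        for v in range(cfg.synonyms_per_side):
            str_tokens = _noisify(base, pool, cfg.noise_rate, rng)
            str_text = " ".join(str_tokens + [f"ont{v}"])
            extras = _rrf_extras(k, v, spec)
            ontology.append(OntologyRecord(cui=cui, lat="ENG",
                                           str_text=str_text, extras=extras))
    corpora = SynthCorpora(lexicon=lexicon, ontology=ontology, truth=truth)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        corpora.lexicon_path = out_dir / "lexicon.tsv"
        corpora.ontology_path = out_dir / "ontology.rrf"
        write_lexicon(lexicon, corpora.lexicon_path)
        write_rrf(ontology, corpora.ontology_path, spec)
    return corpora


def _rrf_extras(k: int, v: int, spec: ColumnSpec) -> tuple[str, ...]:
    """Plausible filler for the non-CUI/LAT/STR columns of an atom row."""
    by_index = {2: "P", 3: f"L{k:07d}", 4: "PF", 5: f"S{k:07d}{v}",
                6: "Y", 7: f"A{k:07d}{v}", 11: "SYNTH", 12: "SY",
                13: f"X{k}{v}", 15: "0", 16: "N"}
    return tuple(by_index.get(i, "") for i in spec.extra_indices)


def gen_similarity_pairs(n_pairs: int, seed: int,
                         out_path: str | Path | None = None,
                         sentence_len: int = 10) -> list[GoldPair]:
    """Generate scored sentence pairs with construction-guaranteed marks.

    Each pair draws an overlap fraction rho uniformly; its two sentences
    share ceil(rho * len) tokens and the mark is round(5 * rho), so the
    token-overlap signal is monotone in the annotation.
    """
    if n_pairs < 1:
        raise ValidationError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    pairs: list[GoldPair] = []
    for p in range(n_pairs):
        rho = float(rng.random())
        n_shared = math.ceil(rho * sentence_len)
        shared = [f"p{p:04d}s{i}" for i in range(n_shared)]
        uniq_a = [f"p{p:04d}a{i}" for i in range(sentence_len - n_shared)]
        uniq_b = [f"p{p:04d}b{i}" for i in range(sentence_len - n_shared)]
        source = " ".join(shared + uniq_a)
        target = " ".join(shared + uniq_b)
        mark = int(np.rint(5 * rho))
        pairs.append(GoldPair(pair_id=str(p), source=source, target=target,
                              mark=mark))
    if out_path is not None:
        write_gold_pairs(pairs, out_path)
    return pairs


def gen_triplets(n_groups: int, dropout: float, seed: int,
                 out_path: str | Path | None = None,
                 sentence_len: int = 8) -> list[TripletGroup]:
    """Generate grouped triplets with one correct target per group.

    The correct target is the source with each token independently
    dropped with probability ``dropout`` (at least one token survives);
    the two distractors are other groups' sources, which share no
    tokens.  The correct target's position is randomized per group.
    """
    if not 0.0 <= dropout < 1.0:
        raise ValidationError("dropout must lie in [0, 1)")
    if n_groups < 3:
        raise ValidationError("need at least 3 groups for distractors")
    rng = np.random.default_rng(seed)
    sources = [" ".join(f"g{i:04d}w{j}" for j in range(sentence_len))
               for i in range(n_groups)]
    groups: list[TripletGroup] = []
    for i in range(n_groups):
        tokens = sources[i].split()
        kept = [t for t in tokens if rng.random() >= dropout]
        correct = " ".join(kept) if kept else tokens[0]
        others = [j for j in range(n_groups) if j != i]
        d1, d2 = rng.choice(others, size=2, replace=False)
        label = int(rng.integers(3))
        targets = [sources[int(d1)], sources[int(d2)]]
        targets.insert(label, correct)
        groups.append(TripletGroup(group_id=str(i), source=sources[i],
                                   targets=targets, label=label))
    if out_path is not None:
        write_gold_triplets(groups, out_path)
    return groups
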