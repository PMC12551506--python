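"""Readers and writers for the file dialects the pipeline consumes.

Covers the pipe-delimited RRF ontology string table (MRCONSO-style, with
a trailing delimiter), the lexicon TSV of layman terms with public-facing
explanations, gold evaluation files (scored sentence pairs and grouped
triplets), rated-alignment TSVs, and YAML/JSON run configs.  The text
normalizer and the CUI left-join used for semantic enrichment live here
as well.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .errors import FormatError, ValidationError

__all__ = [
    "OntologyRecord",
    "LexiconEntry",
    "ColumnSpec",
    "GoldPair",
    "read_rrf",
    "write_rrf",
    "read_lexicon",
    "write_lexicon",
    "normalize_text",
    "left_join_cui",
    "read_gold_pairs",
    "write_gold_pairs",
    "read_gold_triplets",
    "write_gold_triplets",
    "read_rated_alignments",
    "write_rated_alignments",
    "read_run_config",
]


@dataclass(frozen=True)
class ColumnSpec:
    """Layout of an RRF file: delimiter, trailing-delimiter flag and the
    0-based positions of the concept identifier (CUI), language and
    string columns.

    Defaults follow the standard MRCONSO layout (CUI=0, LAT=1, STR=14,
    18 columns) but are configurable.
    """

    delimiter: str = "|"
    trailing_delimiter: bool = True
    index_cui: int = 0
    index_lat: int = 1
    index_str: int = 14
    n_columns: int = 18

    def __post_init__(self) -> None:
        if len(self.delimiter) != 1:
            raise ValidationError("delimiter must be a single character")
        idx = (self.index_cui, self.index_lat, self.index_str)
        if len(set(idx)) != 3:
            raise ValidationError("column indices must be distinct")
        if any(i < 0 or i >= self.n_columns for i in idx):
            raise ValidationError("column indices must lie below n_columns")

    @property
    def extra_indices(self) -> tuple[int, ...]:
        named = {self.index_cui, self.index_lat, self.index_str}
        return tuple(i for i in range(self.n_columns) if i not in named)


@dataclass(frozen=True)
class OntologyRecord:
    """One atom of the ontology string table: a surface string attached
    to a concept identifier, plus the remaining columns in file order."""

    cui: str
    lat: str
    str_text: str
    extras: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.cui:
            raise ValidationError("cui must be non-empty")
        if not self.str_text:
            raise ValidationError("str_text must be non-empty")


@dataclass(frozen=True)
class LexiconEntry:
    """A lexicon row: a term, its public explanation, their concatenation
    (the text that is actually encoded) and an optional 0-5 rating."""

    term: str
    explanation: str
    concat_text: str
    rating: int | None = None

    def __post_init__(self) -> None:
        if self.rating is not None and self.rating not in range(6):
            raise ValidationError(f"rating {self.rating!r} outside 0-5 scale")

    @classmethod
    def build(cls, term: str, explanation: str, rating: int | None = None,
              sep: str = " ") -> "LexiconEntry":
        return cls(term=term, explanation=explanation,
                   concat_text=f"{term}{sep}{explanation}", rating=rating)


@dataclass(frozen=True)
class GoldPair:
    """A scored sentence pair: source, target and an integer 0-5 mark."""

    pair_id: str
    source: str
    target: str
    mark: int

    def __post_init__(self) -> None:
        if self.mark not in range(6):
            raise ValidationError(f"mark {self.mark!r} outside 0-5 scale")


# ---------------------------------------------------------------------------
# RRF ontology table


def read_rrf(path: str | Path, spec: ColumnSpec = ColumnSpec(),
             lang_filter: str | None = None) -> list[OntologyRecord]:
    """Parse a pipe-delimited RRF file into :class:`OntologyRecord` rows.

    Empty lines are skipped; a line with the wrong field count raises a
    :class:`FormatError` naming the 1-based line number.  With
    ``lang_filter`` only records whose language column matches are kept.
    """
    records: list[OntologyRecord] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split(spec.delimiter)
            if spec.trailing_delimiter:
                if fields[-1] != "":
                    raise FormatError(
                        f"line {lineno}: missing trailing delimiter")
                fields = fields[:-1]
            if len(fields) != spec.n_columns:
                raise FormatError(
                    f"line {lineno}: expected {spec.n_columns} fields, "
                    f"got {len(fields)}")
            rec = OntologyRecord(
                cui=fields[spec.index_cui],
                lat=fields[spec.index_lat],
                str_text=fields[spec.index_str],
                extras=tuple(fields[i] for i in spec.extra_indices),
            )
            if lang_filter is None or rec.lat == lang_filter:
                records.append(rec)
    return records


def write_rrf(records: Iterable[OntologyRecord], path: str | Path,
              spec: ColumnSpec = ColumnSpec()) -> None:
    """Write records back to the RRF dialect described by ``spec``.

    Together with :func:`read_rrf` this round-trips well-formed files
    byte-for-byte.
    """
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for rec in records:
            if len(rec.extras) != spec.n_columns - 3:
                raise ValidationError(
                    f"record has {len(rec.extras)} extra fields, "
                    f"spec requires {spec.n_columns - 3}")
            fields = [""] * spec.n_columns
            fields[spec.index_cui] = rec.cui
            fields[spec.index_lat] = rec.lat
            fields[spec.index_str] = rec.str_text
            for i, value in zip(spec.extra_indices, rec.extras):
                fields[i] = value
            line = spec.delimiter.join(fields)
            if spec.trailing_delimiter:
                line += spec.delimiter
            fh.write(line + "\n")


# ---------------------------------------------------------------------------
# Lexicon TSV


def read_lexicon(path: str | Path, has_rating: bool = False,
                 sep: str = " ") -> list[LexiconEntry]:
    """Read a lexicon TSV (header: term, explanation[, rating]).

    ``concat_text`` joins term and explanation with ``sep`` (a single
    space by default).  Row order is preserved.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("term", "explanation"):
        if col not in df.columns:
            raise FormatError(f"lexicon file missing required column {col!r}")
    if has_rating and "rating" not in df.columns:
        raise FormatError("lexicon file missing required column 'rating'")
    entries: list[LexiconEntry] = []
    for row in df.itertuples(index=False):
        rating: int | None = None
        if "rating" in df.columns:
            raw = str(getattr(row, "rating"))
            try:
                rating = int(raw)
            except ValueError as exc:
                raise ValidationError(f"unparseable rating {raw!r}") from exc
        entries.append(LexiconEntry.build(row.term, row.explanation,
                                          rating=rating, sep=sep))
    return entries


def write_lexicon(entries: Iterable[LexiconEntry], path: str | Path) -> None:
    entries = list(entries)
    with_rating = any(e.rating is not None for e in entries)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        header = "term\texplanation" + ("\trating" if with_rating else "")
        fh.write(header + "\n")
        for e in entries:
            row = f"{e.term}\t{e.explanation}"
            if with_rating:
                row += f"\t{e.rating if e.rating is not None else ''}"
            fh.write(row + "\n")


# ---------------------------------------------------------------------------
# Text normalization

_NON_ALNUM = re.compile(r"[\W_]+", re.UNICODE)


def normalize_text(text: str, stopwords: frozenset[str] | set[str] = frozenset()
                   ) -> str:
    """Lowercase, map every non-alphanumeric run to one space, collapse
    whitespace, strip, and drop stopword tokens.  Idempotent."""
    tokens = _NON_ALNUM.sub(" ", text.lower()).split()
    return " ".join(t for t in tokens if t not in stopwords)


# ---------------------------------------------------------------------------
# CUI left-join


def left_join_cui(primary: Sequence[Mapping], aux: Sequence[Mapping],
                  key: str = "cui") -> list[dict]:
    """Left-join two row sequences on a shared concept-identifier key.

    Every primary row appears at least once; k matching aux rows yield k
    output rows; zero matches yield one row with the aux fields set to
    None.  Aux field names colliding with primary ones are prefixed with
    ``aux_``.  Primary order is preserved.
    """
    index: dict[str, list[Mapping]] = {}
    aux_fields: list[str] = []
    for row in aux:
        index.setdefault(row[key], []).append(row)
        for name in row:
            if name != key and name not in aux_fields:
                aux_fields.append(name)
    out: list[dict] = []
    for row in primary:
        matches = index.get(row[key], [None])
        for m in matches:
            joined = dict(row)
            for name in aux_fields:
                target = name if name not in row else f"aux_{name}"
                joined[target] = None if m is None else m.get(name)
            out.append(joined)
    return out


# ---------------------------------------------------------------------------
# Gold files


def read_gold_pairs(path: str | Path) -> list[GoldPair]:
    """Read a gold pair TSV (header: id, source, target, mark)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("id", "source", "target", "mark"):
        if col not in df.columns:
            raise FormatError(f"gold pair file missing column {col!r}")
    pairs = []
    for row in df.itertuples(index=False):
        try:
            mark = int(row.mark)
        except ValueError as exc:
            raise ValidationError(f"unparseable mark {row.mark!r}") from exc
        pairs.append(GoldPair(row.id, row.source, row.target, mark))
    return pairs


def write_gold_pairs(pairs: Iterable[GoldPair], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("id\tsource\ttarget\tmark\n")
        for p in pairs:
            fh.write(f"{p.pair_id}\t{p.source}\t{p.target}\t{p.mark}\n")


def read_gold_triplets(path: str | Path):
    """Read a grouped-triplet TSV (header: id, num, source, target, label).

    Each group ``num`` must hold exactly three candidate rows sharing one
    source, with the label column 1 on exactly one of them.  Returns
    :class:`~ontoquant.evaluation.TripletGroup` objects in file order.
    """
    from .evaluation import TripletGroup  # local: avoids an import cycle

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("id", "num", "source", "target", "label"):
        if col not in df.columns:
            raise FormatError(f"triplet file missing column {col!r}")
    groups: list = []
    seen: dict[str, list] = {}
    order: list[str] = []
    for row in df.itertuples(index=False):
        if row.num not in seen:
            order.append(row.num)
        seen.setdefault(row.num, []).append(row)
    for num in order:
        rows = seen[num]
        if len(rows) != 3:
            raise FormatError(f"group {num!r} has {len(rows)} rows, expected 3")
        sources = {r.source for r in rows}
        if len(sources) != 1:
            raise FormatError(f"group {num!r} has inconsistent sources")
        labels = [int(r.label) for r in rows]
        if sorted(labels) != [0, 0, 1]:
            raise FormatError(f"group {num!r} must have exactly one label=1")
        groups.append(TripletGroup(
            group_id=num, source=rows[0].source,
            targets=[r.target for r in rows], label=labels.index(1)))
    return groups


def write_gold_triplets(groups, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("id\tnum\tsource\ttarget\tlabel\n")
        row_id = 0
        for g in groups:
            for j, target in enumerate(g.targets):
                label = 1 if j == g.label else 0
                fh.write(f"{row_id}\t{g.group_id}\t{g.source}\t{target}\t{label}\n")
                row_id += 1


# ---------------------------------------------------------------------------
# Rated alignments


def read_rated_alignments(path: str | Path):
    """Read a rated-alignment TSV (header: source_key, target_key, score,
    rating, model_tag)."""
    from .postprocess import RatedAlignment  # local: avoids an import cycle

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("source_key", "target_key", "score", "rating", "model_tag"):
        if col not in df.columns:
            raise FormatError(f"rated alignment file missing column {col!r}")
    return [RatedAlignment(r.source_key, r.target_key, float(r.score),
                           int(r.rating), r.model_tag)
            for r in df.itertuples(index=False)]


def write_rated_alignments(alignments, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("source_key\ttarget_key\tscore\trating\tmodel_tag\n")
        for a in alignments:
            fh.write(f"{a.source_key}\t{a.target_key}\t{a.score!r}\t"
                     f"{a.rating}\t{a.model_tag}\n")


# ---------------------------------------------------------------------------
# Run config

_CONFIG_SECTIONS = ("input_model", "data_config", "evaluation",
                    "search_strategy")


def read_run_config(path: str | Path) -> dict:
    """Load a YAML or JSON run config.

    Recognized top-level sections: input_model, data_config, evaluation,
    search_strategy.  Unknown sections raise a :class:`FormatError`.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        cfg = json.loads(text)
    else:
        cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise FormatError("run config must be a mapping")
    unknown = set(cfg) - set(_CONFIG_SECTIONS)
    if unknown:
        raise FormatError(f"unknown config sections: {sorted(unknown)}")
    return cfg
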