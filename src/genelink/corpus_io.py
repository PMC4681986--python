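"""Parsed-corpus I/O and structural validation.

The pipeline consumes dependency-parsed text: documents split into sentences,
each sentence a list of tokens carrying surface word, lemma, Penn-style POS
tag, an optional NER tag, and a dependency edge to a governing token.  The
canonical on-disk format is JSON Lines, one document per line; tabular
outputs (called extractions) are TSV.  Parsing itself (sentence splitting,
tagging, dependency analysis) happens upstream — this module only reads,
validates and writes the already-parsed representation.

Conventions: token indices and ``dep_head`` are 0-based; ``dep_head == -1``
marks a root.  Multi-root or disconnected parses are representable (real
parsers produce them) and are handled gracefully downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

__all__ = [
    "Token",
    "ParsedSentence",
    "Document",
    "ExtractionRecord",
    "CorpusFormatError",
    "read_corpus",
    "write_corpus",
    "read_extractions",
    "write_extractions",
    "canonical_pair",
]

EXTRACTION_COLUMNS = ("doc_id", "sent_index", "gene1", "gene2", "probability", "called")


class CorpusFormatError(ValueError):
    """Raised when a corpus or extraction file violates the format contract."""


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Return the unordered symbol pair in canonical (sorted) order."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class Token:
    index: int
    word: str
    lemma: str
    pos: str
    ner: str
    dep_head: int
    dep_label: str


@dataclass(frozen=True)
class ParsedSentence:
    doc_id: str
    sent_index: int
    tokens: tuple[Token, ...]

    def __len__(self) -> int:
        return len(self.tokens)

    def validate(self) -> None:
        n = len(self.tokens)
        if n == 0:
            raise CorpusFormatError(
                f"doc {self.doc_id!r} sentence {self.sent_index}: zero tokens"
            )
        for pos_i, tok in enumerate(self.tokens):
            if tok.index != pos_i:
                raise CorpusFormatError(
                    f"doc {self.doc_id!r} sentence {self.sent_index}: token indices "
                    f"not contiguous (saw {tok.index} at position {pos_i})"
                )
            if tok.dep_head == tok.index:
                raise CorpusFormatError(
                    f"doc {self.doc_id!r} sentence {self.sent_index}: token "
                    f"{tok.index} is its own dependency head"
                )
            if tok.dep_head != -1 and not (0 <= tok.dep_head < n):
                raise CorpusFormatError(
                    f"doc {self.doc_id!r} sentence {self.sent_index}: token "
                    f"{tok.index} dep_head {tok.dep_head} out of range [0, {n})"
                )

    @property
    def lemmas(self) -> frozenset[str]:
        return frozenset(t.lemma for t in self.tokens)


@dataclass(frozen=True)
class Document:
    doc_id: str
    pub_year: int | None
    sentences: tuple[ParsedSentence, ...]

    def validate(self) -> None:
        prev = -1
        for sent in self.sentences:
            if sent.sent_index <= prev:
                raise CorpusFormatError(
                    f"doc {self.doc_id!r}: sent_index values not strictly "
                    f"increasing ({sent.sent_index} after {prev})"
                )
            prev = sent.sent_index
            sent.validate()


@dataclass(frozen=True)
class ExtractionRecord:
    doc_id: str
    sent_index: int
    gene1: str
    gene2: str
    probability: float
    called: bool

    def __post_init__(self) -> None:
        if not (self.gene1 < self.gene2):
            raise ValueError(
                f"extraction pair not canonical: {self.gene1!r} !< {self.gene2!r}"
            )
        if not (0.0 <= self.probability <= 1.0):
            raise ValueError(f"probability {self.probability} outside [0, 1]")


# ---------------------------------------------------------------------------
# JSONL corpus


def _token_from_json(obj: dict, where: str) -> Token:
    try:
        return Token(
            index=int(obj["index"]),
            word=str(obj["word"]),
            lemma=str(obj["lemma"]),
            pos=str(obj["pos"]),
            ner=str(obj.get("ner", "") or ""),
            dep_head=int(obj["dep_head"]),
            dep_label=str(obj["dep_label"]),
        )
    except KeyError as exc:
        raise CorpusFormatError(f"{where}: token missing field {exc.args[0]!r}") from exc


def document_from_json(obj: dict, where: str = "document") -> Document:
    try:
        doc_id = str(obj["doc_id"])
    except KeyError as exc:
        raise CorpusFormatError(f"{where}: missing field 'doc_id'") from exc
    year = obj.get("pub_year")
    sentences = []
    for sent_obj in obj.get("sentences", []):
        try:
            sent_index = int(sent_obj["sent_index"])
            raw_tokens = sent_obj["tokens"]
        except KeyError as exc:
            raise CorpusFormatError(
                f"{where}: doc {doc_id!r} sentence missing field {exc.args[0]!r}"
            ) from exc
        tokens = tuple(
            _token_from_json(t, f"{where}: doc {doc_id!r} sent {sent_index}")
            for t in raw_tokens
        )
        sentences.append(ParsedSentence(doc_id=doc_id, sent_index=sent_index, tokens=tokens))
    doc = Document(
        doc_id=doc_id,
        pub_year=None if year is None else int(year),
        sentences=tuple(sentences),
    )
    doc.validate()
    return doc


def document_to_json(doc: Document) -> dict:
    return {
        "doc_id": doc.doc_id,
        "pub_year": doc.pub_year,
        "sentences": [
            {
                "sent_index": s.sent_index,
                "tokens": [
                    {
                        "index": t.index,
                        "word": t.word,
                        "lemma": t.lemma,
                        "pos": t.pos,
                        "ner": t.ner,
                        "dep_head": t.dep_head,
                        "dep_label": t.dep_label,
                    }
                    for t in s.tokens
                ],
            }
            for s in doc.sentences
        ],
    }


def read_corpus(path: str | Path) -> Iterator[Document]:
    """Stream validated :class:`Document` objects from a JSONL corpus file.

    Raises :class:`CorpusFormatError` naming the offending line on malformed
    JSON or any structural-invariant violation.  An empty file yields an
    empty stream.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"{path}:{lineno}: invalid JSON ({exc.msg})") from exc
            yield document_from_json(obj, where=f"{path}:{lineno}")


def write_corpus(path: str | Path, documents: Iterable[Document]) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as handle:
        for doc in documents:
            doc.validate()
            handle.write(json.dumps(document_to_json(doc), sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# Extraction TSV


def write_extractions(path: str | Path, records: Iterable[ExtractionRecord]) -> None:
    """Write extraction records as TSV (header + one row per record).

    Probabilities are printed with 6 decimal places; ``read_extractions``
    on the output reproduces the records.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as handle:
        handle.write("\t".join(EXTRACTION_COLUMNS) + "\n")
        for rec in records:
            handle.write(
                f"{rec.doc_id}\t{rec.sent_index}\t{rec.gene1}\t{rec.gene2}\t"
                f"{rec.probability:.6f}\t{str(rec.called).lower()}\n"
            )


def read_extractions(path: str | Path) -> list[ExtractionRecord]:
    path = Path(path)
    records: list[ExtractionRecord] = []
    with path.open("r", encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if tuple(header) != EXTRACTION_COLUMNS:
            raise CorpusFormatError(
                f"{path}: expected columns {EXTRACTION_COLUMNS}, found {tuple(header)}"
            )
        for lineno, line in enumerate(handle, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(EXTRACTION_COLUMNS):
                raise CorpusFormatError(f"{path}:{lineno}: expected {len(EXTRACTION_COLUMNS)} columns")
            doc_id, sent_index, gene1, gene2, prob, called = parts
            records.append(
                ExtractionRecord(
                    doc_id=doc_id,
                    sent_index=int(sent_index),
                    gene1=gene1,
                    gene2=gene2,
                    probability=float(prob),
                    called=called == "true",
                )
            )
    return records
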