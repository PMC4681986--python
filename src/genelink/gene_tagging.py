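"""Dictionary-based gene mention tagging and symbol-to-identifier resolution.

Tagging is deliberately simple and high-recall: a token is a gene mention iff
its surface word occurs, byte-for-byte, in a dictionary of official and
alternate human gene symbols.  Matching is case-sensitive and single-token
only; full gene names are not recognized.  Tokens that double as ordinary
acronyms are still tagged — disambiguation is delegated to the learned
feature weights downstream.

A symbol may map to several gene identifiers (alternate symbols are
ambiguous in real nomenclature).  Ambiguity is preserved through the
pipeline and only resolved at reporting time: pairs involving any ambiguous
symbol are excluded rather than guessed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .corpus_io import ParsedSentence, canonical_pair

__all__ = [
    "GeneDictionary",
    "GeneMention",
    "DictionaryFormatError",
    "load_dictionary",
    "tag_genes",
    "resolve_gene_ids",
]

logger = logging.getLogger(__name__)

DICTIONARY_COLUMNS = ("symbol", "gene_id", "is_official")


class DictionaryFormatError(ValueError):
    pass


@dataclass(frozen=True)
class GeneMention:
    token_index: int
    symbol: str


@dataclass
class GeneDictionary:
    """symbol -> set of gene identifiers, with an official/alternate flag per entry."""

    entries: dict[str, set[str]] = field(default_factory=dict)
    official: dict[tuple[str, str], bool] = field(default_factory=dict)

    def add(self, symbol: str, gene_id: str, is_official: bool) -> None:
        if not symbol:
            raise DictionaryFormatError("blank gene symbol")
        self.entries.setdefault(symbol, set()).add(gene_id)
        self.official[(symbol, gene_id)] = is_official

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.entries

    def identifiers(self, symbol: str) -> set[str]:
        return self.entries[symbol]

    @property
    def symbols(self) -> set[str]:
        return set(self.entries)


def load_dictionary(path: str | Path) -> GeneDictionary:
    """Load a gene-symbol dictionary from TSV with columns symbol, gene_id, is_official.

    Duplicate (symbol, gene_id) rows are deduplicated; multi-token symbols are
    skipped with a warning because tagging is single-token only.
    """
    path = Path(path)
    gd = GeneDictionary()
    with path.open("r", encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if tuple(header) != DICTIONARY_COLUMNS:
            raise DictionaryFormatError(
                f"{path}: expected columns {DICTIONARY_COLUMNS}, found {tuple(header)}"
            )
        for lineno, line in enumerate(handle, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise DictionaryFormatError(f"{path}:{lineno}: expected 3 columns")
            symbol, gene_id, is_official = parts
            if not symbol:
                raise DictionaryFormatError(f"{path}:{lineno}: blank symbol")
            if " " in symbol:
                logger.warning("skipping multi-token symbol %r (%s:%d)", symbol, path, lineno)
                continue
            gd.add(symbol, gene_id, is_official.strip().lower() == "true")
    return gd


def tag_genes(sentence: ParsedSentence, dictionary: GeneDictionary) -> list[GeneMention]:
    """Tag tokens whose surface word exactly matches a dictionary symbol.

    Case-sensitive, single-token matches only; mentions returned in token
    order.  An empty result is valid.
    """
    return [
        GeneMention(token_index=tok.index, symbol=tok.word)
        for tok in sentence.tokens
        if tok.word in dictionary
    ]


def resolve_gene_ids(
    pairs: Iterable[tuple[str, str]], dictionary: GeneDictionary
) -> tuple[set[tuple[str, str]], list[tuple[str, str]]]:
    """Convert symbol pairs to gene-identifier pairs, excluding ambiguous mappings.

    A pair is resolved only when both symbols map to exactly one identifier;
    pairs involving a symbol with multiple identifiers go to the excluded
    list.  Distinct symbol pairs that resolve to the same identifier pair are
    merged.  Returns ``(resolved_id_pairs, excluded_symbol_pairs)``.
    """
    resolved: set[tuple[str, str]] = set()
    excluded: list[tuple[str, str]] = []
    for a, b in pairs:
        for sym in (a, b):
            if sym not in dictionary:
                raise KeyError(f"symbol {sym!r} not in dictionary")
        ids_a = dictionary.identifiers(a)
        ids_b = dictionary.identifiers(b)
        if len(ids_a) == 1 and len(ids_b) == 1:
            resolved.add(canonical_pair(next(iter(ids_a)), next(iter(ids_b))))
        else:
            excluded.append(canonical_pair(a, b))
    return resolved, excluded
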