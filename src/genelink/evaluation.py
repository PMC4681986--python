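"""Evaluation: document-level aggregation, precision/recall, calibration, trends.

Document-level evaluation picks, for every gene pair in a document, the
sentence-level candidate with the highest probability as the representative
interaction.  Precision/recall are computed against a per-document gold
standard of curated pairs, optionally augmented with a "rescue" set of true
positives the gold-standard database missed; predictions in documents the
gold standard never curated are ignored rather than counted as false
positives.  Calibration compares predicted probability with empirical
accuracy on held-out labeled candidates, in ten equal-width bins.
Interaction trends count, per gene and year, documents containing at least
one called interaction involving the gene, normalized by that year's total
interaction-document count.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .corpus_io import Document, ExtractionRecord, canonical_pair

__all__ = [
    "GoldStandard",
    "Metrics",
    "CalibrationBin",
    "aggregate_document_level",
    "precision_recall",
    "curation_precision",
    "calibration_bins",
    "interaction_trends",
    "load_gold_standard",
]

logger = logging.getLogger(__name__)

Pair = tuple[str, str]
DocPair = tuple[str, Pair]


@dataclass(frozen=True)
class GoldStandard:
    pairs_by_doc: frozenset[DocPair]
    rescue_pairs: frozenset[DocPair] = frozenset()

    def __post_init__(self) -> None:
        if self.pairs_by_doc & self.rescue_pairs:
            raise ValueError("rescue pairs must be disjoint from the base gold set")

    @property
    def documents(self) -> frozenset[str]:
        return frozenset(d for d, _ in self.pairs_by_doc) | frozenset(
            d for d, _ in self.rescue_pairs
        )


@dataclass(frozen=True)
class Metrics:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def f_measure(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0


@dataclass(frozen=True)
class CalibrationBin:
    lower: float
    upper: float
    count: int
    accuracy: float | None  # None when the bin is empty


def load_gold_standard(path: str | Path) -> GoldStandard:
    """Read a gold TSV with columns doc_id, symbol_a, symbol_b, set ∈ {base, rescue}."""
    base: set[DocPair] = set()
    rescue: set[DocPair] = set()
    path = Path(path)
    with path.open("r", encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if tuple(header) != ("doc_id", "symbol_a", "symbol_b", "set"):
            raise ValueError(f"{path}: unexpected gold columns {tuple(header)}")
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            doc_id, a, b, which = line.split("\t")
            entry = (doc_id, canonical_pair(a, b))
            (base if which == "base" else rescue).add(entry)
    return GoldStandard(
        pairs_by_doc=frozenset(base), rescue_pairs=frozenset(rescue - base)
    )


def aggregate_document_level(
    records: Iterable[ExtractionRecord],
) -> dict[DocPair, ExtractionRecord]:
    """Representative record per (document, pair): highest probability wins.

    Ties are broken toward the smallest sentence index.
    """
    best: dict[DocPair, ExtractionRecord] = {}
    for rec in records:
        key = (rec.doc_id, canonical_pair(rec.gene1, rec.gene2))
        cur = best.get(key)
        if (
            cur is None
            or rec.probability > cur.probability
            or (rec.probability == cur.probability and rec.sent_index < cur.sent_index)
        ):
            best[key] = rec
    return best


def precision_recall(
    predicted: Iterable[DocPair], gold: GoldStandard, use_rescue: bool = False
) -> Metrics:
    """Document-level precision/recall against a curated gold standard.

    Only predictions in gold-standard documents count; with ``use_rescue``
    the rescue pairs are additional true positives (they never add to the
    false-negative denominator).
    """
    gold_docs = gold.documents
    in_scope = {dp for dp in predicted if dp[0] in gold_docs}
    truth = set(gold.pairs_by_doc)
    if use_rescue:
        truth |= set(gold.rescue_pairs)
    tp = len(in_scope & truth)
    fp = len(in_scope - truth)
    fn = len(set(gold.pairs_by_doc) - in_scope)
    return Metrics(tp=tp, fp=fp, fn=fn)


def curation_precision(
    records: Sequence[ExtractionRecord],
    curation_labels: Mapping[str, str],
) -> tuple[float, float]:
    """Sentence- and document-level precision from per-record curation verdicts.

    ``curation_labels`` maps "doc_id|sent_index|gene1|gene2" keys to a
    verdict in {true_sentence, true_document, false}.  Sentence-level
    precision counts only true_sentence; document-level counts
    true_sentence or true_document.
    """
    if not records:
        raise ValueError("curation precision undefined for an empty record set")
    sent_tp = 0
    doc_tp = 0
    for rec in records:
        key = f"{rec.doc_id}|{rec.sent_index}|{rec.gene1}|{rec.gene2}"
        try:
            verdict = curation_labels[key]
        except KeyError as exc:
            raise ValueError(f"record {key} has no curation verdict") from exc
        if verdict == "true_sentence":
            sent_tp += 1
            doc_tp += 1
        elif verdict == "true_document":
            doc_tp += 1
        elif verdict != "false":
            raise ValueError(f"unknown curation verdict {verdict!r} for {key}")
    n = len(records)
    return sent_tp / n, doc_tp / n


def calibration_bins(
    probabilities: Sequence[float],
    holdout_labels: Sequence[bool],
    n_bins: int = 10,
) -> list[CalibrationBin]:
    """Per-bin count and empirical accuracy over the labeled holdout set.

    Bin k covers [k/n, (k+1)/n), the last bin closed above so probability
    1.0 lands in it.  Accuracy in a bin is the fraction of its items whose
    holdout label is True — for a calibrated model it tracks the bin's
    probability.  Empty bins report ``accuracy=None``.
    """
    if len(probabilities) != len(holdout_labels):
        raise ValueError("probabilities and labels differ in length")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts = np.zeros(n_bins, dtype=int)
    correct = np.zeros(n_bins, dtype=int)
    for p, label in zip(probabilities, holdout_labels):
        k = min(int(p * n_bins), n_bins - 1)
        counts[k] += 1
        if bool(label):
            correct[k] += 1
    return [
        CalibrationBin(
            lower=float(edges[k]),
            upper=float(edges[k + 1]),
            count=int(counts[k]),
            accuracy=(correct[k] / counts[k]) if counts[k] else None,
        )
        for k in range(n_bins)
    ]


def interaction_trends(
    records: Iterable[ExtractionRecord],
    documents: Iterable[Document],
) -> list[tuple[str, int, int, float]]:
    """Per (gene, year): interaction-document count and normalized fraction.

    An interaction document contains at least one called extraction.  A gene
    participating in several called pairs of one document is counted once
    for that document.  Documents with unknown year are excluded (logged).
    Returns rows (gene, year, doc_count, normalized), sorted.
    """
    years: dict[str, int | None] = {d.doc_id: d.pub_year for d in documents}
    genes_by_doc: dict[str, set[str]] = defaultdict(set)
    for rec in records:
        if rec.called:
            genes_by_doc[rec.doc_id].update((rec.gene1, rec.gene2))

    skipped = 0
    docs_per_year: dict[int, int] = defaultdict(int)
    gene_docs: dict[tuple[str, int], int] = defaultdict(int)
    for doc_id, genes in genes_by_doc.items():
        year = years.get(doc_id)
        if year is None:
            skipped += 1
            continue
        docs_per_year[year] += 1
        for gene in genes:
            gene_docs[(gene, year)] += 1
    if skipped:
        logger.info("interaction_trends: excluded %d documents with unknown year", skipped)

    return sorted(
        (gene, year, count, count / docs_per_year[year])
        for (gene, year), count in gene_docs.items()
    )
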