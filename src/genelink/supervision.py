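"""Distant supervision: labeling candidates from interaction knowledge bases.

Candidates are labeled True when their gene pair is a known interaction
(a BioGRID-style physical-interaction table filtered to high-confidence
evidence types, a ChEA-style transcription-factor table taken wholesale, or
a snowball set recycled from a previous iteration), False when the pair is a
known non-interaction (Negatome-style) or drawn as a random negative, and
Unknown otherwise.  Random negatives are sampled, at a fixed 8% rate, from
candidates whose pair is not a known positive and whose sentence shows no
lexical interaction evidence (no trigger lemma).

Known positives that occur extremely often in the corpus are demoted to
Unknown so the feature weights do not overfit a handful of famous pairs.

Every candidate — labeled or not — remains a query variable downstream, so
the model assigns a probability even to its own training sentences.  Labeled
candidates are split half-and-half into a train set (clamped evidence during
learning) and a holdout set (calibration and internal testing).
"""

from __future__ import annotations

import hashlib
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .candidates import CandidateRelation
from .corpus_io import ExtractionRecord, canonical_pair

__all__ = [
    "KnowledgeBase",
    "SupervisionConfig",
    "LabeledCandidate",
    "filter_positive_kb",
    "high_frequency_pairs",
    "label_candidates",
    "build_snowball_set",
    "load_kb_table",
    "write_labels",
]

Pair = tuple[str, str]

DEFAULT_EVIDENCE = frozenset(
    {"Co-crystal Structure", "Reconstituted Complex", "Co-purification"}
)
DEFAULT_TRIGGERS = frozenset(
    {
        "bind", "binding", "interact", "interaction", "regulate", "associate",
        "association", "phosphorylate", "activate", "inhibit", "complex", "target",
    }
)


@dataclass(frozen=True)
class SupervisionConfig:
    allowed_evidence: frozenset[str] = DEFAULT_EVIDENCE
    random_negative_rate: float = 0.08
    trigger_lemmas: frozenset[str] = DEFAULT_TRIGGERS
    high_frequency_threshold: int = 50
    holdout_fraction: float = 0.5
    seed: int = 0
    positive_precedence: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.random_negative_rate <= 1.0):
            raise ValueError("random_negative_rate outside [0, 1]")
        if not (0.0 <= self.holdout_fraction <= 1.0):
            raise ValueError("holdout_fraction outside [0, 1]")
        if self.high_frequency_threshold < 1:
            raise ValueError("high_frequency_threshold must be >= 1")


@dataclass(frozen=True)
class KnowledgeBase:
    """Positive and negative interaction pair tables, with provenance.

    ``positive_pairs``/``negative_pairs`` are canonicalized symbol pairs. The
    two sets may intersect — real databases disagree — and the intersection
    is preserved here; precedence is applied only at labeling time.
    """

    positive_pairs: frozenset[Pair]
    negative_pairs: frozenset[Pair]


@dataclass(frozen=True)
class LabeledCandidate:
    candidate_id: str
    pair: Pair
    label: str  # "True" | "False" | "Unknown"
    label_source: str
    split: str  # "train" | "holdout" | "query"


def load_kb_table(path: str | Path) -> list[tuple[str, str, str, str]]:
    """Read a KB TSV with columns symbol_a, symbol_b, source, evidence."""
    path = Path(path)
    rows: list[tuple[str, str, str, str]] = []
    with path.open("r", encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if tuple(header) != ("symbol_a", "symbol_b", "source", "evidence"):
            raise ValueError(f"{path}: unexpected KB columns {tuple(header)}")
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                parts = parts + [""] * (4 - len(parts))
            rows.append((parts[0], parts[1], parts[2], parts[3]))
    return rows


def filter_positive_kb(
    records: Iterable[tuple[str, str, str, str]],
    config: SupervisionConfig = SupervisionConfig(),
) -> frozenset[Pair]:
    """Filter raw positive-KB rows to the trusted positive pair set.

    BioGRID-like rows are kept only with an allowed physical-evidence type;
    ChEA-like rows (curated TF-target relations) are kept unconditionally.
    Output is canonicalized and deduplicated.
    """
    pairs: set[Pair] = set()
    for sym_a, sym_b, source, evidence in records:
        if source == "biogrid-like":
            if evidence in config.allowed_evidence:
                pairs.add(canonical_pair(sym_a, sym_b))
        elif source == "chea-like":
            pairs.add(canonical_pair(sym_a, sym_b))
        else:
            raise ValueError(f"unknown positive-KB source tag {source!r}")
    return frozenset(pairs)


def high_frequency_pairs(
    candidates: Sequence[CandidateRelation],
    positive_pairs: frozenset[Pair],
    threshold: int,
) -> frozenset[Pair]:
    """Known-positive pairs whose candidate count strictly exceeds ``threshold``."""
    counts = Counter(c.pair for c in candidates)
    return frozenset(
        pair for pair in positive_pairs if counts.get(pair, 0) > threshold
    )


def _stable_hash(candidate_id: str, seed: int, salt: str) -> int:
    digest = hashlib.sha256(f"{salt}:{seed}:{candidate_id}".encode()).digest()
    return int.from_bytes(digest[:8], "big")


def label_candidates(
    candidates: Sequence[CandidateRelation],
    kb: KnowledgeBase,
    config: SupervisionConfig = SupervisionConfig(),
    snowball: frozenset[Pair] = frozenset(),
) -> list[LabeledCandidate]:
    """Assign a distant-supervision label and split to every candidate.

    Precedence per candidate: (1) high-frequency demotion to Unknown;
    (2) positive KB or snowball -> True; (3) negative KB -> False;
    (4) seeded random-negative sampling (floor(rate * n_eligible) candidates
    whose pair is not a known positive and whose sentence has no trigger
    lemma) -> False; (5) Unknown.  True/False candidates are split into
    train/holdout by seeded hash order; Unknown candidates carry
    split="query".  Every candidate is also a query variable downstream
    regardless of label.
    """
    hi_freq = high_frequency_pairs(
        candidates, kb.positive_pairs, config.high_frequency_threshold
    )
    positives = kb.positive_pairs | snowball

    labels: dict[str, tuple[str, str]] = {}
    eligible: list[int] = []
    for pos, cand in enumerate(candidates):
        pair = cand.pair
        in_neg = pair in kb.negative_pairs
        if pair in hi_freq:
            labels[cand.candidate_id] = ("Unknown", "high_frequency_demoted")
        elif in_neg and not config.positive_precedence:
            labels[cand.candidate_id] = ("False", "kb_negative")
        elif pair in kb.positive_pairs:
            labels[cand.candidate_id] = ("True", "kb_positive")
        elif pair in snowball:
            labels[cand.candidate_id] = ("True", "snowball")
        elif in_neg:
            labels[cand.candidate_id] = ("False", "kb_negative")
        else:
            labels[cand.candidate_id] = ("Unknown", "unlabeled")
            if pair not in positives and not (
                cand.sentence_lemmas & config.trigger_lemmas
            ):
                eligible.append(pos)

    n_draw = int(np.floor(config.random_negative_rate * len(eligible)))
    if n_draw > 0:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EED]))
        drawn = rng.choice(len(eligible), size=n_draw, replace=False)
        for k in sorted(drawn):
            cand = candidates[eligible[k]]
            labels[cand.candidate_id] = ("False", "random_negative")

    # Train/holdout split over labeled candidates: order by seeded hash of
    # candidate_id (stable under reruns and insertion order), first
    # floor(n * holdout_fraction) become holdout -- exact to within 1.
    labeled_ids = [
        c.candidate_id for c in candidates if labels[c.candidate_id][0] != "Unknown"
    ]
    order = sorted(
        labeled_ids, key=lambda cid: (_stable_hash(cid, config.seed, "split"), cid)
    )
    n_holdout = int(np.floor(config.holdout_fraction * len(order)))
    holdout_ids = set(order[:n_holdout])

    out: list[LabeledCandidate] = []
    for cand in candidates:
        label, source = labels[cand.candidate_id]
        if label == "Unknown":
            split = "query"
        else:
            split = "holdout" if cand.candidate_id in holdout_ids else "train"
        out.append(
            LabeledCandidate(
                candidate_id=cand.candidate_id,
                pair=cand.pair,
                label=label,
                label_source=source,
                split=split,
            )
        )
    return out


def build_snowball_set(
    prev_extractions: Iterable[ExtractionRecord],
    prev_labels: Iterable[LabeledCandidate],
    curated_true: frozenset[Pair],
) -> frozenset[Pair]:
    """Pairs to recycle as positive training examples in the next iteration.

    A pair qualifies iff it (a) was labeled Unknown in the previous
    iteration, (b) was called (probability >= cutoff) in the previous
    extractions, and (c) was curated as a true interaction from the text.
    """
    unknown_pairs = {lc.pair for lc in prev_labels if lc.label == "Unknown"}
    labeled_pairs = {lc.pair for lc in prev_labels if lc.label != "Unknown"}
    called_pairs = {
        canonical_pair(rec.gene1, rec.gene2)
        for rec in prev_extractions
        if rec.called
    }
    return frozenset(
        (unknown_pairs - labeled_pairs) & called_pairs & curated_true
    )


def write_labels(path: str | Path, labels: Iterable[LabeledCandidate]) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as handle:
        handle.write("candidate_id\tlabel\tlabel_source\tsplit\n")
        for lc in labels:
            handle.write(f"{lc.candidate_id}\t{lc.label}\t{lc.label_source}\t{lc.split}\n")
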