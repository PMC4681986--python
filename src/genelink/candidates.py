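"""Candidate gene-pair construction and feature extraction.

A candidate relation is an unordered pair of distinct gene symbols mentioned
in one sentence, plus a set of binary textual features.  Feature templates
are high-level patterns instantiated per sentence: word windows around each
gene, the word sequence and verbs between the genes, the shortest dependency
path connecting them, and prepositional attachment patterns ("binding of A
to B", "interaction between A and B").

Naming conventions, fixed across the package:

* gene1 is always the leftmost mention, gene2 the rightmost.
* In any feature payload, a token whose word equals either mention's symbol
  is masked as the literal ``GENE``.
* Window n-grams and phrases use surface words; verb and dependency-path
  features use lemmas.
* A feature string renders as ``<template>_[<payload>]`` with payload tokens
  space-separated, e.g. ``Single_Verb_Between_Genes_[bind]``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from .corpus_io import ParsedSentence, Token, canonical_pair
from .gene_tagging import GeneMention

__all__ = [
    "CandidateRelation",
    "DependencyPath",
    "FeatureConfig",
    "build_candidates",
    "shortest_dependency_path",
    "extract_features",
    "featurize",
    "render_feature",
    "parse_feature",
]


@dataclass(frozen=True)
class FeatureConfig:
    """Knobs for the feature-template grammar.

    ``max_sentence_tokens`` caps candidate construction (longer sentences are
    mostly parse errors and enumeration blow-ups); ``between_phrase_max``
    bounds the noisiest template family, the full between-genes phrase.
    """

    max_sentence_tokens: int = 50
    between_phrase_max: int = 6
    enable_windows: bool = True
    enable_between: bool = True
    enable_dependency: bool = True
    enable_prep_pattern: bool = True


DEFAULT_CONFIG = FeatureConfig()


@dataclass(frozen=True)
class CandidateRelation:
    doc_id: str
    sent_index: int
    mention1: GeneMention
    mention2: GeneMention
    pair: tuple[str, str]
    features: frozenset[str]
    candidate_id: str
    # Lemma set of the host sentence, carried along so distant supervision can
    # test for interaction-trigger lemmas without re-reading the corpus.
    sentence_lemmas: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.mention1.token_index >= self.mention2.token_index:
            raise ValueError("mention1 must be strictly left of mention2")
        if self.mention1.symbol == self.mention2.symbol:
            raise ValueError("candidate mentions must have distinct symbols")


@dataclass(frozen=True)
class DependencyPath:
    """Shortest undirected path between two tokens in the dependency graph.

    ``steps`` walk from the first endpoint to the second: each step records
    the edge direction ('up' = dependent to head, 'down' = head to
    dependent), the dependency label of the traversed edge, and the token
    index arrived at.  The last step's token is the second endpoint; all
    earlier step tokens are intermediates.
    """

    start: int
    end: int
    steps: tuple[tuple[str, str, int], ...]

    @property
    def intermediate_indices(self) -> tuple[int, ...]:
        return tuple(idx for _, _, idx in self.steps[:-1])


def build_candidates(
    sentence: ParsedSentence,
    mentions: Sequence[GeneMention],
    max_sentence_tokens: int = 50,
) -> list[CandidateRelation]:
    """Build one candidate per unordered pair of mentions with distinct symbols.

    Sentences longer than ``max_sentence_tokens`` yield no candidates.
    Candidates are ordered by their (token_index, token_index) pairs and carry
    empty feature sets; call :func:`featurize` to attach features.
    """
    if len(sentence) > max_sentence_tokens:
        return []
    lemmas = sentence.lemmas
    out: list[CandidateRelation] = []
    for a_pos in range(len(mentions)):
        for b_pos in range(a_pos + 1, len(mentions)):
            m1, m2 = mentions[a_pos], mentions[b_pos]
            if m1.token_index > m2.token_index:
                m1, m2 = m2, m1
            if m1.symbol == m2.symbol:
                continue
            out.append(
                CandidateRelation(
                    doc_id=sentence.doc_id,
                    sent_index=sentence.sent_index,
                    mention1=m1,
                    mention2=m2,
                    pair=canonical_pair(m1.symbol, m2.symbol),
                    features=frozenset(),
                    candidate_id=(
                        f"{sentence.doc_id}|{sentence.sent_index}|"
                        f"{m1.token_index}|{m2.token_index}"
                    ),
                    sentence_lemmas=lemmas,
                )
            )
    out.sort(key=lambda c: (c.mention1.token_index, c.mention2.token_index))
    return out


# ---------------------------------------------------------------------------
# Dependency paths


def _dependency_graph(sentence: ParsedSentence) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(t.index for t in sentence.tokens)
    for tok in sentence.tokens:
        if tok.dep_head != -1:
            g.add_edge(tok.index, tok.dep_head)
    return g


def _edge_step(sentence: ParsedSentence, u: int, v: int) -> tuple[str, str, int]:
    """Encode traversing the edge u->v as a (direction, label, arrived-at) step.

    If the edge exists in both orientations (degenerate mutual-head parses)
    the lexicographically smaller encoding wins.
    """
    tokens = sentence.tokens
    options = []
    if tokens[u].dep_head == v:
        options.append(("up", tokens[u].dep_label, v))
    if tokens[v].dep_head == u:
        options.append(("down", tokens[v].dep_label, v))
    if not options:
        raise ValueError(f"no dependency edge between tokens {u} and {v}")
    return min(options)


def shortest_dependency_path(
    sentence: ParsedSentence, i: int, j: int
) -> DependencyPath | None:
    """Shortest path between tokens i and j in the undirected dependency graph.

    Returns ``None`` when the tokens lie in different connected components
    (disconnected parses are valid input).  Ties between equal-length paths
    are broken by lexicographic order of the (direction, label, token-index)
    step sequences.
    """
    if i == j:
        raise ValueError("path endpoints must differ")
    g = _dependency_graph(sentence)
    try:
        node_paths = list(nx.all_shortest_paths(g, i, j))
    except nx.NetworkXNoPath:
        return None
    best: tuple[tuple[str, str, int], ...] | None = None
    for nodes in node_paths:
        steps = tuple(
            _edge_step(sentence, u, v) for u, v in zip(nodes[:-1], nodes[1:])
        )
        if best is None or steps < best:
            best = steps
    assert best is not None
    return DependencyPath(start=i, end=j, steps=best)


# ---------------------------------------------------------------------------
# Feature templates


def _sanitize(text: str) -> str:
    # Payload tokens must never contain the grammar delimiters "_[" or "]".
    return text.replace("_[", "_(").replace("]", ")")


def render_feature(template: str, payload_tokens: Sequence[str]) -> str:
    return f"{template}_[{' '.join(payload_tokens)}]"


def parse_feature(feature: str) -> tuple[str, str]:
    """Split a rendered feature string back into (template, payload)."""
    cut = feature.index("_[")
    if not feature.endswith("]"):
        raise ValueError(f"malformed feature string: {feature!r}")
    return feature[:cut], feature[cut + 2 : -1]


def coarse_pos(pos: str) -> str:
    if pos.startswith("VB"):
        return "VERB"
    if pos.startswith("NN"):
        return "NOUN"
    return "OTHER"


def _prep_attachment(sentence: ParsedSentence, gene_index: int) -> tuple[int, str] | None:
    """Find a (noun index, preposition word) the gene attaches to, if any.

    Two encodings are recognized: collapsed dependencies, where the gene hangs
    directly off the noun with a ``prep_<p>`` / ``nmod:<p>`` label, and basic
    dependencies, where the gene is the ``pobj`` of a ``prep`` token governed
    by the noun.
    """
    tokens = sentence.tokens
    tok = tokens[gene_index]
    if tok.dep_head == -1:
        return None
    head = tokens[tok.dep_head]
    label = tok.dep_label
    if label.startswith("prep_") and head.pos.startswith("NN"):
        return head.index, label[len("prep_"):]
    if label.startswith("nmod:") and head.pos.startswith("NN"):
        return head.index, label[len("nmod:"):]
    if label == "pobj" and head.dep_label == "prep" and head.dep_head != -1:
        noun = tokens[head.dep_head]
        if noun.pos.startswith("NN"):
            return noun.index, head.word
    return None


def extract_features(
    sentence: ParsedSentence,
    candidate: CandidateRelation,
    config: FeatureConfig = DEFAULT_CONFIG,
) -> set[str]:
    """Instantiate every enabled feature template for one candidate.

    Deterministic in (sentence, candidate, config).  See the module docstring
    for the template inventory and naming rules.
    """
    tokens = sentence.tokens
    i1 = candidate.mention1.token_index
    i2 = candidate.mention2.token_index
    symbols = {candidate.mention1.symbol, candidate.mention2.symbol}

    def mask_word(tok: Token) -> str:
        return "GENE" if tok.word in symbols else _sanitize(tok.word)

    def mask_lemma(tok: Token) -> str:
        return "GENE" if tok.word in symbols or tok.lemma in symbols else _sanitize(tok.lemma)

    features: set[str] = set()

    if config.enable_windows:
        for role, idx in (("Gene1", i1), ("Gene2", i2)):
            left = tokens[max(0, idx - 2) : idx]
            right = tokens[idx + 1 : idx + 3]
            if left:
                features.add(render_feature(f"Window_Left_{role}_1gram", [mask_word(left[-1])]))
                payload = [mask_word(t) for t in left]
                features.add(render_feature(f"Window_Left_{role}_2gram", payload))
                features.add(render_feature(f"Window_Left_{role}_Phrase", payload))
            if right:
                features.add(render_feature(f"Window_Right_{role}_1gram", [mask_word(right[0])]))
                payload = [mask_word(t) for t in right]
                features.add(render_feature(f"Window_Right_{role}_2gram", payload))
                features.add(render_feature(f"Window_Right_{role}_Phrase", payload))

    between = tokens[i1 + 1 : i2]
    if config.enable_between:
        if 1 <= len(between) <= config.between_phrase_max:
            features.add(
                render_feature("Phrase_Between_Genes", [mask_word(t) for t in between])
            )
        verbs = [t for t in between if t.pos.startswith("VB")]
        for verb in verbs:
            features.add(render_feature("Verb_Between_Genes", [mask_lemma(verb)]))
        if len(verbs) == 1:
            features.add(
                render_feature("Single_Verb_Between_Genes", [mask_lemma(verbs[0])])
            )

    if config.enable_dependency:
        path = shortest_dependency_path(sentence, i1, i2)
        if path is not None:
            intermediates = [tokens[k] for k in path.intermediate_indices]
            for tok in intermediates:
                if tok.pos.startswith("VB"):
                    features.add(
                        render_feature("Verb_On_Dependency_Path", [mask_lemma(tok)])
                    )
            parts = ["GENE"]
            for direction, label, node in path.steps:
                parts.append(("^" if direction == "up" else "v") + _sanitize(label))
                parts.append("GENE" if node == i2 else mask_lemma(tokens[node]))
            features.add(render_feature("Dependency_Path", parts))
            collapsed = ["GENE"] + [coarse_pos(t.pos) for t in intermediates] + ["GENE"]
            features.add(render_feature("Collapsed_Dependency_Path", ["—".join(collapsed)]))

    if config.enable_prep_pattern:
        att1 = _prep_attachment(sentence, i1)
        att2 = _prep_attachment(sentence, i2)
        if att1 is not None and att2 is not None and att1[0] == att2[0]:
            noun = tokens[att1[0]]
            features.add(
                render_feature(
                    "Prep_Pattern",
                    [mask_lemma(noun), _sanitize(att1[1]), _sanitize(att2[1])],
                )
            )

    return features


def featurize(
    sentence: ParsedSentence,
    candidate: CandidateRelation,
    config: FeatureConfig = DEFAULT_CONFIG,
) -> CandidateRelation:
    """Return a copy of ``candidate`` with its feature set attached."""
    return dataclasses.replace(
        candidate, features=frozenset(extract_features(sentence, candidate, config))
    )
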