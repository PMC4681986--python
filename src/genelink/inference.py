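"""Factor-graph model over binary is_correct variables.

Each candidate relation owns one binary variable.  Two factor families give
the joint distribution

    P(v) ∝ exp( Σ_i v_i · (w_bias + Σ_{f ∈ F_i} w_f)
                + w_link · Σ_{(i,j) ∈ L} 1[v_i = v_j] )

* a logistic feature factor per (variable, feature) incidence plus an
  always-on BIAS intercept: the factor contributes the feature's weight when
  the variable is 1 and nothing when it is 0;
* an Ising-style agreement factor, with one shared learned weight, linking
  each candidate to the previous mention of the same gene pair in the same
  document — interaction evidence for a pair tends to be consistent within
  a document.

The conditional of a single variable is therefore
``P(v_i = 1 | rest) = logistic(w_bias + Σ w_f + w_link · Σ_nb (2 v_nb − 1))``.

Weights are learned by stochastic gradient ascent on the conditional
likelihood of the clamped train-split evidence, using contrastive
clamped-versus-free Gibbs samples (persistent chains).  Marginals are
estimated by Gibbs sweep averages after burn-in; an exact enumeration
oracle is provided for small graphs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.special import logsumexp

from .candidates import CandidateRelation
from .corpus_io import ExtractionRecord
from .supervision import LabeledCandidate

__all__ = [
    "FactorGraph",
    "ModelWeights",
    "InferenceConfig",
    "build_factor_graph",
    "gibbs_marginals",
    "bruteforce_marginals",
    "learn_weights",
    "call_extractions",
    "write_weights",
    "read_weights",
]

BIAS = "BIAS"
LINKAGE = "LINKAGE"


@dataclass(frozen=True)
class InferenceConfig:
    learning_iterations: int = 1000
    samples_per_iteration: int = 1
    inference_iterations: int = 1000
    learning_rate: float = 0.001
    diminish_rate: float = 0.95
    call_cutoff: float = 0.90
    seed: int = 0
    linkage_enabled: bool = True
    learn_linkage: bool = True

    def __post_init__(self) -> None:
        if self.learning_iterations < 1 or self.inference_iterations < 1:
            raise ValueError("iteration counts must be >= 1")
        if self.learning_rate <= 0 or self.diminish_rate <= 0:
            raise ValueError("rates must be > 0")
        if not (0.0 < self.call_cutoff < 1.0):
            raise ValueError("call_cutoff must lie in (0, 1)")


@dataclass(frozen=True)
class ModelWeights:
    feature_weights: dict[str, float]
    bias_weight: float = 0.0
    linkage_weight: float = 0.0

    def weight(self, feature: str) -> float:
        return self.feature_weights.get(feature, 0.0)


@dataclass
class FactorGraph:
    """One binary variable per candidate plus feature and linkage factors."""

    candidate_ids: list[str]
    feature_names: list[str]
    incidence: sp.csr_matrix  # (n_vars, n_features) binary
    linkage_edges: np.ndarray  # (n_edges, 2) int, var <- predecessor var
    evidence: dict[int, bool]

    @property
    def n_vars(self) -> int:
        return len(self.candidate_ids)

    def local_fields(self, weights: ModelWeights) -> np.ndarray:
        """bias + sum of active feature weights, per variable."""
        w = np.array(
            [weights.weight(name) for name in self.feature_names], dtype=float
        )
        if not np.all(np.isfinite(w)) or not np.isfinite(weights.bias_weight):
            raise ValueError("non-finite model weight")
        return weights.bias_weight + self.incidence @ w

    def neighbor_lists(self) -> list[list[int]]:
        nbrs: list[list[int]] = [[] for _ in range(self.n_vars)]
        for a, b in self.linkage_edges:
            nbrs[int(a)].append(int(b))
            nbrs[int(b)].append(int(a))
        return nbrs

    @classmethod
    def from_parts(
        cls,
        features_per_var: Sequence[Iterable[str]],
        linkage_edges: Sequence[tuple[int, int]] = (),
        evidence: Mapping[int, bool] | None = None,
        candidate_ids: Sequence[str] | None = None,
    ) -> "FactorGraph":
        """Assemble a graph directly from per-variable feature sets (tests, tools)."""
        n = len(features_per_var)
        vocab: dict[str, int] = {}
        rows: list[int] = []
        cols: list[int] = []
        for i, feats in enumerate(features_per_var):
            for f in feats:
                j = vocab.setdefault(f, len(vocab))
                rows.append(i)
                cols.append(j)
        incidence = sp.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(n, len(vocab))
        )
        edges = np.array(sorted(set(map(tuple, linkage_edges))), dtype=int).reshape(-1, 2)
        return cls(
            candidate_ids=list(candidate_ids or (f"v{i}" for i in range(n))),
            feature_names=list(vocab),
            incidence=incidence,
            linkage_edges=edges,
            evidence=dict(evidence or {}),
        )


def build_factor_graph(
    candidates: Sequence[CandidateRelation],
    labels: Sequence[LabeledCandidate] | None = None,
    linkage_enabled: bool = True,
) -> FactorGraph:
    """Build the factor graph for a featurized, labeled candidate set.

    Variables follow candidate order.  When ``linkage_enabled``, each
    candidate is linked to the most recent prior candidate (by sentence
    index, then token order) of the same pair in the same document; chains
    never cross documents.  Evidence is placed on train-split True/False
    candidates only.
    """
    by_id = {}
    if labels is not None:
        by_id = {lc.candidate_id: lc for lc in labels}

    vocab: dict[str, int] = {}
    rows: list[int] = []
    cols: list[int] = []
    for i, cand in enumerate(candidates):
        for f in sorted(cand.features):
            j = vocab.setdefault(f, len(vocab))
            rows.append(i)
            cols.append(j)
    incidence = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)),
        shape=(len(candidates), len(vocab)),
    )

    edges: list[tuple[int, int]] = []
    if linkage_enabled:
        groups: dict[tuple[str, str, str], list[int]] = {}
        for i, cand in enumerate(candidates):
            groups.setdefault((cand.doc_id, *cand.pair), []).append(i)
        for members in groups.values():
            members.sort(
                key=lambda i: (
                    candidates[i].sent_index,
                    candidates[i].mention1.token_index,
                    candidates[i].mention2.token_index,
                )
            )
            edges.extend(zip(members[1:], members[:-1]))

    evidence: dict[int, bool] = {}
    for i, cand in enumerate(candidates):
        lc = by_id.get(cand.candidate_id)
        if lc is not None and lc.split == "train" and lc.label in ("True", "False"):
            evidence[i] = lc.label == "True"

    return FactorGraph(
        candidate_ids=[c.candidate_id for c in candidates],
        feature_names=list(vocab),
        incidence=incidence,
        linkage_edges=np.array(sorted(edges), dtype=int).reshape(-1, 2),
        evidence=evidence,
    )


# ---------------------------------------------------------------------------
# Sampling


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


class _Sampler:
    """Persistent-state Gibbs sweeps over the non-evidence variables.

    Variables without linkage neighbors are conditionally independent given
    the weights, so they are resampled as one vectorized block; chained
    variables are resampled sequentially in index order.
    """

    def __init__(self, graph: FactorGraph, clamp_evidence: bool, rng: np.random.Generator):
        self.rng = rng
        n = graph.n_vars
        self.n = n
        self.neighbors = graph.neighbor_lists()
        clamped = set(graph.evidence) if clamp_evidence else set()
        self.clamped = clamped
        chained = {i for i in range(n) if self.neighbors[i] and i not in clamped}
        self.free_indep = np.array(
            sorted(set(range(n)) - chained - clamped), dtype=int
        )
        self.free_chained = sorted(chained)
        self._forward = True  # scan direction alternates per sweep (mixes chains faster)
        self.state = (rng.random(n) < 0.5).astype(np.int8)
        for i, val in graph.evidence.items():
            if clamp_evidence:
                self.state[i] = 1 if val else 0

    def sweep(
        self,
        fields: np.ndarray,
        linkage_weight: float,
        accumulate: np.ndarray | None = None,
    ) -> np.ndarray:
        """One full Gibbs sweep; optionally accumulate the conditional
        probabilities used at each resampling (Rao-Blackwellized marginals)."""
        state = self.state
        if self.free_indep.size:
            probs = _sigmoid(fields[self.free_indep])
            state[self.free_indep] = self.rng.random(self.free_indep.size) < probs
            if accumulate is not None:
                accumulate[self.free_indep] += probs
        scan = self.free_chained if self._forward else self.free_chained[::-1]
        self._forward = not self._forward
        for i in scan:
            coupling = sum(2 * int(state[j]) - 1 for j in self.neighbors[i])
            p = _sigmoid(fields[i] + linkage_weight * coupling)
            state[i] = self.rng.random() < p
            if accumulate is not None:
                accumulate[i] += p
        return state


def _components(n: int, neighbors: list[list[int]]) -> list[list[int]]:
    seen = [False] * n
    comps: list[list[int]] = []
    for start in range(n):
        if seen[start]:
            continue
        comp = [start]
        seen[start] = True
        queue = [start]
        while queue:
            u = queue.pop()
            for v in neighbors[u]:
                if not seen[v]:
                    seen[v] = True
                    comp.append(v)
                    queue.append(v)
        comps.append(comp)
    return comps


def _chain_order(comp: list[int], neighbors: list[list[int]]) -> list[int] | None:
    """Path order of a component, or None if it is not a simple chain."""
    degrees = {v: len(neighbors[v]) for v in comp}
    if len(comp) == 1:
        return comp
    if any(d > 2 for d in degrees.values()):
        return None
    ends = [v for v in comp if degrees[v] == 1]
    if len(ends) != 2:
        return None  # a cycle
    order = [min(ends)]
    prev = -1
    while len(order) < len(comp):
        nxt = [v for v in neighbors[order[-1]] if v != prev]
        if not nxt:
            return None
        prev = order[-1]
        order.append(nxt[0])
    return order


def _chain_marginals(
    thetas: np.ndarray, lw: float, clamped: dict[int, bool]
) -> np.ndarray:
    """Exact marginals of a binary chain with agreement coupling.

    Transfer-matrix forward-backward in log space; ``clamped`` maps chain
    positions to fixed values.
    """
    k = len(thetas)
    unary = np.zeros((k, 2))
    unary[:, 1] = thetas
    for pos, val in clamped.items():
        unary[pos, 0 if val else 1] = -np.inf
    pair = np.array([[lw, 0.0], [0.0, lw]])

    alpha = np.zeros((k, 2))
    alpha[0] = unary[0]
    for i in range(1, k):
        alpha[i] = unary[i] + logsumexp(alpha[i - 1][:, None] + pair, axis=0)
    beta = np.zeros((k, 2))
    for i in range(k - 2, -1, -1):
        beta[i] = logsumexp(unary[i + 1] + pair + beta[i + 1], axis=1)
    log_p = alpha + beta
    log_p -= logsumexp(log_p, axis=1, keepdims=True)
    return np.exp(log_p[:, 1])


def gibbs_marginals(
    graph: FactorGraph,
    weights: ModelWeights,
    config: InferenceConfig = InferenceConfig(),
) -> np.ndarray:
    """P(is_correct = 1) per variable, conditioned on clamped evidence.

    The linkage factors the pipeline builds form disjoint chains, so the
    joint distribution factorizes over chain components; for those (and for
    isolated variables) the marginal is computed exactly by transfer-matrix
    forward-backward — the zero-variance limit of Rao-Blackwellized Gibbs
    sweep averaging.  Components with any non-chain linkage structure
    (possible only for hand-built graphs) fall back to sampling:
    ``inference_iterations // 10`` burn-in sweeps, then the resampling
    conditional probability averaged over ``inference_iterations`` sweeps.
    Evidence variables report their clamped label.
    """
    fields = graph.local_fields(weights)
    lw = weights.linkage_weight if config.linkage_enabled else 0.0
    if not np.isfinite(lw):
        raise ValueError("non-finite linkage weight")
    neighbors = graph.neighbor_lists()
    marginals = np.empty(graph.n_vars)

    sampled_vars: list[int] = []
    for comp in _components(graph.n_vars, neighbors):
        order = _chain_order(comp, neighbors)
        if order is None:
            sampled_vars.extend(comp)
            continue
        clamped = {
            pos: graph.evidence[v]
            for pos, v in enumerate(order)
            if v in graph.evidence
        }
        effective_lw = lw if len(order) > 1 else 0.0
        marginals[order] = _chain_marginals(fields[order], effective_lw, clamped)

    if sampled_vars:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x1FE2]))
        sampler = _Sampler(graph, clamp_evidence=True, rng=rng)
        for _ in range(config.inference_iterations // 10):
            sampler.sweep(fields, lw)
        totals = np.zeros(graph.n_vars)
        for _ in range(config.inference_iterations):
            sampler.sweep(fields, lw, accumulate=totals)
        marginals[sampled_vars] = (totals / config.inference_iterations)[sampled_vars]

    for i, val in graph.evidence.items():
        marginals[i] = 1.0 if val else 0.0
    return marginals


def bruteforce_marginals(graph: FactorGraph, weights: ModelWeights) -> np.ndarray:
    """Exact marginals by enumeration of all joint configurations (<= 20 vars).

    Conditions on evidence like the sampler.  Intended as an independent
    oracle for tests and diagnostics; refuses graphs with more than 20
    non-evidence variables.
    """
    free = sorted(set(range(graph.n_vars)) - set(graph.evidence))
    k = len(free)
    if k > 20:
        raise ValueError(f"refusing exact enumeration over {k} > 20 free variables")
    fields = graph.local_fields(weights)
    lw = weights.linkage_weight

    configs = ((np.arange(2**k)[:, None] >> np.arange(k)[None, :]) & 1).astype(float)
    log_w = configs @ fields[free]
    pos = {v: idx for idx, v in enumerate(free)}
    ev = {i: (1.0 if val else 0.0) for i, val in graph.evidence.items()}
    for a, b in graph.linkage_edges:
        a, b = int(a), int(b)
        if a in pos and b in pos:
            log_w += lw * (configs[:, pos[a]] == configs[:, pos[b]])
        elif a in pos:
            log_w += lw * (configs[:, pos[a]] == ev[b])
        elif b in pos:
            log_w += lw * (configs[:, pos[b]] == ev[a])
    log_w -= log_w.max()
    p = np.exp(log_w)
    p /= p.sum()
    marginals = np.empty(graph.n_vars)
    if k:
        marginals[free] = p @ configs
    for i, val in graph.evidence.items():
        marginals[i] = 1.0 if val else 0.0
    return marginals


# ---------------------------------------------------------------------------
# Learning


def learn_weights(
    graph: FactorGraph, config: InferenceConfig = InferenceConfig()
) -> ModelWeights:
    """Learn feature, bias and linkage weights by contrastive stochastic gradient.

    Per learning iteration, ``samples_per_iteration`` Gibbs sweeps are drawn
    from a persistent chain with evidence clamped and from one with evidence
    free; every weight moves by ``learning_rate`` times the difference of its
    factor's sufficient statistic between the two samples, and the learning
    rate is multiplied by ``diminish_rate`` each iteration.  Deterministic
    given ``config.seed``.
    """
    if not graph.evidence:
        raise ValueError("cannot learn weights without evidence variables")
    seq = np.random.SeedSequence([config.seed, 0x7EA5])
    rng_c, rng_f = (np.random.default_rng(s) for s in seq.spawn(2))
    clamped = _Sampler(graph, clamp_evidence=True, rng=rng_c)
    free = _Sampler(graph, clamp_evidence=False, rng=rng_f)

    n_feat = len(graph.feature_names)
    w = np.zeros(n_feat)
    bias = 0.0
    linkage = 0.0
    use_linkage = config.linkage_enabled and graph.linkage_edges.size > 0
    edges = graph.linkage_edges
    Xt = graph.incidence.T.tocsr()
    lr = config.learning_rate

    for _ in range(config.learning_iterations):
        fields = bias + graph.incidence @ w
        lw = linkage if use_linkage else 0.0
        grad_w = np.zeros(n_feat)
        grad_bias = 0.0
        grad_link = 0.0
        for _ in range(config.samples_per_iteration):
            s_c = clamped.sweep(fields, lw).astype(float)
            s_f = free.sweep(fields, lw).astype(float)
            grad_w += Xt @ (s_c - s_f)
            grad_bias += s_c.sum() - s_f.sum()
            if use_linkage:
                grad_link += float(
                    np.sum(s_c[edges[:, 0]] == s_c[edges[:, 1]])
                    - np.sum(s_f[edges[:, 0]] == s_f[edges[:, 1]])
                )
        scale = lr / config.samples_per_iteration
        w += scale * grad_w
        bias += scale * grad_bias
        if use_linkage and config.learn_linkage:
            linkage += scale * grad_link
        lr *= config.diminish_rate

    return ModelWeights(
        feature_weights=dict(zip(graph.feature_names, w.tolist())),
        bias_weight=float(bias),
        linkage_weight=float(linkage),
    )


# ---------------------------------------------------------------------------
# Calling and weight I/O


def call_extractions(
    marginals: np.ndarray,
    candidates: Sequence[CandidateRelation],
    cutoff: float = 0.90,
) -> list[ExtractionRecord]:
    """One extraction record per candidate; called iff probability >= cutoff."""
    if len(marginals) != len(candidates):
        raise ValueError("marginals and candidates differ in length")
    return [
        ExtractionRecord(
            doc_id=cand.doc_id,
            sent_index=cand.sent_index,
            gene1=cand.pair[0],
            gene2=cand.pair[1],
            probability=float(p),
            called=bool(p >= cutoff),
        )
        for cand, p in zip(candidates, marginals)
    ]


def write_weights(path: str | Path, weights: ModelWeights) -> None:
    """Write weights TSV sorted by |weight| descending, with BIAS and LINKAGE rows."""
    rows = sorted(
        weights.feature_weights.items(), key=lambda kv: (-abs(kv[1]), kv[0])
    )
    path = Path(path)
    with path.open("w", encoding="utf-8") as handle:
        handle.write("feature\tweight\n")
        handle.write(f"{BIAS}\t{weights.bias_weight:.6f}\n")
        handle.write(f"{LINKAGE}\t{weights.linkage_weight:.6f}\n")
        for name, val in rows:
            handle.write(f"{name}\t{val:.6f}\n")


def read_weights(path: str | Path) -> ModelWeights:
    path = Path(path)
    feature_weights: dict[str, float] = {}
    bias = 0.0
    linkage = 0.0
    with path.open("r", encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if tuple(header) != ("feature", "weight"):
            raise ValueError(f"{path}: unexpected weights columns {tuple(header)}")
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            name, val = line.split("\t")
            if name == BIAS:
                bias = float(val)
            elif name == LINKAGE:
                linkage = float(val)
            else:
                feature_weights[name] = float(val)
    return ModelWeights(
        feature_weights=feature_weights, bias_weight=bias, linkage_weight=linkage
    )
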