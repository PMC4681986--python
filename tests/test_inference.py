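"""Factor-graph inference: exact oracle, Gibbs agreement, learning behavior."""

import dataclasses
import math

import numpy as np
import pytest

from genelink.candidates import CandidateRelation
from genelink.corpus_io import ExtractionRecord
from genelink.gene_tagging import GeneMention
from genelink.inference import (
    FactorGraph,
    InferenceConfig,
    ModelWeights,
    bruteforce_marginals,
    build_factor_graph,
    call_extractions,
    gibbs_marginals,
    learn_weights,
    read_weights,
    write_weights,
)
from genelink.supervision import LabeledCandidate


def sigmoid(x):
    return 1.0 / (1.0 + math.exp(-x))


def make_candidate(doc, sent_idx, sym1, sym2, features=(), t1=0, t2=1):
    return CandidateRelation(
        doc_id=doc, sent_index=sent_idx,
        mention1=GeneMention(t1, sym1), mention2=GeneMention(t2, sym2),
        pair=tuple(sorted((sym1, sym2))),
        features=frozenset(features),
        candidate_id=f"{doc}|{sent_idx}|{t1}|{t2}",
    )


class TestBuildFactorGraph:
    def test_four_mentions_one_pair_form_one_chain(self):
        cands = [make_candidate("d1", k, "A", "B") for k in range(4)]
        graph = build_factor_graph(cands, linkage_enabled=True)
        assert graph.linkage_edges.shape == (3, 2)
        # each variable has at most one predecessor
        preds = graph.linkage_edges[:, 0]
        assert len(set(preds.tolist())) == 3

    def test_no_cross_document_linkage(self):
        cands = [make_candidate("d1", 0, "A", "B"), make_candidate("d2", 0, "A", "B")]
        graph = build_factor_graph(cands, linkage_enabled=True)
        assert graph.linkage_edges.size == 0

    def test_linkage_disabled(self):
        cands = [make_candidate("d1", k, "A", "B") for k in range(4)]
        graph = build_factor_graph(cands, linkage_enabled=False)
        assert graph.linkage_edges.size == 0


class TestExactMarginals:
    def test_independent_variables_match_closed_form(self):
        graph = FactorGraph.from_parts([{"f"}, {"g"}, set()])
        weights = ModelWeights({"f": 1.3, "g": -0.7}, bias_weight=0.2)
        marg = bruteforce_marginals(graph, weights)
        assert marg == pytest.approx(
            [sigmoid(1.5), sigmoid(-0.5), sigmoid(0.2)], abs=1e-12
        )

    def test_three_variable_chain_matches_hand_enumeration(self):
        graph = FactorGraph.from_parts(
            [set(), set(), set()], linkage_edges=[(1, 0), (2, 1)]
        )
        weights = ModelWeights({}, bias_weight=0.5, linkage_weight=1.0)
        # Hand enumeration over the 8 states of exp(0.5*sum(v) + agreements).
        states = [(a, b, c) for a in (0, 1) for b in (0, 1) for c in (0, 1)]
        log_w = [0.5 * sum(s) + 1.0 * ((s[0] == s[1]) + (s[1] == s[2]))
                 for s in states]
        z = sum(math.exp(x) for x in log_w)
        expected = [
            sum(math.exp(x) for s, x in zip(states, log_w) if s[k]) / z
            for k in range(3)
        ]
        assert bruteforce_marginals(graph, weights) == pytest.approx(expected, abs=1e-12)

    def test_refuses_more_than_twenty_variables(self):
        graph = FactorGraph.from_parts([set()] * 21)
        with pytest.raises(ValueError, match="20"):
            bruteforce_marginals(graph, ModelWeights({}))


class TestGibbsMarginals:
    CONFIG = InferenceConfig(seed=11)

    def test_bias_only_symmetry(self):
        graph = FactorGraph.from_parts([set()])
        marg = gibbs_marginals(graph, ModelWeights({}), self.CONFIG)
        assert marg[0] == pytest.approx(0.5, abs=0.02)

    def test_single_active_feature_logistic(self):
        graph = FactorGraph.from_parts([{"f"}])
        marg = gibbs_marginals(graph, ModelWeights({"f": 2.0}), self.CONFIG)
        assert marg[0] == pytest.approx(sigmoid(2.0), abs=0.02)

    def test_clamped_neighbor_pulls_through_linkage(self):
        graph = FactorGraph.from_parts(
            [set(), set()], linkage_edges=[(1, 0)], evidence={0: True}
        )
        weights = ModelWeights({}, linkage_weight=3.0)
        marg = gibbs_marginals(graph, weights, self.CONFIG)
        assert marg[0] == 1.0
        assert marg[1] == pytest.approx(sigmoid(3.0), abs=0.02)

    def test_agrees_with_enumeration_on_random_graphs(self):
        """Sweep-averaged marginals track exact enumeration within 0.03.

        Random graphs respect the model's structural invariant: linkage
        factors form disjoint chains (each variable has at most one
        predecessor and one successor).
        """
        rng = np.random.default_rng(2024)
        worst = 0.0
        for trial in range(20):
            n = int(rng.integers(3, 13))
            features = [
                {f"f{k}" for k in rng.choice(6, size=rng.integers(0, 4), replace=False)}
                for _ in range(n)
            ]
            order = rng.permutation(n)
            edges = [
                (int(order[i]), int(order[i - 1]))
                for i in range(1, n)
                if rng.random() < 0.5  # a skipped edge starts a new chain
            ]
            evidence = {0: bool(rng.random() < 0.5)} if rng.random() < 0.5 else {}
            graph = FactorGraph.from_parts(features, edges, evidence)
            weights = ModelWeights(
                {f"f{k}": float(rng.normal(0, 0.8)) for k in range(6)},
                bias_weight=float(rng.normal(0, 0.5)),
                linkage_weight=float(rng.uniform(-1.0, 1.0)),
            )
            exact = bruteforce_marginals(graph, weights)
            approx = gibbs_marginals(
                graph, weights, InferenceConfig(seed=100 + trial)
            )
            worst = max(worst, float(np.max(np.abs(exact - approx))))
        assert worst < 0.03

    def test_chain_free_marginals_equal_logistic_closed_form(self):
        rng = np.random.default_rng(5)
        features = [
            {f"f{k}" for k in rng.choice(8, size=rng.integers(0, 5), replace=False)}
            for _ in range(30)
        ]
        graph = FactorGraph.from_parts(features)
        weights = ModelWeights(
            {f"f{k}": float(rng.normal(0, 1.0)) for k in range(8)},
            bias_weight=-0.3,
        )
        marg = gibbs_marginals(graph, weights, InferenceConfig(seed=42))
        expected = 1.0 / (1.0 + np.exp(-graph.local_fields(weights)))
        assert np.max(np.abs(marg - expected)) < 0.02

    def test_positive_feature_never_decreases_chain_free_marginal(self):
        base = ModelWeights({"f": 0.8}, bias_weight=-0.2)
        plus = ModelWeights({"f": 0.8, "g": 1.1}, bias_weight=-0.2)
        without = bruteforce_marginals(FactorGraph.from_parts([{"f"}]), base)
        withg = bruteforce_marginals(FactorGraph.from_parts([{"f", "g"}]), plus)
        assert withg[0] >= without[0]

    def test_non_chain_linkage_falls_back_to_sampling(self):
        # A hub variable with three linkage partners is not a chain; the
        # sweep-sampling path must still track enumeration.
        graph = FactorGraph.from_parts(
            [{"f0"}, {"f1"}, set(), set()],
            linkage_edges=[(1, 0), (2, 0), (3, 0)],
        )
        weights = ModelWeights(
            {"f0": 0.8, "f1": -0.5}, bias_weight=0.1, linkage_weight=0.6
        )
        exact = bruteforce_marginals(graph, weights)
        approx = gibbs_marginals(graph, weights, InferenceConfig(seed=7))
        assert np.max(np.abs(exact - approx)) < 0.03

    def test_non_finite_weight_rejected(self):
        graph = FactorGraph.from_parts([{"f"}])
        with pytest.raises(ValueError, match="non-finite"):
            gibbs_marginals(graph, ModelWeights({"f": float("nan")}), self.CONFIG)


def separable_graph():
    """Feature POS fires only on True-evidence vars, NEG only on False."""
    features = [{"POS"}] * 20 + [{"NEG"}] * 20
    evidence = {i: i < 20 for i in range(40)}
    return FactorGraph.from_parts(features, evidence=evidence)


class TestLearning:
    def test_sign_recovery_on_separable_data(self):
        for seed in range(5):
            weights = learn_weights(separable_graph(), InferenceConfig(seed=seed))
            assert weights.feature_weights["POS"] > 0
            assert weights.feature_weights["NEG"] < 0

    def test_uninformative_feature_stays_near_zero(self):
        features = [{"POS"}] * 20 + [{"NEG"}] * 20
        for i in range(0, 40, 2):
            features[i] = features[i] | {"MIX"}
        evidence = {i: i < 20 for i in range(40)}
        graph = FactorGraph.from_parts(features, evidence=evidence)
        for seed in range(5):
            weights = learn_weights(graph, InferenceConfig(seed=seed))
            assert abs(weights.feature_weights["MIX"]) < 0.1

    def test_same_seed_identical_weights(self):
        w1 = learn_weights(separable_graph(), InferenceConfig(seed=3))
        w2 = learn_weights(separable_graph(), InferenceConfig(seed=3))
        assert w1 == w2

    def test_no_evidence_rejected(self):
        graph = FactorGraph.from_parts([{"f"}])
        with pytest.raises(ValueError, match="evidence"):
            learn_weights(graph, InferenceConfig(seed=0))

    def test_chain_free_weights_match_independent_logistic_fit(self):
        """SGD on the factor graph recovers the logistic-regression MLE.

        Labels are drawn stochastically from a known logistic model so the
        MLE is finite; statsmodels provides the independent fit.  The decay
        is relaxed so the stated iteration count actually converges.
        """
        import statsmodels.api as sm

        rng = np.random.default_rng(77)
        n = 300
        X = (rng.random((n, 3)) < 0.5).astype(float)
        true_w = np.array([1.2, -0.8, 0.5])
        probs = 1.0 / (1.0 + np.exp(-(X @ true_w - 0.3)))
        labels = rng.random(n) < probs

        features = [
            {f"f{k}" for k in range(3) if X[i, k]} for i in range(n)
        ]
        graph = FactorGraph.from_parts(
            features, evidence={i: bool(labels[i]) for i in range(n)}
        )
        config = InferenceConfig(
            seed=1, learning_iterations=10000, learning_rate=0.001,
            diminish_rate=0.9995, linkage_enabled=False,
        )
        learned = learn_weights(graph, config)

        fit = sm.Logit(labels.astype(float), sm.add_constant(X)).fit(disp=0)
        mle = fit.params  # [intercept, f0, f1, f2]
        assert learned.bias_weight == pytest.approx(mle[0], abs=0.15)
        for k in range(3):
            assert learned.feature_weights[f"f{k}"] == pytest.approx(
                mle[k + 1], abs=0.15
            )


class TestCallExtractions:
    def test_cutoff_inclusive_at_ninety(self):
        cands = [
            make_candidate("d", 0, "A", "B"),
            make_candidate("d", 1, "C", "D"),
            make_candidate("d", 2, "E", "F"),
        ]
        records = call_extractions(np.array([0.90, 0.8999, 0.95]), cands, cutoff=0.90)
        assert [r.called for r in records] == [True, False, True]

    def test_empty_marginals_empty_records(self):
        assert call_extractions(np.array([]), [], cutoff=0.9) == []


class TestWeightsIO:
    def test_round_trip_with_special_rows(self, tmp_path):
        weights = ModelWeights({"A_[x]": 1.25, "B_[y]": -0.4}, 0.1, 0.7)
        path = tmp_path / "w.tsv"
        write_weights(path, weights)
        lines = path.read_text().splitlines()
        assert lines[1].startswith("BIAS\t")
        assert lines[2].startswith("LINKAGE\t")
        # sorted by |weight| descending after the special rows
        assert lines[3].startswith("A_[x]\t")
        back = read_weights(path)
        assert back.feature_weights == pytest.approx(weights.feature_weights)
        assert back.bias_weight == pytest.approx(0.1)
        assert back.linkage_weight == pytest.approx(0.7)
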