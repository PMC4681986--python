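"""Distant-supervision labeling: KB filtering, precedence, sampling, splits."""

import dataclasses

import pytest

from genelink.candidates import CandidateRelation
from genelink.corpus_io import ExtractionRecord
from genelink.gene_tagging import GeneMention
from genelink.supervision import (
    KnowledgeBase,
    LabeledCandidate,
    SupervisionConfig,
    build_snowball_set,
    filter_positive_kb,
    high_frequency_pairs,
    label_candidates,
)


def make_candidate(doc, sent_idx, sym1, sym2, lemmas=(), t1=0, t2=1):
    pair = tuple(sorted((sym1, sym2)))
    return CandidateRelation(
        doc_id=doc,
        sent_index=sent_idx,
        mention1=GeneMention(t1, sym1),
        mention2=GeneMention(t2, sym2),
        pair=pair,
        features=frozenset({"F_[x]"}),
        candidate_id=f"{doc}|{sent_idx}|{t1}|{t2}",
        sentence_lemmas=frozenset(lemmas),
    )


class TestFilterPositiveKB:
    def test_biogrid_like_needs_allowed_evidence(self):
        rows = [
            ("A", "B", "biogrid-like", "Co-fractionation"),
            ("C", "D", "biogrid-like", "Co-purification"),
        ]
        assert filter_positive_kb(rows) == {("C", "D")}

    def test_chea_like_kept_unconditionally(self):
        assert filter_positive_kb([("A", "B", "chea-like", "")]) == {("A", "B")}

    def test_reversed_duplicates_canonicalized(self):
        rows = [
            ("B", "A", "chea-like", ""),
            ("A", "B", "biogrid-like", "Co-crystal Structure"),
        ]
        assert filter_positive_kb(rows) == {("A", "B")}

    def test_unknown_source_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            filter_positive_kb([("A", "B", "mystery", "")])


class TestHighFrequencyPairs:
    def make_candidates(self, pair, n):
        return [make_candidate(f"d{i}", 0, *pair) for i in range(n)]

    def test_strictly_above_threshold_demoted(self):
        cands = self.make_candidates(("A", "B"), 12)
        assert high_frequency_pairs(cands, frozenset({("A", "B")}), 10) == {("A", "B")}

    def test_exactly_at_threshold_kept(self):
        cands = self.make_candidates(("A", "B"), 10)
        assert high_frequency_pairs(cands, frozenset({("A", "B")}), 10) == frozenset()

    def test_only_known_positives_eligible(self):
        cands = self.make_candidates(("A", "B"), 1000)
        assert high_frequency_pairs(cands, frozenset(), 10) == frozenset()


class TestLabelCandidates:
    CONFIG = SupervisionConfig(seed=7, high_frequency_threshold=3)

    def test_positive_kb_pair_is_true(self):
        cands = [make_candidate("d1", 0, "A", "B", lemmas=["bind"])]
        kb = KnowledgeBase(frozenset({("A", "B")}), frozenset())
        (lc,) = label_candidates(cands, kb, self.CONFIG)
        assert (lc.label, lc.label_source) == ("True", "kb_positive")

    def test_high_frequency_pair_demoted_to_unknown(self):
        cands = [make_candidate(f"d{i}", 0, "A", "B") for i in range(5)]
        kb = KnowledgeBase(frozenset({("A", "B")}), frozenset())
        labels = label_candidates(cands, kb, self.CONFIG)
        assert {(lc.label, lc.label_source) for lc in labels} == {
            ("Unknown", "high_frequency_demoted")
        }

    def test_positive_outranks_negative_by_default(self):
        cands = [make_candidate("d1", 0, "A", "B")]
        kb = KnowledgeBase(frozenset({("A", "B")}), frozenset({("A", "B")}))
        (lc,) = label_candidates(cands, kb, self.CONFIG)
        assert lc.label == "True"
        flipped = dataclasses.replace(self.CONFIG, positive_precedence=False)
        (lc,) = label_candidates(cands, kb, flipped)
        assert (lc.label, lc.label_source) == ("False", "kb_negative")

    def test_negative_kb_pair_is_false(self):
        cands = [make_candidate("d1", 0, "A", "B")]
        kb = KnowledgeBase(frozenset(), frozenset({("A", "B")}))
        (lc,) = label_candidates(cands, kb, self.CONFIG)
        assert (lc.label, lc.label_source) == ("False", "kb_negative")

    def eligible_candidates(self, n):
        # Distinct pairs, no trigger lemmas, not in any KB.
        return [
            make_candidate(f"d{i}", 0, f"S{i:03d}A", f"S{i:03d}B",
                           lemmas=["measure", "cell"])
            for i in range(n)
        ]

    def test_random_negative_count_is_floor_of_rate(self):
        cands = self.eligible_candidates(100)
        kb = KnowledgeBase(frozenset(), frozenset())
        labels = label_candidates(cands, kb, self.CONFIG)
        randoms = [lc for lc in labels if lc.label_source == "random_negative"]
        assert len(randoms) == 8  # floor(0.08 * 100)

    def test_trigger_sentences_never_random_negatives(self):
        cands = self.eligible_candidates(50) + [
            make_candidate(f"t{i}", 0, f"T{i:03d}A", f"T{i:03d}B",
                           lemmas=["bind", "cell"])
            for i in range(50)
        ]
        kb = KnowledgeBase(frozenset(), frozenset())
        labels = label_candidates(cands, kb, self.CONFIG)
        by_id = {c.candidate_id: c for c in cands}
        for lc in labels:
            if lc.label_source == "random_negative":
                lemmas = by_id[lc.candidate_id].sentence_lemmas
                assert not (lemmas & self.CONFIG.trigger_lemmas)
        assert sum(lc.label_source == "random_negative" for lc in labels) == 4

    def test_same_seed_reproducible_different_seed_differs(self):
        cands = self.eligible_candidates(200)
        kb = KnowledgeBase(frozenset(), frozenset())
        pick = lambda cfg: {
            lc.candidate_id
            for lc in label_candidates(cands, kb, cfg)
            if lc.label_source == "random_negative"
        }
        assert pick(self.CONFIG) == pick(self.CONFIG)
        assert pick(self.CONFIG) != pick(dataclasses.replace(self.CONFIG, seed=8))

    def test_label_partition_covers_all_candidates(self):
        cands = self.eligible_candidates(30) + [
            make_candidate("p", 0, "A", "B"), make_candidate("n", 0, "C", "D")
        ]
        kb = KnowledgeBase(frozenset({("A", "B")}), frozenset({("C", "D")}))
        labels = label_candidates(cands, kb, self.CONFIG)
        assert len(labels) == len(cands)
        counts = {"True": 0, "False": 0, "Unknown": 0}
        for lc in labels:
            counts[lc.label] += 1
        assert sum(counts.values()) == len(cands)

    def test_holdout_split_within_one_of_half(self):
        cands = [make_candidate("d", i, "A", "B", t1=2 * i, t2=2 * i + 1)
                 for i in range(11)]
        kb = KnowledgeBase(frozenset({("A", "B")}), frozenset())
        config = SupervisionConfig(seed=1, high_frequency_threshold=50)
        labels = label_candidates(cands, kb, config)
        splits = [lc.split for lc in labels if lc.label != "Unknown"]
        assert len(splits) == 11
        assert abs(splits.count("holdout") - 5.5) <= 0.5
        assert set(splits) == {"train", "holdout"}
        unknown_splits = {lc.split for lc in labels if lc.label == "Unknown"}
        assert unknown_splits <= {"query"}


class TestSnowball:
    LABELS = [
        LabeledCandidate("c1", ("A", "B"), "Unknown", "unlabeled", "query"),
        LabeledCandidate("c2", ("C", "D"), "True", "kb_positive", "train"),
        LabeledCandidate("c3", ("E", "F"), "Unknown", "unlabeled", "query"),
    ]
    EXTRACTIONS = [
        ExtractionRecord("d1", 0, "A", "B", 0.95, True),
        ExtractionRecord("d1", 1, "C", "D", 0.99, True),
        ExtractionRecord("d2", 0, "E", "F", 0.40, False),
    ]

    def test_unknown_called_curated_pair_in_snowball(self):
        out = build_snowball_set(
            self.EXTRACTIONS, self.LABELS, frozenset({("A", "B"), ("E", "F")})
        )
        assert out == {("A", "B")}

    def test_previously_true_pair_excluded(self):
        out = build_snowball_set(
            self.EXTRACTIONS, self.LABELS, frozenset({("C", "D")})
        )
        assert out == frozenset()

    def test_uncurated_called_pair_excluded(self):
        out = build_snowball_set(self.EXTRACTIONS, self.LABELS, frozenset())
        assert out == frozenset()
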