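"""End-to-end orchestration: tag → featurize → supervise → learn → infer → call.

Stages hand off through plain files (TSV/JSONL) in a run directory; a
manifest records the configuration hash, seeds and per-stage row counts so a
rerun with the identical configuration can be verified byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import candidates as cand_mod
from . import evaluation as eval_mod
from . import gene_tagging, inference, supervision
from .candidates import CandidateRelation, FeatureConfig
from .corpus_io import canonical_pair, read_corpus, write_extractions
from .inference import InferenceConfig
from .supervision import KnowledgeBase, SupervisionConfig

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""


@dataclass(frozen=True)
class PipelineConfig:
    corpus_path: str
    dictionary_path: str
    kb_positive_path: str
    kb_negative_path: str
    out_dir: str
    gold_path: str | None = None
    use_rescue: bool = False
    feature: FeatureConfig = FeatureConfig()
    supervision: SupervisionConfig = SupervisionConfig()
    inference: InferenceConfig = InferenceConfig()
    seed: int = 0

    def with_seed(self, seed: int) -> "PipelineConfig":
        return dataclasses.replace(
            self,
            seed=seed,
            supervision=dataclasses.replace(self.supervision, seed=seed),
            inference=dataclasses.replace(self.inference, seed=seed),
        )

    def config_hash(self) -> str:
        def encode(obj):
            if dataclasses.is_dataclass(obj):
                return encode(dataclasses.asdict(obj))
            if isinstance(obj, dict):
                return {k: encode(v) for k, v in obj.items()}
            if isinstance(obj, (frozenset, set)):
                return sorted(obj)
            if isinstance(obj, (tuple, list)):
                return [encode(v) for v in obj]
            return obj

        payload = encode(self)
        payload.pop("out_dir", None)  # output location is not part of the computation
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_feature_dump(path: Path, candidates: list[CandidateRelation]) -> int:
    rows = 0
    with path.open("w", encoding="utf-8") as handle:
        handle.write("candidate_id\tdoc_id\tsent_index\tgene1\tgene2\tfeature\n")
        for cand in candidates:
            for feat in sorted(cand.features):
                handle.write(
                    f"{cand.candidate_id}\t{cand.doc_id}\t{cand.sent_index}\t"
                    f"{cand.pair[0]}\t{cand.pair[1]}\t{feat}\n"
                )
                rows += 1
    return rows


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the manifest (also written to the run dir).

    Outputs in ``out_dir``: candidates.tsv (feature dump), labels.tsv,
    weights.tsv, extractions.tsv, optional evaluation.json, trends.tsv, and
    manifest.json.  Reruns with an identical config reproduce identical files.
    """
    for name in ("corpus_path", "dictionary_path", "kb_positive_path", "kb_negative_path"):
        path = getattr(config, name)
        if not Path(path).exists():
            raise PipelineError(f"stage=setup: missing input file for {name}: {path}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    stage = "tag+featurize"
    try:
        dictionary = gene_tagging.load_dictionary(config.dictionary_path)
        documents = list(read_corpus(config.corpus_path))
        candidates: list[CandidateRelation] = []
        for doc in documents:
            for sentence in doc.sentences:
                mentions = gene_tagging.tag_genes(sentence, dictionary)
                for cand in cand_mod.build_candidates(
                    sentence, mentions, config.feature.max_sentence_tokens
                ):
                    candidates.append(cand_mod.featurize(sentence, cand, config.feature))
        counts["documents"] = len(documents)
        counts["candidates"] = len(candidates)
        counts["feature_rows"] = _write_feature_dump(out / "candidates.tsv", candidates)

        stage = "supervise"
        kb = KnowledgeBase(
            positive_pairs=supervision.filter_positive_kb(
                supervision.load_kb_table(config.kb_positive_path), config.supervision
            ),
            negative_pairs=frozenset(
                canonical_pair(a, b)
                for a, b, _, _ in supervision.load_kb_table(config.kb_negative_path)
            ),
        )
        labels = supervision.label_candidates(candidates, kb, config.supervision)
        supervision.write_labels(out / "labels.tsv", labels)
        counts["labels"] = len(labels)
        counts["evidence"] = sum(
            1 for lc in labels if lc.split == "train" and lc.label != "Unknown"
        )

        stage = "learn"
        graph = inference.build_factor_graph(
            candidates, labels, linkage_enabled=config.inference.linkage_enabled
        )
        weights = inference.learn_weights(graph, config.inference)
        inference.write_weights(out / "weights.tsv", weights)
        counts["features"] = len(weights.feature_weights)

        stage = "infer+call"
        marginals = inference.gibbs_marginals(graph, weights, config.inference)
        records = inference.call_extractions(
            marginals, candidates, config.inference.call_cutoff
        )
        write_extractions(out / "extractions.tsv", records)
        counts["extractions"] = len(records)
        counts["called"] = sum(1 for r in records if r.called)

        stage = "evaluate"
        if config.gold_path is not None:
            gold = eval_mod.load_gold_standard(config.gold_path)
            representatives = eval_mod.aggregate_document_level(records)
            predicted = [k for k, rec in representatives.items() if rec.called]
            metrics = eval_mod.precision_recall(predicted, gold, config.use_rescue)
            (out / "evaluation.json").write_text(
                json.dumps(
                    {
                        "precision": metrics.precision,
                        "recall": metrics.recall,
                        "f_measure": metrics.f_measure,
                        "tp": metrics.tp,
                        "fp": metrics.fp,
                        "fn": metrics.fn,
                    },
                    indent=2,
                )
                + "\n"
            )

        stage = "trends"
        trend_rows = eval_mod.interaction_trends(records, documents)
        with (out / "trends.tsv").open("w", encoding="utf-8") as handle:
            handle.write("gene\tyear\tdoc_count\tnormalized\n")
            for gene, year, count, frac in trend_rows:
                handle.write(f"{gene}\t{year}\t{count}\t{frac:.6f}\n")
        counts["trend_rows"] = len(trend_rows)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage={stage}: {exc}") from exc

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "supervision_seed": config.supervision.seed,
        "inference_seed": config.inference.seed,
        "counts": counts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
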