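"""End-to-end pipeline: index -> retrieve -> rerank -> TREC run file.

Model implementations (embedder, answer extractor, summarizer) are resolved
by registry name from the config, so swapping a trained model in is a config
change, not a code change. Every run directory gets a JSON manifest recording
the config, its hash and the seeds, making runs reproducible and auditable.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

from .config import PipelineConfig
from .corpus import Document, FieldPolicy, Topic, topic_text
from .dense import Embedder, HashedProjectionEmbedder, embed_collection
from .fusion import FusionParams, RetrievalIndexes, retrieve
from .ranking import Run, write_run
from .rerank import (AnswerExtractor, KeywordAnswerExtractor,
                     LeadSentenceSummarizer, Summarizer, rerank)
from .sparse import TfidfConfig, build_bm25, fit_tfidf

logger = logging.getLogger(__name__)


def make_embedder(config: PipelineConfig) -> Embedder:
    if config.embedder == "hashed-projection":
        return HashedProjectionEmbedder(config.embedder_dim, config.embedder_seed)
    raise ValueError(f"unknown embedder {config.embedder!r}")


def make_extractor(config: PipelineConfig) -> AnswerExtractor | None:
    if config.extractor == "keyword":
        return KeywordAnswerExtractor()
    if config.extractor == "none":
        return None
    raise ValueError(f"unknown extractor {config.extractor!r}")


def make_summarizer(config: PipelineConfig) -> Summarizer | None:
    if config.summarizer == "lead":
        return LeadSentenceSummarizer()
    if config.summarizer == "none":
        return None
    raise ValueError(f"unknown summarizer {config.summarizer!r}")


def build_indexes(docs: Sequence[Document], config: PipelineConfig) -> RetrievalIndexes:
    """Build all three per-corpus indexes (TF-IDF, BM25, embedding store)."""
    if not docs:
        raise ValueError("empty corpus")
    embedder = make_embedder(config)
    return RetrievalIndexes(
        tfidf=fit_tfidf(docs, TfidfConfig(config.tfidf_vocab_size,
                                          config.tfidf_max_df,
                                          config.tfidf_min_df)),
        bm25=build_bm25(docs, config.bm25_k1, config.bm25_b),
        store=embed_collection(docs, embedder),
        embedder=embedder,
    )


def fusion_params(config: PipelineConfig) -> FusionParams:
    return FusionParams(
        mu=config.mu, k=config.k, depth=config.depth,
        dense_candidates=config.dense_candidates, knn_mode=config.knn_mode,
        field_policy=FieldPolicy(config.field_policy),
    )


def run_pipeline(config: PipelineConfig, docs: Sequence[Document],
                 topics: Sequence[Topic], out_dir: str | Path,
                 indexes: RetrievalIndexes | None = None) -> tuple[Run, Path]:
    """Index, retrieve and (optionally) rerank every topic; write the TREC
    run and a manifest under ``out_dir``. Returns (run, run-file path)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if indexes is None:
        indexes = build_indexes(docs, config)
    params = fusion_params(config)
    corpus_by_id = {d.doc_id: d for d in docs}
    extractor = make_extractor(config)
    summarizer = make_summarizer(config)

    retrieval_run: Run = {}
    final_run: Run = {}
    for topic in topics:
        ranked = retrieve(topic, indexes, params)
        retrieval_run[topic.topic_id] = ranked
        if config.rerank_enabled and len(ranked) > 0:
            query = topic_text(topic, FieldPolicy(config.field_policy))
            reranked, _ = rerank(
                ranked, query, corpus_by_id, extractor, summarizer,
                indexes.embedder, indexes.store,
                context_docs=config.rerank_context_docs,
            )
            final_run[topic.topic_id] = reranked
        else:
            final_run[topic.topic_id] = ranked

    retrieval_path = out_dir / "retrieval.run.txt"
    run_path = out_dir / "final.run.txt"
    write_run(retrieval_run, retrieval_path, tag=config.run_tag + "-retrieval")
    write_run(final_run, run_path, tag=config.run_tag)
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.hash,
        "seeds": {"pipeline": config.seed, "embedder": config.embedder_seed},
        "n_docs": len(docs),
        "n_topics": len(topics),
        "outputs": {"retrieval": retrieval_path.name, "final": run_path.name},
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
    )
    return final_run, run_path
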