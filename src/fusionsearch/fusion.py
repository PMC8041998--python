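"""Channel fusion: linear dense/TF-IDF combination and reciprocal rank fusion.

The retrieval stage produces three signals for a query q and document d:

* dense:  max over paragraphs p of d of cos(p_e, q_e)
* TF-IDF: cosine between whole-document TF-IDF vectors
* BM25:   Okapi BM25 over the inverted index

The first two are combined linearly,

    C(q, d) = mu * max_p cos(p_e, q_e) + (1 - mu) * tfidf(q, d)

which induces a ranking R_C; reciprocal rank fusion then merges R_C with the
BM25 ranking R_B:

    RRF(q, d) = 1/(k + R_C(d)) + 1/(k + R_B(d))

with a document absent from one list contributing no term for that list.
Defaults mu = 0.7, k = 60, final depth 1000.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .corpus import FieldPolicy, Topic, topic_text
from .dense import Embedder, EmbeddingStore, doc_max_cosine, knn
from .ranking import RankedList
from .sparse import Bm25Index, TfidfModel, bm25_search
from .text import tokenize


@dataclass(frozen=True)
class FusionParams:
    mu: float = 0.7
    k: float = 60.0
    depth: int = 1000
    dense_candidates: int = 5000  # paragraphs fetched before doc grouping
    knn_mode: str = "exact"
    field_policy: FieldPolicy = FieldPolicy.QUERY_QUESTION

    def __post_init__(self):
        if not 0 <= self.mu <= 1:
            raise ValueError("mu must be in [0, 1]")
        if self.k <= 0:
            raise ValueError("k must be > 0")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")


def combine_linear(max_cos: float, tfidf_sim: float, mu: float) -> float:
    """``C = mu * max_cos + (1 - mu) * tfidf_sim``."""
    if not 0 <= mu <= 1:
        raise ValueError("mu must be in [0, 1]")
    return mu * max_cos + (1 - mu) * tfidf_sim


def induce_ranking(scores: Mapping[str, float], topic_id: int = 0) -> RankedList:
    """Sort by descending score, ties by lexicographic doc_id; ranks 1..n."""
    if not scores:
        raise ValueError("cannot induce a ranking from an empty score map")
    return RankedList.from_scores(topic_id, scores)


def rrf_fuse(rank_c: RankedList, rank_b: RankedList, k: float = 60.0,
             depth: int | None = None) -> RankedList:
    """Reciprocal rank fusion of two ranked lists.

    Each document in the union scores the sum of 1/(k + rank) over the lists
    that contain it; documents missing from a list get no term for it (no
    pseudo-rank). Ranks are 1-based. Output re-ranked by descending RRF,
    ties by doc_id, truncated to ``depth``.
    """
    if k <= 0:
        raise ValueError("k must be > 0")
    scores: dict[str, float] = {}
    for ranked in (rank_c, rank_b):
        for e in ranked:
            scores[e.doc_id] = scores.get(e.doc_id, 0.0) + 1.0 / (k + e.rank)
    return RankedList.from_scores(rank_c.topic_id, scores, depth=depth)


@dataclass
class RetrievalIndexes:
    """The three per-corpus indexes the retrieval stage needs."""

    tfidf: TfidfModel
    bm25: Bm25Index
    store: EmbeddingStore
    embedder: Embedder


def retrieve(topic: Topic, indexes: RetrievalIndexes,
             params: FusionParams = FusionParams()) -> RankedList:
    """Full hybrid retrieval for one topic: top-``depth`` fused documents.

    Dense candidates come from paragraph kNN grouped to documents; the linear
    combination C is computed over the union of dense and TF-IDF candidates,
    with the missing channel's score treated as 0. The BM25 list is fused in
    by RRF.
    """
    if indexes.bm25.n_docs == 0:
        raise ValueError("empty corpus")
    query = topic_text(topic, params.field_policy)

    # Dense channel: paragraph kNN -> candidate documents -> max cosine.
    qvec = indexes.embedder.embed(query)
    m = min(params.dense_candidates, len(indexes.store))
    dense_docs: dict[str, float] = {}
    if m >= 1:
        for nb in knn(qvec, indexes.store, m, mode=params.knn_mode):
            doc_id = nb.para_id[0]
            if doc_id not in dense_docs:
                dense_docs[doc_id] = doc_max_cosine(qvec, doc_id, indexes.store)

    tfidf_sims = indexes.tfidf.similarities(query)

    union = set(dense_docs) | set(tfidf_sims)
    if union:
        combined = {
            d: combine_linear(dense_docs.get(d, 0.0), tfidf_sims.get(d, 0.0), params.mu)
            for d in union
        }
        rank_c = RankedList.from_scores(topic.topic_id, combined, depth=params.depth)
    else:
        rank_c = RankedList(topic.topic_id, [])

    rank_b = bm25_search(tokenize(query), indexes.bm25, params.depth,
                         topic_id=topic.topic_id)
    return rrf_fuse(rank_c, rank_b, k=params.k, depth=params.depth)
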