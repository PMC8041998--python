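"""Re-ranking: modulate retrieval (RRF) scores by answer- and summary-match.

For a query q and retrieved document d the final ranking score is

    R(q, d) = S(q, d) * Q(q, d) * RRF(q, d)

where

* ``Q(q, d) = 1.1 ** N`` with N the number of distinct extracted answer spans
  appearing (case-insensitively) in the document — a document answering the
  query more often is boosted geometrically;
* ``S(q, d) = 1/2 + 1/2 * max_p cos(p_e, M(q)_e)`` with M(q) the abstractive
  summary of the retrieved set, embedded with the same embedder as the
  paragraph store — a document resembling the consensus summary is boosted.

The answer extractor and summarizer are pluggable contracts. The neural
models that fill them in production (a multi-hop paragraph-selector QA
pipeline; an encoder–decoder abstractive summarizer) are out of scope here;
the package ships deterministic reference implementations so the cascade is
fully runnable and testable without trained weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Protocol, Sequence, runtime_checkable

from .corpus import Document
from .dense import Embedder, EmbeddingStore, doc_max_cosine
from .ranking import RankedList
from .text import count_tokens, split_sentences, tokenize

logger = logging.getLogger(__name__)

#: Per-paragraph sentence budget when assembling the summarizer input.
SENTENCES_PER_PARAGRAPH = 4
#: Whitespace-token budget of the assembled summarizer input.
SUMMARY_INPUT_TOKENS = 512
#: Upper bounds (inclusive) of the first four summary-length buckets; the
#: fifth bucket is everything above. Generation targets bucket 1 (< 65).
BUCKET_BOUNDS = (64, 124, 194, 294)


@runtime_checkable
class AnswerExtractor(Protocol):
    """(query text, retrieved paragraph texts) -> set of answer spans."""

    def extract(self, query: str, paragraphs: Sequence[str]) -> set[str]: ...


@runtime_checkable
class Summarizer(Protocol):
    """(query text, assembled input text) -> summary text."""

    def summarize(self, query: str, input_text: str) -> str: ...


class KeywordAnswerExtractor:
    """Reference extractor: query tokens of length >= ``min_len`` that occur
    verbatim (case-insensitively) in the supplied paragraphs.

    Deterministic and training-free; returned spans are substrings of the
    paragraphs by construction.
    """

    def __init__(self, min_len: int = 4):
        self.min_len = min_len

    def extract(self, query: str, paragraphs: Sequence[str]) -> set[str]:
        lowered = [p.lower() for p in paragraphs]
        spans = set()
        for token in tokenize(query):
            if len(token) >= self.min_len and any(token in p for p in lowered):
                spans.add(token)
        return spans


class LeadSentenceSummarizer:
    """Reference summarizer: first sentence of each of the first ``n_parts``
    paragraphs of the assembled input, truncated to the short-summary budget
    (bucket 1: fewer than 65 tokens)."""

    def __init__(self, n_parts: int = 3, max_tokens: int = 64):
        self.n_parts = n_parts
        self.max_tokens = max_tokens

    def summarize(self, query: str, input_text: str) -> str:
        sentences = split_sentences(input_text)[: self.n_parts]
        words = " ".join(sentences).split()
        return " ".join(words[: self.max_tokens])


class ConstantStubExtractor:
    """Extracts nothing: Q = 1 for every document (testing aid)."""

    def extract(self, query: str, paragraphs: Sequence[str]) -> set[str]:
        return set()


def count_answer_matches(answers: set[str], doc: Document) -> int:
    """N = distinct answers occurring case-insensitively as substrings of any
    text field of the document (title, abstract, paragraphs, captions)."""
    fields = [t.lower() for t in doc.text_fields() if t]
    return sum(
        1 for a in answers if any(a.lower() in f for f in fields)
    )


def qa_score(n_matches: int) -> float:
    """``Q = 1.1 ** N`` — strictly increasing, Q = 1 when nothing matches."""
    if n_matches < 0:
        raise ValueError("answer-match count must be >= 0")
    return 1.1 ** n_matches


def assemble_summary_input(paragraphs: Sequence[str],
                           max_tokens: int = SUMMARY_INPUT_TOKENS,
                           sentences_per_para: int = SENTENCES_PER_PARAGRAPH) -> str:
    """Concatenate the first ``sentences_per_para`` sentences of each
    paragraph, in retrieval order, accumulating whole sentences while the
    running whitespace-token count stays within ``max_tokens``.

    The first sentence is always admitted even if it alone exceeds the
    budget, so a nonempty input never assembles to the empty string.
    """
    parts: list[str] = []
    used = 0
    for para in paragraphs:
        for sentence in split_sentences(para)[:sentences_per_para]:
            cost = count_tokens(sentence)
            if parts and used + cost > max_tokens:
                return " ".join(parts)
            parts.append(sentence)
            used += cost
    return " ".join(parts)


def summary_length_bucket(token_count: int) -> int:
    """Summary-length category 1..5 with bounds <65, 65-124, 125-194,
    195-294, and above."""
    if token_count < 0:
        raise ValueError("token count must be >= 0")
    for bucket, bound in enumerate(BUCKET_BOUNDS, start=1):
        if token_count <= bound:
            return bucket
    return 5


def summary_score(summary_vec, doc_id: str, store: EmbeddingStore) -> float:
    """``S = 1/2 + 1/2 * max_p cos(p_e, M(q)_e)`` in [0, 1].

    A document with no embedded units scores 0 (with a warning), ranking it
    below any document the summary can be compared against.
    """
    if doc_id not in store.doc_rows:
        logger.warning("doc %r has no embedded units; S = 0", doc_id)
        return 0.0
    return 0.5 + 0.5 * doc_max_cosine(summary_vec, doc_id, store)


@dataclass(frozen=True)
class RerankScores:
    doc_id: str
    rrf: float
    q_score: float
    s_score: float

    @property
    def final(self) -> float:
        return self.s_score * self.q_score * self.rrf


def rerank(retrieved: RankedList, query: str, corpus: dict[str, Document],
           extractor: AnswerExtractor | None, summarizer: Summarizer | None,
           embedder: Embedder, store: EmbeddingStore,
           context_docs: int = 10) -> tuple[RankedList, list[RerankScores]]:
    """Re-rank a retrieved list by R = S * Q * RRF.

    The answer extractor and summarizer see the paragraphs of the top
    ``context_docs`` retrieved documents, in retrieval order. Passing
    ``None`` for either contract disables that factor (Q = 1 resp. S = 1),
    which supports ablating each module independently. The list length never
    changes; ties in R break by doc_id.
    """
    if len(retrieved) == 0:
        raise ValueError("cannot rerank an empty list")
    top_paras: list[str] = []
    for e in retrieved.entries[:context_docs]:
        doc = corpus.get(e.doc_id)
        if doc is not None:
            top_paras.extend(p.text for p in doc.paragraphs)

    answers = extractor.extract(query, top_paras) if extractor is not None else set()
    summary_vec = None
    if summarizer is not None:
        summary = summarizer.summarize(query, assemble_summary_input(top_paras))
        summary_vec = embedder.embed(summary)

    details = []
    for e in retrieved:
        doc = corpus.get(e.doc_id)
        n = count_answer_matches(answers, doc) if doc is not None else 0
        s = (summary_score(summary_vec, e.doc_id, store)
             if summary_vec is not None else 1.0)
        details.append(RerankScores(e.doc_id, e.score, qa_score(n), s))

    reranked = RankedList.from_scores(
        retrieved.topic_id, {d.doc_id: d.final for d in details}
    )
    return reranked, details
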