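"""Keyword retrieval channels: TF-IDF with cosine scoring, and Okapi BM25.

TF-IDF uses the smoothed-idf weighting

    w(t, d) = tf(t, d) * (ln((1 + n) / (1 + df(t))) + 1)

with L2-normalized document vectors scored by cosine similarity; the default
configuration caps the vocabulary at 13,000 terms, drops terms in more than
half the corpus (max_df 0.5) or fewer than 3 documents (min_df 3). The
vectorization is backed by scikit-learn's TfidfVectorizer, whose idf matches
the formula above exactly; :func:`tfidf_weight` implements it directly and the
two are cross-checked in the test suite.

BM25 is the Okapi scoring function over an inverted index with the Lucene idf
form, default parameters k1 = 1.2 and b = 0.75. Both channels vectorize entire
documents (title + abstract + paragraphs + captions), unlike the dense channel
which works at paragraph granularity.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.feature_extraction.text import TfidfVectorizer

from .corpus import Document
from .ranking import RankedList
from .text import tokenize


@dataclass(frozen=True)
class TfidfConfig:
    vocab_size: int = 13_000
    max_df: float = 0.5
    min_df: int = 3


def tfidf_weight(tf: float, df: int, n: int) -> float:
    """Smoothed TF-IDF weight: ``tf * (ln((1+n)/(1+df)) + 1)`` (natural log)."""
    if n < 1:
        raise ValueError("corpus size n must be >= 1")
    if not 0 <= df <= n:
        raise ValueError(f"document frequency {df} outside [0, {n}]")
    if tf < 0:
        raise ValueError("term frequency must be >= 0")
    return tf * (math.log((1 + n) / (1 + df)) + 1.0)


def tfidf_score(query_vec, doc_vec, atol: float = 1e-6) -> float:
    """Cosine similarity of two L2-normalized nonnegative sparse vectors.

    Raises if a nonzero input is not unit-norm (the vectors produced by
    :class:`TfidfModel` always are); returns 0 if either vector is zero.
    """
    q = sp.csr_matrix(query_vec)
    d = sp.csr_matrix(doc_vec)
    for name, v in (("query", q), ("doc", d)):
        norm = sp.linalg.norm(v)
        if norm == 0:
            return 0.0
        if abs(norm - 1.0) > atol:
            raise ValueError(f"{name} vector not L2-normalized (norm={norm:.6g})")
    return float(q.multiply(d).sum())


@dataclass
class TfidfModel:
    """Fitted TF-IDF vectorizer plus the document matrix it produced.

    ``vectorizer`` is ``None`` when the df filters pruned every term (e.g. a
    one-document corpus under max_df 0.5); the channel then scores nothing
    and the other retrieval channels carry the query.
    """

    vectorizer: TfidfVectorizer | None
    matrix: sp.csr_matrix  # docs x vocab, L2-normalized rows
    doc_ids: list[str]
    config: TfidfConfig

    @property
    def vocabulary(self) -> dict[str, int]:
        return self.vectorizer.vocabulary_ if self.vectorizer is not None else {}

    def transform(self, texts: Sequence[str]) -> sp.csr_matrix:
        if self.vectorizer is None:
            return sp.csr_matrix((len(texts), 0))
        return self.vectorizer.transform(texts)

    def save(self, path: str | Path) -> None:
        """Plain-JSON layout: vocabulary (column order), idf, CSR doc matrix."""
        vocab = sorted(self.vocabulary, key=self.vocabulary.get)
        m = self.matrix.tocsr()
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({
                "format": "fusionsearch-tfidf-v1",
                "config": {"vocab_size": self.config.vocab_size,
                           "max_df": self.config.max_df,
                           "min_df": self.config.min_df},
                "vocabulary": vocab,
                "idf": (self.vectorizer.idf_.tolist()
                        if self.vectorizer is not None else []),
                "doc_ids": self.doc_ids,
                "matrix": {"data": m.data.tolist(),
                           "indices": m.indices.tolist(),
                           "indptr": m.indptr.tolist(),
                           "shape": list(m.shape)},
            }, fh)

    @classmethod
    def load(cls, path: str | Path) -> "TfidfModel":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        if raw.get("format") != "fusionsearch-tfidf-v1":
            raise ValueError(f"{path}: not a TF-IDF model file")
        config = TfidfConfig(**raw["config"])
        m = raw["matrix"]
        matrix = sp.csr_matrix(
            (m["data"], m["indices"], m["indptr"]), shape=tuple(m["shape"])
        )
        if not raw["vocabulary"]:
            return cls(None, matrix, list(raw["doc_ids"]), config)
        vec = TfidfVectorizer(
            analyzer=tokenize,
            vocabulary={t: i for i, t in enumerate(raw["vocabulary"])},
            norm="l2", smooth_idf=True, sublinear_tf=False,
        )
        vec.idf_ = np.asarray(raw["idf"], dtype=float)
        return cls(vec, matrix, list(raw["doc_ids"]), config)

    def similarities(self, query_text: str) -> dict[str, float]:
        """Cosine similarity of the query against every document.

        Rows and the query are already unit vectors, so cosine is a dot
        product; documents with zero similarity are omitted.
        """
        if self.vectorizer is None:
            return {}
        qv = self.transform([query_text])
        sims = np.asarray(self.matrix @ qv.T.todense()).ravel()
        return {self.doc_ids[i]: float(s) for i, s in enumerate(sims) if s > 0}


def fit_tfidf(docs: Sequence[Document], config: TfidfConfig = TfidfConfig()) -> TfidfModel:
    """Fit the TF-IDF channel over whole-document texts.

    Vocabulary: terms passing the df filters, truncated to the ``vocab_size``
    highest-corpus-frequency terms, ties broken by lexicographic term order
    (scikit-learn's stable selection over its sorted vocabulary).
    """
    if not docs:
        raise ValueError("cannot fit TF-IDF on an empty corpus")
    vec = TfidfVectorizer(
        analyzer=tokenize,
        max_df=config.max_df,
        min_df=config.min_df,
        max_features=config.vocab_size,
        norm="l2",
        smooth_idf=True,
        sublinear_tf=False,
    )
    texts = [d.full_text() for d in docs]
    try:
        matrix = vec.fit_transform(texts)
    except ValueError as exc:
        # df filters can legitimately prune every term on tiny corpora
        if "no terms remain" not in str(exc) and "max_df corresponds" not in str(exc):
            raise
        import logging

        logging.getLogger(__name__).warning(
            "TF-IDF vocabulary empty after df filtering (%s); channel disabled",
            exc,
        )
        return TfidfModel(None, sp.csr_matrix((len(docs), 0)),
                          [d.doc_id for d in docs], config)
    return TfidfModel(vec, matrix.tocsr(), [d.doc_id for d in docs], config)


@dataclass
class Bm25Index:
    """Inverted index with Okapi BM25 scoring (Lucene idf form).

    idf(t)   = ln(1 + (n - df + 0.5) / (df + 0.5))
    score    = sum over query terms t in d of
               idf(t) * tf * (k1 + 1) / (tf + k1 * (1 - b + b * |d| / avgdl))
    """

    k1: float = 1.2
    b: float = 0.75
    postings: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    doc_len: dict[str, int] = field(default_factory=dict)
    avgdl: float = 0.0

    @property
    def n_docs(self) -> int:
        return len(self.doc_len)

    def idf(self, term: str) -> float:
        df = len(self.postings.get(term, ()))
        return math.log(1 + (self.n_docs - df + 0.5) / (df + 0.5))

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({
                "format": "fusionsearch-bm25-v1",
                "k1": self.k1, "b": self.b, "avgdl": self.avgdl,
                "doc_len": self.doc_len,
                "postings": {t: [[d, tf] for d, tf in pl]
                             for t, pl in self.postings.items()},
            }, fh)

    @classmethod
    def load(cls, path: str | Path) -> "Bm25Index":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        if raw.get("format") != "fusionsearch-bm25-v1":
            raise ValueError(f"{path}: not a BM25 index file")
        return cls(
            k1=raw["k1"], b=raw["b"], avgdl=raw["avgdl"], doc_len=raw["doc_len"],
            postings={t: [(d, int(tf)) for d, tf in pl]
                      for t, pl in raw["postings"].items()},
        )


def build_bm25(docs: Sequence[Document], k1: float = 1.2, b: float = 0.75) -> Bm25Index:
    if k1 <= 0 or b < 0:
        raise ValueError("BM25 parameters must be positive")
    index = Bm25Index(k1=k1, b=b)
    for doc in docs:
        tokens = tokenize(doc.full_text())
        index.doc_len[doc.doc_id] = len(tokens)
        counts: dict[str, int] = {}
        for t in tokens:
            counts[t] = counts.get(t, 0) + 1
        for term, tf in counts.items():
            index.postings.setdefault(term, []).append((doc.doc_id, tf))
    for plist in index.postings.values():
        plist.sort()
    lens = list(index.doc_len.values())
    index.avgdl = float(sum(lens)) / len(lens) if lens else 0.0
    return index


def bm25_score(query_terms: Sequence[str], doc_id: str, index: Bm25Index) -> float:
    """BM25 score of one document for a bag of query terms (>= 0)."""
    if doc_id not in index.doc_len:
        raise KeyError(f"unknown doc_id {doc_id!r}")
    dl = index.doc_len[doc_id]
    norm = index.k1 * (1 - index.b + index.b * dl / index.avgdl) if index.avgdl else index.k1
    score = 0.0
    for term in query_terms:
        plist = index.postings.get(term)
        if not plist:
            continue
        tf = next((tf for d, tf in plist if d == doc_id), 0)
        if tf == 0:
            continue
        score += index.idf(term) * tf * (index.k1 + 1) / (tf + norm)
    return score


def bm25_search(query_terms: Sequence[str], index: Bm25Index, depth: int,
                topic_id: int = 0) -> RankedList:
    """Top-``depth`` documents by BM25, ties broken by lexicographic doc_id.

    Only documents containing at least one query term are scored (all others
    score exactly 0 and are never returned).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    candidates: set[str] = set()
    for term in set(query_terms):
        candidates.update(d for d, _tf in index.postings.get(term, ()))
    scores = {d: bm25_score(query_terms, d, index) for d in candidates}
    return RankedList.from_scores(topic_id, scores, depth=depth)
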