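"""TREC-style retrieval evaluation: P@N, nDCG@N, MAP, Bpref.

Relevance judgments (qrels) grade (topic, document) pairs 0 (irrelevant),
1 (partially relevant) or 2 (relevant). Judgments are sparse: most retrieved
pairs are unjudged. The metrics handle this differently —

* P@N, MAP treat unjudged documents as non-relevant (binarized at a
  configurable grade threshold, default grade >= 1);
* nDCG@N uses graded relevance, unjudged counting 0;
* Bpref ignores unjudged documents entirely, measuring only how often
  judged-relevant documents are retrieved before judged-nonrelevant ones —
  which makes it robust to missing judgments.

Two formula variants exist for nDCG and Bpref. The defaults here are the
classic discrete forms:

    DCG  = rel_1 + sum_{i=2..N} rel_i / log2(i)
    Bpref = (1/R) sum_r (1 - |nonrelevant above r, capped at R| / R)

with the trec_eval conventions (log2(i+1) discount for every position;
Bpref denominator min(R, #judged-nonrelevant)) available via the
``variant="trec"`` flag.

A judged-only rescoring mode strips unjudged documents from a run before
scoring, re-ranking the survivors contiguously — the protocol used to
compare systems strictly on judged pairs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

from .ranking import RankedList, Run

logger = logging.getLogger(__name__)

DEFAULT_METRICS = ("Bpref", "MAP", "P@5", "P@10", "nDCG@10")


@dataclass
class Qrels:
    """Graded judgments: (topic_id, doc_id) -> grade in {0, 1, 2}."""

    grades: dict[tuple[int, str], int] = field(default_factory=dict)

    def add(self, topic_id: int, doc_id: str, grade: int) -> None:
        if grade not in (0, 1, 2):
            raise ValueError(f"grade must be 0, 1 or 2, got {grade}")
        key = (topic_id, doc_id)
        if key in self.grades and self.grades[key] != grade:
            raise ValueError(f"conflicting judgments for {key}")
        self.grades[key] = grade

    def topics(self) -> list[int]:
        return sorted({t for t, _d in self.grades})

    def grade(self, topic_id: int, doc_id: str) -> int | None:
        return self.grades.get((topic_id, doc_id))

    def judged(self, topic_id: int) -> dict[str, int]:
        return {d: g for (t, d), g in self.grades.items() if t == topic_id}

    def relevant(self, topic_id: int, threshold: int = 1) -> set[str]:
        return {d for d, g in self.judged(topic_id).items() if g >= threshold}

    def save(self, path: str | Path) -> None:
        """Standard TREC qrels format: ``topic_id 0 doc_id grade``."""
        with open(path, "w", encoding="utf-8") as fh:
            for (t, d), g in sorted(self.grades.items()):
                fh.write(f"{t} 0 {d} {g}\n")

    @classmethod
    def load(cls, path: str | Path) -> "Qrels":
        qrels = cls()
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if not line.strip():
                    continue
                t, _iter, d, g = line.split()
                qrels.add(int(t), d, int(g))
        return qrels

    def __len__(self) -> int:
        return len(self.grades)


def precision_at(run_topic: RankedList, qrels: Qrels, n: int,
                 threshold: int = 1) -> float:
    """Fraction of the top-``n`` retrieved documents judged relevant.

    Unjudged documents count as non-relevant, so a system retrieving
    relevant-but-unannotated documents is penalized.
    """
    if n < 1:
        raise ValueError("N must be >= 1")
    hits = sum(
        1 for e in run_topic.entries[:n]
        if (qrels.grade(run_topic.topic_id, e.doc_id) or 0) >= threshold
    )
    return hits / n


def _dcg(grades: list[int], variant: str) -> float:
    if variant == "as_printed":
        return sum(
            g if i == 1 else g / math.log2(i)
            for i, g in enumerate(grades, start=1)
        )
    if variant == "trec":
        return sum(g / math.log2(i + 1) for i, g in enumerate(grades, start=1))
    raise ValueError(f"unknown nDCG variant {variant!r}")


def ndcg_at(run_topic: RankedList, qrels: Qrels, n: int,
            variant: str = "as_printed") -> float:
    """Normalized discounted cumulative gain over the top ``n``.

    The ideal DCG ranks all judged documents for the topic by grade. Defined
    as 0 when the topic has no judged-relevant document (IDCG = 0).
    """
    if n < 1:
        raise ValueError("N must be >= 1")
    topic = run_topic.topic_id
    retrieved = [qrels.grade(topic, e.doc_id) or 0 for e in run_topic.entries[:n]]
    ideal = sorted(qrels.judged(topic).values(), reverse=True)[:n]
    idcg = _dcg(ideal, variant)
    if idcg == 0:
        return 0.0
    return _dcg(retrieved, variant) / idcg


def average_precision(run_topic: RankedList, qrels: Qrels,
                      threshold: int = 1) -> float:
    """Non-interpolated AP: mean of P@rank over the ranks of relevant
    retrieved documents, divided by the *total* judged-relevant count (so
    relevant documents the run missed still count against it)."""
    topic = run_topic.topic_id
    relevant = qrels.relevant(topic, threshold)
    if not relevant:
        logger.warning("topic %d has no judged-relevant documents; AP = 0", topic)
        return 0.0
    hits = 0
    total = 0.0
    for e in run_topic:
        if e.doc_id in relevant:
            hits += 1
            total += hits / e.rank
    return total / len(relevant)


def bpref(run_topic: RankedList, qrels: Qrels, threshold: int = 1,
          variant: str = "as_printed") -> float | None:
    """Binary preference: how often judged-relevant documents are retrieved
    before judged-nonrelevant ones; unjudged documents are ignored entirely.

    ``as_printed`` uses denominator R (the judged-relevant count), counting
    only the first R judged-nonrelevant retrieved documents. ``trec`` uses
    the trec_eval denominator min(R, #judged-nonrelevant). Returns ``None``
    (topic excluded from means) when R = 0.
    """
    topic = run_topic.topic_id
    judged = qrels.judged(topic)
    relevant = {d for d, g in judged.items() if g >= threshold}
    r_total = len(relevant)
    if r_total == 0:
        logger.warning("topic %d has no judged-relevant documents; Bpref undefined",
                       topic)
        return None
    n_nonrel_total = len(judged) - r_total
    if variant == "as_printed":
        denom = r_total
    elif variant == "trec":
        denom = min(r_total, n_nonrel_total)
    else:
        raise ValueError(f"unknown Bpref variant {variant!r}")

    total = 0.0
    nonrel_seen = 0
    for e in run_topic:
        grade = judged.get(e.doc_id)
        if grade is None:
            continue  # unjudged: invisible to Bpref
        if e.doc_id in relevant:
            total += 1.0 if denom == 0 else 1.0 - min(nonrel_seen, denom) / denom
        else:
            nonrel_seen += 1
    return total / r_total


def judged_only_filter(run: Run, qrels: Qrels) -> Run:
    """Keep only judged documents in each topic's list, re-ranking the
    survivors contiguously from 1 with scores preserved."""
    out: Run = {}
    for topic_id, ranked in run.items():
        kept = [e for e in ranked if qrels.grade(topic_id, e.doc_id) is not None]
        out[topic_id] = RankedList(topic_id, [
            type(e)(e.doc_id, e.score, i + 1) for i, e in enumerate(kept)
        ])
    return out


@dataclass
class MetricReport:
    """Per-topic and mean metric values.

    Means are over the topics present in the qrels; a topic the run missed
    scores 0 on every metric except Bpref, which excludes topics with no
    judged-relevant documents.
    """

    per_topic: dict[str, dict[int, float | None]]
    mean: dict[str, float]
    judged_only: bool = False

    def __getitem__(self, metric: str) -> float:
        return self.mean[metric]


def evaluate(run: Run, qrels: Qrels, p_cutoffs: tuple[int, ...] = (5, 10),
             ndcg_cutoffs: tuple[int, ...] = (10,), judged_only: bool = False,
             threshold: int = 1, ndcg_variant: str = "as_printed",
             bpref_variant: str = "as_printed") -> MetricReport:
    """Score a run against qrels: Bpref, MAP, P@N, nDCG@N by default."""
    topics = qrels.topics()
    if not topics or not set(run) & set(topics):
        raise ValueError("run and qrels share no topics")
    if judged_only:
        run = judged_only_filter(run, qrels)

    metrics = (["Bpref", "MAP"] + [f"P@{n}" for n in p_cutoffs]
               + [f"nDCG@{n}" for n in ndcg_cutoffs])
    per_topic: dict[str, dict[int, float | None]] = {m: {} for m in metrics}
    for topic_id in topics:
        ranked = run.get(topic_id, RankedList(topic_id, []))
        per_topic["Bpref"][topic_id] = bpref(ranked, qrels, threshold, bpref_variant)
        per_topic["MAP"][topic_id] = average_precision(ranked, qrels, threshold)
        for n in p_cutoffs:
            per_topic[f"P@{n}"][topic_id] = precision_at(ranked, qrels, n, threshold)
        for n in ndcg_cutoffs:
            per_topic[f"nDCG@{n}"][topic_id] = ndcg_at(ranked, qrels, n, ndcg_variant)

    mean = {}
    for metric, values in per_topic.items():
        defined = [v for v in values.values() if v is not None]
        mean[metric] = sum(defined) / len(defined) if defined else 0.0
    return MetricReport(per_topic, mean, judged_only)
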