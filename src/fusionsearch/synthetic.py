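"""Seeded synthetic corpora with planted topical structure.

The generator emulates, at toy scale, the structure the cascade exploits in a
real scholarly corpus: documents cluster into topics with distinctive
vocabulary; topics overlap partially with their neighbors; citations are
homophilous (documents mostly cite within their topic); and relevance
judgments grade same-topic documents relevant, vocabulary-sharing
adjacent-topic documents partially relevant, and a sample of off-topic
documents irrelevant.

Text is a bag of Zipf-distributed tokens joined by spaces — no grammar, no
prose. That is sufficient to separate the sparse and dense channels and to
plant recoverable structure, and it is cheap enough to regenerate on every
test run. Everything is driven by one seed: equal seeds give byte-identical
serialized output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .corpus import CitationEntry, Document, Paragraph, Topic
from .evaluation import Qrels


@dataclass(frozen=True)
class SynthParams:
    n_topics: int = 5
    docs_per_topic: int = 100
    vocab_size: int = 2000          # total distinct terms
    block_size: int = 60            # topic-specific terms per topic
    topic_vocab_overlap: float = 0.1  # fraction of a block borrowed from the next
    paragraphs_per_doc: tuple[int, int] = (2, 5)  # inclusive range
    tokens_per_paragraph: int = 40
    topic_token_weight: float = 0.55  # mixture weight of topic block vs background
    within_topic_citation_prob: float = 0.9
    max_citations_per_paragraph: int = 2
    qrels_coverage: float = 1.0     # subsample fraction of judgments
    zero_judgments_per_topic: int = 20
    seed: int = 0

    def __post_init__(self):
        if min(self.n_topics, self.docs_per_topic, self.vocab_size,
               self.block_size) < 1:
            raise ValueError("all counts must be >= 1")
        for frac in (self.topic_vocab_overlap, self.within_topic_citation_prob,
                     self.qrels_coverage):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must be in [0, 1]")
        if self.vocab_size < self.n_topics * self.block_size + self.block_size:
            raise ValueError(
                "vocab_size too small for the requested topic blocks "
                f"(need > {self.n_topics * self.block_size})"
            )


def _zipf_probs(n: int) -> np.ndarray:
    p = 1.0 / np.arange(1, n + 1)
    return p / p.sum()


def generate(params: SynthParams = SynthParams()) -> tuple[list[Document], list[Topic], Qrels]:
    """Generate (corpus, topics, qrels) with planted topical clusters."""
    rng = np.random.default_rng(params.seed)
    vocab = [f"w{i:05d}" for i in range(params.vocab_size)]
    blocks = [
        vocab[t * params.block_size:(t + 1) * params.block_size]
        for t in range(params.n_topics)
    ]
    background = vocab[params.n_topics * params.block_size:]
    n_borrow = int(round(params.topic_vocab_overlap * params.block_size))

    def effective_block(t: int) -> list[str]:
        # own terms plus the head of the next topic's block (ring adjacency)
        borrowed = blocks[(t + 1) % params.n_topics][:n_borrow]
        return blocks[t] + borrowed

    def sample_tokens(t: int, n: int) -> list[str]:
        block = effective_block(t)
        from_topic = rng.random(n) < params.topic_token_weight
        n_topic = int(from_topic.sum())
        topic_tokens = rng.choice(block, size=n_topic, p=_zipf_probs(len(block)))
        bg_tokens = rng.choice(background, size=n - n_topic,
                               p=_zipf_probs(len(background)))
        out = np.empty(n, dtype=object)
        out[from_topic] = topic_tokens
        out[~from_topic] = bg_tokens
        return list(out)

    # Documents (titles first: they are the citation targets).
    doc_topic: dict[str, int] = {}
    titles: dict[str, str] = {}
    doc_ids: list[str] = []
    for t in range(params.n_topics):
        probs = _zipf_probs(len(blocks[t]))
        for i in range(params.docs_per_topic):
            doc_id = f"d{t:02d}{i:04d}"
            doc_ids.append(doc_id)
            doc_topic[doc_id] = t
            head = rng.choice(blocks[t], size=3, replace=False, p=probs)
            titles[doc_id] = f"study of {' '.join(head)} cohort {t}{i:04d}"

    by_topic = [
        [d for d in doc_ids if doc_topic[d] == t] for t in range(params.n_topics)
    ]

    docs: list[Document] = []
    lo, hi = params.paragraphs_per_doc
    for doc_id in doc_ids:
        t = doc_topic[doc_id]
        n_para = int(rng.integers(lo, hi + 1))
        cited: list[str] = []  # target doc_ids, in citation order
        paragraphs: list[Paragraph] = []
        for j in range(n_para):
            tokens = sample_tokens(t, params.tokens_per_paragraph)
            n_cit = int(rng.integers(0, params.max_citations_per_paragraph + 1))
            keys = []
            for _ in range(n_cit):
                if rng.random() < params.within_topic_citation_prob:
                    pool = [d for d in by_topic[t] if d != doc_id]
                else:
                    pool = [d for d in doc_ids if doc_topic[d] != t]
                target = pool[int(rng.integers(len(pool)))]
                if target not in cited:
                    cited.append(target)
                keys.append(f"b{cited.index(target)}")
            paragraphs.append(
                Paragraph(doc_id, j, " ".join(tokens), tuple(dict.fromkeys(keys)))
            )
        captions = []
        if rng.random() < 0.3:
            captions.append("figure showing " + " ".join(sample_tokens(t, 10)))
        docs.append(Document(
            doc_id=doc_id,
            title=titles[doc_id],
            abstract=" ".join(sample_tokens(t, 20)),
            paragraphs=paragraphs,
            captions=captions,
            bibliography=[
                CitationEntry(f"b{i}", titles[d]) for i, d in enumerate(cited)
            ],
        ))

    # Topics: queries built from each block's highest-probability terms.
    topics = []
    for t in range(params.n_topics):
        head = blocks[t][:6]
        topics.append(Topic(
            topic_id=t + 1,
            query=" ".join(head[:3]),
            question=f"which studies discuss {' '.join(head[3:6])}",
            narrative=f"reports mentioning {' '.join(head)}",
        ))

    # Qrels: 2 same-topic; 1 adjacent-topic docs that substantially share the
    # topic's own vocabulary (>= 3 distinct terms, reachable via block
    # borrowing); 0 for a sample of the rest.
    qrels = Qrels()
    own_terms = [set(b) for b in blocks]
    doc_tokens = {d.doc_id: set(d.full_text().split()) for d in docs}
    for t in range(params.n_topics):
        topic_id = t + 1
        for d in by_topic[t]:
            qrels.add(topic_id, d, 2)
        prev_topic = (t - 1) % params.n_topics
        if prev_topic != t:
            for d in by_topic[prev_topic]:
                if len(doc_tokens[d] & own_terms[t]) >= 3:
                    qrels.add(topic_id, d, 1)
        unjudged = [d for d in doc_ids if (topic_id, d) not in qrels.grades]
        n_zero = min(params.zero_judgments_per_topic, len(unjudged))
        if n_zero:
            for d in rng.choice(unjudged, size=n_zero, replace=False):
                qrels.add(topic_id, str(d), 0)

    if params.qrels_coverage < 1.0:
        keys = sorted(qrels.grades)
        keep = rng.random(len(keys)) < params.qrels_coverage
        qrels = _subsample(qrels, [k for k, m in zip(keys, keep) if m])

    return docs, topics, qrels


def _subsample(qrels: Qrels, keys: Sequence[tuple[int, str]]) -> Qrels:
    out = Qrels()
    for t, d in keys:
        out.add(t, d, qrels.grades[(t, d)])
    return out
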