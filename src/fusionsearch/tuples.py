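"""Citation-bipartite training-tuple generation.

Documents are split into paragraphs; each inline citation resolved against the
document bibliography yields an edge (paragraph, citation title) in a bipartite
graph. Positive training tuples are exactly the edges; negatives pair each
paragraph with citation titles it does *not* cite, sampled uniformly, one per
positive, so the output is balanced. These tuples are the supervision signal
for training a bi-encoder to match short query-like texts (titles) to
paragraphs; the training itself is out of scope and trainer-agnostic writers
(TSV / JSON-lines) are provided instead.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .corpus import Document
from .text import normalize_title

logger = logging.getLogger(__name__)

ParaId = tuple[str, int]


@dataclass
class BipartiteGraph:
    """Paragraph / citation-title bipartite graph.

    Citation titles are normalized (casefold + whitespace collapse) before
    node identity, so format variants of the same cited work collapse to one
    node. ``paragraph_text`` retains the raw text needed to emit tuples.
    """

    paragraph_nodes: set[ParaId] = field(default_factory=set)
    citation_nodes: set[str] = field(default_factory=set)
    edges: set[tuple[ParaId, str]] = field(default_factory=set)
    paragraph_text: dict[ParaId, str] = field(default_factory=dict)
    dangling_count: int = 0

    def neighbors(self, para_id: ParaId) -> set[str]:
        return {c for (p, c) in self.edges if p == para_id}


@dataclass(frozen=True)
class TrainingTuple:
    paragraph_text: str
    citation_title: str
    label: int  # 1 positive (edge), 0 negative (non-edge)


def build_graph(docs: Iterable[Document]) -> BipartiteGraph:
    """One edge per (paragraph, resolved cited title); captions excluded.

    Dangling citation keys (no bibliography entry) are skipped and counted.
    """
    g = BipartiteGraph()
    for doc in docs:
        titles = doc.bib_titles()
        for para in doc.paragraphs:
            pid = para.para_id
            g.paragraph_nodes.add(pid)
            g.paragraph_text[pid] = para.text
            for key in para.cited_keys:
                if key not in titles:
                    g.dangling_count += 1
                    continue
                title = normalize_title(titles[key])
                if not title:
                    continue
                g.citation_nodes.add(title)
                g.edges.add((pid, title))
    return g


def sample_tuples(graph: BipartiteGraph, seed: int) -> list[TrainingTuple]:
    """Balanced positive/negative tuples, fully reproducible given ``seed``.

    Positives are the graph edges. For each paragraph, as many negatives as it
    has positives are drawn uniformly from the citation titles not adjacent to
    it — without replacement while distinct candidates remain, topping up with
    replacement (warned) when a paragraph has fewer non-adjacent titles than
    positives, so the output stays balanced. A paragraph adjacent to every
    citation title contributes no negatives (warned); only then is the output
    unbalanced, by that paragraph's positive count.
    """
    if not graph.edges:
        raise ValueError("cannot sample tuples from a graph with no edges")
    rng = np.random.default_rng(seed)
    all_titles = sorted(graph.citation_nodes)
    out: list[TrainingTuple] = []
    # Deterministic paragraph order, independent of set iteration order.
    by_para: dict[ParaId, list[str]] = {}
    for pid, title in sorted(graph.edges):
        by_para.setdefault(pid, []).append(title)
    for pid, pos_titles in by_para.items():
        for title in pos_titles:
            out.append(TrainingTuple(graph.paragraph_text[pid], title, 1))
        adjacent = set(pos_titles)
        candidates = [t for t in all_titles if t not in adjacent]
        if not candidates:
            logger.warning(
                "paragraph %r cites every citation title; no negatives sampled", pid
            )
            continue
        n_neg = len(pos_titles)
        n_distinct = min(n_neg, len(candidates))
        picks = list(rng.choice(len(candidates), size=n_distinct, replace=False))
        if n_distinct < n_neg:
            logger.warning(
                "paragraph %r: only %d non-adjacent titles for %d positives; "
                "repeating negatives to keep the output balanced",
                pid, len(candidates), n_neg,
            )
            picks += list(rng.choice(len(candidates), size=n_neg - n_distinct))
        for i in picks:
            out.append(TrainingTuple(graph.paragraph_text[pid], candidates[i], 0))
    return out


def write_tuples_tsv(tuples: Iterable[TrainingTuple], path: str | Path) -> None:
    """Columns: paragraph_text, citation_title, label. Tabs/newlines in text
    are replaced by spaces so the file stays one-record-per-line."""
    with open(path, "w", encoding="utf-8") as fh:
        for t in tuples:
            para = t.paragraph_text.replace("\t", " ").replace("\n", " ")
            title = t.citation_title.replace("\t", " ").replace("\n", " ")
            fh.write(f"{para}\t{title}\t{t.label}\n")


def write_tuples_jsonl(tuples: Iterable[TrainingTuple], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t in tuples:
            fh.write(json.dumps(
                {"paragraph": t.paragraph_text, "citation_title": t.citation_title,
                 "label": t.label},
                ensure_ascii=False) + "\n")
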