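"""Ranked lists and TREC run-file I/O — the currency passed between stages."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping


@dataclass(frozen=True)
class RankedEntry:
    doc_id: str
    score: float
    rank: int  # 1-based


@dataclass
class RankedList:
    """An ordered result list for one topic.

    Invariants: ranks contiguous from 1, scores non-increasing, doc_ids
    unique. All ranking in the package breaks score ties by lexicographic
    doc_id, so equal inputs always produce identical lists.
    """

    topic_id: int
    entries: list[RankedEntry]

    @classmethod
    def from_scores(cls, topic_id: int, scores: Mapping[str, float],
                    depth: int | None = None) -> "RankedList":
        """Induce a ranking: sort by descending score, ties by doc_id."""
        ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
        if depth is not None:
            ordered = ordered[:depth]
        return cls(topic_id, [
            RankedEntry(doc_id, float(score), i + 1)
            for i, (doc_id, score) in enumerate(ordered)
        ])

    def doc_ids(self) -> list[str]:
        return [e.doc_id for e in self.entries]

    def scores(self) -> dict[str, float]:
        return {e.doc_id: e.score for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[RankedEntry]:
        return iter(self.entries)

    def validate(self) -> None:
        ranks = [e.rank for e in self.entries]
        if ranks != list(range(1, len(ranks) + 1)):
            raise ValueError(f"topic {self.topic_id}: ranks not contiguous from 1")
        scores = [e.score for e in self.entries]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise ValueError(f"topic {self.topic_id}: scores increase down the list")
        ids = self.doc_ids()
        if len(ids) != len(set(ids)):
            raise ValueError(f"topic {self.topic_id}: duplicate doc_id")


Run = dict[int, RankedList]
"""A full run: topic_id -> RankedList."""


def write_run(run: Run, path: str | Path, tag: str = "fusionsearch") -> None:
    """Standard TREC run format: ``topic_id Q0 doc_id rank score tag``."""
    with open(path, "w", encoding="utf-8") as fh:
        for topic_id in sorted(run):
            for e in run[topic_id].entries:
                fh.write(f"{topic_id} Q0 {e.doc_id} {e.rank} {e.score:.6f} {tag}\n")


def read_run(path: str | Path) -> Run:
    """Read a TREC run file; entries re-sorted by the stated rank per topic."""
    per_topic: dict[int, list[RankedEntry]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            topic_id, _q0, doc_id, rank, score, _tag = line.split()
            per_topic.setdefault(int(topic_id), []).append(
                RankedEntry(doc_id, float(score), int(rank))
            )
    run: Run = {}
    for topic_id, entries in per_topic.items():
        entries.sort(key=lambda e: e.rank)
        run[topic_id] = RankedList(topic_id, entries)
    return run
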