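"""Corpus data model: documents, paragraphs, citations, topics, and readers.

The corpus is a minimal JSON-lines dialect (UTF-8, one document per line):

.. code-block:: json

    {"doc_id": "d1", "title": "...", "abstract": "...",
     "paragraphs": [{"text": "...", "cited_keys": ["b1"]}],
     "captions": ["..."],
     "bibliography": [{"bib_key": "b1", "title": "..."}]}

This is a deliberately small stand-in for full-text scholarly corpora such
as CORD-19; an adapter mapping CORD-19's ``paper_id``/``body_text``/
``ref_entries``/``bib_entries`` fields onto this schema is a thin transform
(see README) and is out of scope here.

Topics are (query, question, narrative) triples, read either from a
tab-separated file or from the TREC-COVID XML topic layout.
"""

from __future__ import annotations

import enum
import json
import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .text import normalize_ws

logger = logging.getLogger(__name__)


class CorpusError(ValueError):
    """Malformed corpus input (bad line, duplicate id, schema violation)."""


@dataclass(frozen=True)
class CitationEntry:
    """One bibliography entry: a key as cited inline, and the cited title."""

    bib_key: str
    title: str


@dataclass(frozen=True)
class Paragraph:
    """A unit of embedding: one paragraph (or caption) of one document.

    ``para_id`` is the (doc_id, ordinal) pair; ordinals are contiguous per
    document, with captions promoted after the body paragraphs and flagged.
    """

    doc_id: str
    ordinal: int
    text: str
    cited_keys: tuple[str, ...] = ()
    is_caption: bool = False

    @property
    def para_id(self) -> tuple[str, int]:
        return (self.doc_id, self.ordinal)


@dataclass
class Document:
    doc_id: str
    title: str = ""
    abstract: str = ""
    paragraphs: list[Paragraph] = field(default_factory=list)
    captions: list[str] = field(default_factory=list)
    bibliography: list[CitationEntry] = field(default_factory=list)

    def bib_titles(self) -> dict[str, str]:
        """bib_key -> title lookup."""
        return {e.bib_key: e.title for e in self.bibliography}

    def dangling_keys(self) -> list[str]:
        """Inline citation keys that resolve to no bibliography entry."""
        known = set(self.bib_titles())
        out = []
        for p in self.paragraphs:
            out.extend(k for k in p.cited_keys if k not in known)
        return out

    def text_fields(self) -> list[str]:
        """All searchable text of the document, in reading order."""
        return (
            [self.title, self.abstract]
            + [p.text for p in self.paragraphs]
            + list(self.captions)
        )

    def full_text(self) -> str:
        return " ".join(t for t in self.text_fields() if t)


@dataclass(frozen=True)
class Topic:
    """A search topic: query, question, and narrative, increasingly detailed."""

    topic_id: int
    query: str
    question: str = ""
    narrative: str = ""


class FieldPolicy(str, enum.Enum):
    """Which topic fields are submitted to the engine as query text."""

    QUERY = "query"
    QUESTION = "question"
    QUERY_QUESTION = "query+question"


def topic_text(topic: Topic, policy: FieldPolicy = FieldPolicy.QUERY_QUESTION) -> str:
    """Deterministic single-space join of the selected topic fields."""
    policy = FieldPolicy(policy)
    if policy is FieldPolicy.QUERY:
        parts = [topic.query]
    elif policy is FieldPolicy.QUESTION:
        parts = [topic.question]
    else:
        parts = [topic.query, topic.question]
    return " ".join(p for p in parts if p)


def _parse_document(record: dict) -> Document:
    doc_id = record["doc_id"]
    paragraphs = []
    for i, p in enumerate(record.get("paragraphs", [])):
        text = normalize_ws(p["text"])
        if not text:
            raise CorpusError(f"doc {doc_id!r}: paragraph {i} empty after normalization")
        paragraphs.append(
            Paragraph(doc_id, i, text, tuple(p.get("cited_keys", [])))
        )
    bib = [CitationEntry(e["bib_key"], e["title"]) for e in record.get("bibliography", [])]
    keys = [e.bib_key for e in bib]
    if len(keys) != len(set(keys)):
        raise CorpusError(f"doc {doc_id!r}: duplicate bib_key")
    return Document(
        doc_id=doc_id,
        title=record.get("title", ""),
        abstract=record.get("abstract", ""),
        paragraphs=paragraphs,
        captions=list(record.get("captions", [])),
        bibliography=bib,
    )


def read_corpus(path: str | Path) -> list[Document]:
    """Read a JSON-lines corpus, preserving file order.

    Dangling citation keys are logged (one warning per document), not fatal.
    A malformed line or duplicate ``doc_id`` raises :class:`CorpusError`
    naming the line number.
    """
    docs: list[Document] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                record = json.loads(line)
                doc = _parse_document(record)
            except (json.JSONDecodeError, KeyError, TypeError, CorpusError) as exc:
                raise CorpusError(f"{path}: line {lineno}: {exc}") from exc
            if doc.doc_id in seen:
                raise CorpusError(f"{path}: line {lineno}: duplicate doc_id {doc.doc_id!r}")
            seen.add(doc.doc_id)
            dangling = doc.dangling_keys()
            if dangling:
                logger.warning(
                    "doc %r: %d dangling citation key(s): %s",
                    doc.doc_id, len(dangling), sorted(set(dangling)),
                )
            docs.append(doc)
    return docs


def write_corpus(docs: Iterable[Document], path: str | Path) -> None:
    """Inverse of :func:`read_corpus` (round-trip identical)."""
    with open(path, "w", encoding="utf-8") as fh:
        for d in docs:
            record = {
                "doc_id": d.doc_id,
                "title": d.title,
                "abstract": d.abstract,
                "paragraphs": [
                    {"text": p.text, "cited_keys": list(p.cited_keys)}
                    for p in d.paragraphs
                ],
                "captions": list(d.captions),
                "bibliography": [
                    {"bib_key": e.bib_key, "title": e.title} for e in d.bibliography
                ],
            }
            fh.write(json.dumps(record, ensure_ascii=False, sort_keys=True) + "\n")


def split_paragraphs(doc: Document) -> list[Paragraph]:
    """Document -> embedding units: body paragraphs, then captions.

    Captions are promoted to caption-paragraphs with contiguous ordinals and
    ``is_caption=True``; they carry no inline citations. The unit count is
    always ``len(doc.paragraphs) + len(doc.captions)``.
    """
    units = list(doc.paragraphs)
    base = len(units)
    for j, cap in enumerate(doc.captions):
        units.append(Paragraph(doc.doc_id, base + j, normalize_ws(cap), (), True))
    return units


def read_topics_tsv(path: str | Path) -> list[Topic]:
    """Tab-separated topics: topic_id, query, question, narrative."""
    topics = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise CorpusError(f"{path}: line {lineno}: expected >=2 tab-separated fields")
            parts += [""] * (4 - len(parts))
            topics.append(Topic(int(parts[0]), parts[1], parts[2], parts[3]))
    ids = [t.topic_id for t in topics]
    if len(ids) != len(set(ids)):
        raise CorpusError(f"{path}: duplicate topic_id")
    return topics


def write_topics_tsv(topics: Iterable[Topic], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t in topics:
            fh.write(f"{t.topic_id}\t{t.query}\t{t.question}\t{t.narrative}\n")


def read_topics_xml(path: str | Path) -> list[Topic]:
    """TREC-COVID XML topic layout:

    ``<topics><topic number="1"><query>..</query><question>..</question>
    <narrative>..</narrative></topic>...</topics>``
    """
    root = ET.parse(path).getroot()
    topics = []
    for el in root.findall("topic"):
        topics.append(
            Topic(
                topic_id=int(el.get("number")),
                query=normalize_ws(el.findtext("query", "")),
                question=normalize_ws(el.findtext("question", "")),
                narrative=normalize_ws(el.findtext("narrative", "")),
            )
        )
    return topics
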