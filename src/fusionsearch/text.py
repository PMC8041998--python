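"""Deterministic text primitives shared by the sparse, dense and rerank stages.

The choices here are deliberately frozen: every index, embedding and score in
the pipeline depends on them, so they are simple, documented, and never
locale-dependent.
"""

from __future__ import annotations

import re

_TOKEN_SPLIT = re.compile(r"[^0-9a-z]+")

# Sentence boundary: terminal punctuation, whitespace, then an uppercase letter
# or digit. Intentionally naive but deterministic.
_SENTENCE_SPLIT = re.compile(r"(?<=[.?!])\s+(?=[A-Z0-9])")

_WS = re.compile(r"\s+")


def tokenize(text: str) -> list[str]:
    """Lowercase and split on non-alphanumeric runs.

    No stemming, no stopword removal: the simplest reproducible analyzer,
    used identically for TF-IDF, BM25 and the stub embedder.
    """
    return [t for t in _TOKEN_SPLIT.split(text.lower()) if t]


def split_sentences(text: str) -> list[str]:
    """Split on ``[.?!]`` followed by whitespace and an uppercase/digit start."""
    text = text.strip()
    if not text:
        return []
    return [s for s in _SENTENCE_SPLIT.split(text) if s.strip()]


def count_tokens(text: str) -> int:
    """Whitespace-delimited word count (the unit of the 512/65 length limits)."""
    return len(text.split())


def normalize_ws(text: str) -> str:
    """Collapse internal whitespace and strip."""
    return _WS.sub(" ", text).strip()


def normalize_title(title: str) -> str:
    """Casefold + whitespace collapse; identity for citation-title nodes."""
    return normalize_ws(title.casefold())
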