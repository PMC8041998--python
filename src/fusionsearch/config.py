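"""Pipeline configuration: every engine constant surfaced, none hard-coded.

The defaults are the reference operating point of the cascade — mu = 0.7,
RRF k = 60, retrieval depth 1000, BM25 k1 = 1.2 / b = 0.75, TF-IDF vocabulary
13,000 with max_df 0.5 and min_df 3 — and experiments vary them explicitly
through a TOML file. Configs hash stably (sha256 over canonical JSON), so a
run manifest pins exactly what produced it.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import asdict, dataclass, replace
from pathlib import Path

from .corpus import FieldPolicy


@dataclass(frozen=True)
class PipelineConfig:
    # fusion
    mu: float = 0.7
    k: float = 60.0
    depth: int = 1000
    dense_candidates: int = 5000
    knn_mode: str = "exact"
    # bm25
    bm25_k1: float = 1.2
    bm25_b: float = 0.75
    # tfidf
    tfidf_vocab_size: int = 13_000
    tfidf_max_df: float = 0.5
    tfidf_min_df: int = 3
    # query construction
    field_policy: str = FieldPolicy.QUERY_QUESTION.value
    # pluggable models (by registry name)
    embedder: str = "hashed-projection"
    embedder_dim: int = 64
    embedder_seed: int = 0
    extractor: str = "keyword"
    summarizer: str = "lead"
    rerank_enabled: bool = True
    rerank_context_docs: int = 10
    # bookkeeping
    run_tag: str = "fusionsearch"
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def with_overrides(self, **kw) -> "PipelineConfig":
        return replace(self, **kw)


_SECTIONS = {
    "fusion": ("mu", "k", "depth", "dense_candidates", "knn_mode"),
    "bm25": ("bm25_k1", "bm25_b"),
    "tfidf": ("tfidf_vocab_size", "tfidf_max_df", "tfidf_min_df"),
    "query": ("field_policy",),
    "models": ("embedder", "embedder_dim", "embedder_seed", "extractor",
               "summarizer", "rerank_enabled", "rerank_context_docs"),
    "run": ("run_tag", "seed"),
}


def load_config(path: str | Path) -> PipelineConfig:
    """Read a TOML config; unknown keys are rejected, missing ones default."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    values: dict = {}
    for section, keys in _SECTIONS.items():
        body = raw.pop(section, {})
        for key, value in body.items():
            full = key if key in keys else None
            # section-local names drop the section prefix (e.g. bm25.k1)
            if full is None:
                prefixed = f"{section}_{key}"
                full = prefixed if prefixed in keys else None
            if full is None:
                raise ValueError(f"unknown config key [{section}] {key}")
            values[full] = value
    if raw:
        raise ValueError(f"unknown config section(s): {sorted(raw)}")
    config = PipelineConfig(**values)
    FieldPolicy(config.field_policy)  # validate
    return config


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    return json.dumps(v)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    """Emit the config as TOML (flat scalar sections only)."""
    d = config.to_dict()
    lines = []
    for section, keys in _SECTIONS.items():
        lines.append(f"[{section}]")
        for key in keys:
            local = key[len(section) + 1:] if key.startswith(section + "_") else key
            lines.append(f"{local} = {_toml_value(d[key])}")
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")
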