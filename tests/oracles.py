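"""Independent straight-line reference implementations used as test oracles.

Everything here works on plain Python data (lists of doc_ids, dicts of
grades, token lists) and is written directly from the metric and scoring
definitions, with no imports from the package under test — so agreement
between the two is a genuine cross-check, not a tautology.
"""

from __future__ import annotations

import math
from collections import Counter


# ---------------------------------------------------------------------------
# TREC metric oracles (trec-eval semantics unless noted)

def precision_oracle(ranked: list[str], grades: dict[str, int], n: int,
                     threshold: int = 1) -> float:
    return sum(1 for d in ranked[:n] if grades.get(d, 0) >= threshold) / n


def ap_oracle(ranked: list[str], grades: dict[str, int],
              threshold: int = 1) -> float:
    relevant = {d for d, g in grades.items() if g >= threshold}
    if not relevant:
        return 0.0
    hits, total = 0, 0.0
    for i, d in enumerate(ranked, start=1):
        if d in relevant:
            hits += 1
            total += hits / i
    return total / len(relevant)


def ndcg_oracle(ranked: list[str], grades: dict[str, int], n: int,
                variant: str = "trec") -> float:
    def dcg(gains: list[int]) -> float:
        if variant == "trec":
            return sum(g / math.log2(i + 1) for i, g in enumerate(gains, 1))
        # classic discrete form: positions 1 and 2 undiscounted
        return sum(g if i == 1 else g / math.log2(i)
                   for i, g in enumerate(gains, 1))

    got = [grades.get(d, 0) for d in ranked[:n]]
    ideal = sorted(grades.values(), reverse=True)[:n]
    denom = dcg(ideal)
    return dcg(got) / denom if denom > 0 else 0.0


def bpref_enumeration_oracle(ranked: list[str], grades: dict[str, int],
                             threshold: int = 1) -> float | None:
    """Direct enumeration of the binary-preference sum: for each judged
    relevant retrieved document r, count the judged nonrelevant documents
    among the first R such ranked above r; denominator R."""
    relevant = {d for d, g in grades.items() if g >= threshold}
    nonrelevant = {d for d in grades if d not in relevant}
    big_r = len(relevant)
    if big_r == 0:
        return None
    # the first R judged-nonrelevant retrieved documents, with their ranks
    first_r_nonrel_ranks = [
        i for i, d in enumerate(ranked) if d in nonrelevant
    ][:big_r]
    total = 0.0
    for i, d in enumerate(ranked):
        if d in relevant:
            n_above = sum(1 for j in first_r_nonrel_ranks if j < i)
            total += 1.0 - n_above / big_r
    return total / big_r


# ---------------------------------------------------------------------------
# BM25 reference (Okapi with Lucene idf), computed from raw token lists

def bm25_reference(query_tokens: list[str], doc_tokens: dict[str, list[str]],
                   doc_id: str, k1: float = 1.2, b: float = 0.75) -> float:
    n = len(doc_tokens)
    avgdl = sum(len(t) for t in doc_tokens.values()) / n
    counts = Counter(doc_tokens[doc_id])
    dl = len(doc_tokens[doc_id])
    score = 0.0
    for term in query_tokens:
        tf = counts.get(term, 0)
        if tf == 0:
            continue
        df = sum(1 for toks in doc_tokens.values() if term in toks)
        idf = math.log(1 + (n - df + 0.5) / (df + 0.5))
        score += idf * tf * (k1 + 1) / (tf + k1 * (1 - b + b * dl / avgdl))
    return score


def bm25_full_ranking(query_tokens: list[str],
                      doc_tokens: dict[str, list[str]],
                      k1: float = 1.2, b: float = 0.75) -> list[str]:
    """Exhaustively score every doc; drop zero scores; sort desc, tie by id."""
    scores = {
        d: bm25_reference(query_tokens, doc_tokens, d, k1, b)
        for d in doc_tokens
    }
    scored = [(d, s) for d, s in scores.items() if s > 0]
    return [d for d, _s in sorted(scored, key=lambda kv: (-kv[1], kv[0]))]


# ---------------------------------------------------------------------------
# Dense / fusion oracles

def knn_bruteforce(query, matrix, ids, m):
    """Top-m rows by cosine against unit-row matrix; ties by id."""
    import numpy as np

    q = np.asarray(query, dtype=float)
    norm = np.linalg.norm(q)
    if norm > 0:
        q = q / norm
    cosines = matrix @ q
    order = sorted(range(len(ids)), key=lambda i: (-cosines[i], ids[i]))[:m]
    return [(ids[i], float(cosines[i])) for i in order]


def rrf_oracle(lists: list[list[str]], k: float) -> dict[str, float]:
    """Sum 1/(k + 1-based rank) over every list containing the doc."""
    scores: dict[str, float] = {}
    for ranked in lists:
        for i, d in enumerate(ranked, start=1):
            scores[d] = scores.get(d, 0.0) + 1.0 / (k + i)
    return scores
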