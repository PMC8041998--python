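# Methods

This note records the models the package implements, the defaults it ships,
the numerical conventions it freezes, and what its tests do and do not
demonstrate.

## The cascade

Retrieval is a two-stage cascade. Stage one produces a top-1000 candidate
list per topic from three channels; stage two re-orders that list.

**Dense channel.** Paragraphs and figure captions are the unit of embedding:
long documents are too heterogeneous for a single vector, while a paragraph
is short enough for a bi-encoder to represent faithfully. A document enters
the dense candidate pool if any of its units is retrieved by k-nearest-
neighbor search, and is scored by its best unit, `max_{p∈d} cos(p_e, q_e)`.
The max (rather than mean) rewards a single highly relevant passage inside an
otherwise broad paper, which matches how a reader judges relevance.

**TF-IDF channel.** Whole-document vectors under the smoothed-idf weighting
`tf·(ln((1+n)/(1+df))+1)` (natural log), L2-normalized, cosine-scored. The
smoothing keeps idf finite for terms present in every document and bounds
every weight below by tf. Defaults: vocabulary capped at 13,000 terms,
max_df 0.5 (drops corpus-wide boilerplate), min_df 3 (drops hapax noise).
The vectorization is delegated to scikit-learn's TfidfVectorizer, whose idf
matches the formula exactly; `tfidf_weight` implements it directly and the
test suite cross-checks the two against each other.

**BM25 channel.** Okapi BM25 over an inverted index with the Lucene idf
`ln(1 + (n − df + 0.5)/(df + 0.5))`, k1 = 1.2, b = 0.75. The classic
`(k1+1)` numerator factor is kept; it scales every term equally and is
therefore rank-preserving, so the choice between the older and newer Lucene
conventions does not affect any ranking this package produces.

**Fusion.** `C = μ·dense + (1−μ)·tfidf` with μ = 0.7 weights meaning over
keywords but keeps the exact-match signal alive; C is computed over the
union of the dense and TF-IDF candidate sets, with a missing channel
contributing 0 (not −1: that keeps C on the same nonnegative scale as the
TF-IDF cosine). The induced ranking is merged with the BM25 ranking by
reciprocal rank fusion, `Σ 1/(k + rank)` with k = 60 and 1-based ranks. A
document absent from one list simply contributes no term for it; assigning
pseudo-ranks would let a single channel's tail dominate. RRF operates on
ranks, not scores, so the three channels' incomparable score scales never
need calibration.

**Re-ranking.** `R = S·Q·RRF` with `Q = 1.1^N` (N = distinct answer spans
found case-insensitively in the document's title, abstract, paragraphs or
captions; no cap on N) and `S = ½ + ½·max_{p∈d} cos(p_e, M(q)_e)` (the
affine map keeps S in [0,1] so it can only attenuate, never negate). Both
multiplicative factors default to 1 when their module is disabled, so
ablations reduce cleanly to pure retrieval. The answer extractor and
summarizer are contracts; the shipped reference implementations are
deterministic and training-free — a keyword-span extractor (query tokens of
length ≥ 4 occurring verbatim in the top retrieved paragraphs) and a
lead-sentence summarizer (first sentence of each of the first three
paragraphs of the assembled input, truncated to the short-summary budget).
They are honest members of their contract classes, not approximations of any
particular neural model; a trained multi-hop QA selector or encoder–decoder
summarizer plugs in behind the same interfaces.

**Summarizer input assembly.** The first four sentences of each retrieved
paragraph, in retrieval order, accumulating whole sentences while the
running whitespace-token count stays within 512; the first sentence is
always admitted. Summary lengths are bucketed 1–5 at boundaries 64/124/
194/294 tokens (bucket 5 is everything ≥ 295); generation targets bucket 1
(< 65 tokens), since short summaries discriminate better when used as a
matching signal.

## Evaluation conventions

- Grades are 0/1/2; P@N, MAP and Bpref binarize at grade ≥ 1 by default
  (configurable), the usual convention for partially-relevant pools.
- nDCG defaults to the classic discrete form `rel_1 + Σ_{i≥2} rel_i/log2(i)`
  (positions 1 and 2 undiscounted); the trec_eval discount `log2(i+1)` is
  available via `variant="trec"`. IDCG ranks all judged documents for the
  topic; nDCG is defined as 0 when IDCG = 0.
- Bpref defaults to the discrete form with denominator R (the judged-relevant
  count), counting only the first R judged-nonrelevant retrieved documents;
  the trec_eval denominator `min(R, #judged-nonrelevant)` is the
  `variant="trec"` alternative. Topics with R = 0 are excluded from means.
- MAP divides by the total judged-relevant count, so relevant documents a run
  never retrieved still count against it.
- Judged-only rescoring removes unjudged documents per topic and re-ranks the
  survivors contiguously, scores preserved.
- Topics present in qrels but absent from a run score 0 (Bpref excepted as
  above); means are over the topics in the qrels.

## Determinism and tie-breaking

Every ranking in the package breaks score ties by lexicographic doc_id (and
kNN ties by para_id), so equal inputs give byte-identical run files. The
tokenizer is lowercase + split on non-alphanumeric runs, no stemming, no
stopwords — the simplest reproducible analyzer, shared by all three channels
and the stub embedder. Sentences split on `[.?!]` followed by whitespace and
an uppercase letter or digit. A token for the 512/65 length budgets is a
whitespace-delimited word. Citation titles are normalized (casefold +
whitespace collapse) before graph-node identity. Vocabulary truncation keeps
the highest-corpus-frequency terms with lexicographic tie-break.

Degenerate inputs: a corpus whose df filters prune every term disables the
TF-IDF channel (warning) rather than failing — the other channels still
retrieve; a document with no embedded units scores −1 in the dense channel
helper and S = 0 in re-ranking, each with a warning; an empty ranked list
cannot be re-ranked; a citation graph with no edges cannot yield tuples.

## The stub embedder

`HashedProjectionEmbedder` maps each token to a fixed Gaussian direction
(seeded by a stable hash of the token and the embedder seed) and embeds a
text as the normalized sum of its tokens' directions, D = 64 by default.
Shared tokens produce correlated vectors, so topical similarity survives the
projection — enough for the dense channel to separate planted clusters —
while remaining fully deterministic across processes. It captures no word
order, synonymy or compositionality; it is a test vehicle and a contract
reference, not a semantic model.

## Approximate kNN

The approximate mode is an inverted-file (IVF) search: a k-means coarse
quantizer with `nlist = √n` cells, probing the `nprobe` cells nearest the
query and scanning exactly within them. The default `nprobe = nlist/2` is
chosen so the backend meets its documented recall contract (recall@10 ≥ 0.9
versus exact search) even on unstructured near-uniform vectors, where coarse
quantization carries the least information; clustered corpora reach the same
recall with far fewer probes. Exact mode is the default everywhere else.

## Training tuples

Positives are exactly the bipartite-graph edges. Negatives are drawn per
paragraph, uniformly over non-adjacent citation titles, without replacement
while distinct candidates remain and topping up with replacement (with a
warning) when a paragraph has more positives than non-adjacent titles — the
balanced-output guarantee takes precedence over distinctness, since balanced
classes matter more to a downstream trainer than occasional duplicate
negatives. A paragraph adjacent to every title contributes no negatives.
Negative sampling is uniform; hard-negative mining (e.g. same-document
titles) is deliberately not implemented.

## Synthetic corpora

The generator plants T topics, each with a block of topic-specific terms; a
fraction of each block is borrowed by the previous topic (ring adjacency),
creating partial-relevance structure. Documents sample Zipf-distributed
tokens from a mixture of their topic block (weight 0.55) and a shared
background vocabulary; citations stay within topic with probability 0.9.
Qrels grade same-topic documents 2, adjacent-topic documents that contain at
least three of the topic's own terms 1, and a per-topic sample of other
documents 0; coverage can be subsampled to emulate sparse pooled judgments.
Defaults (5 topics × 100 documents, ~2000-term vocabulary) give a
judged-relevant fraction near 0.23 per topic.

What it emulates: topical vocabulary clustering, graded and incomplete
judgments, citation homophily, caption units. What it does not: grammar,
discourse structure, synonymy, polysemy, citation-text mismatch, realistic
document-length and vocabulary distributions. Consequently, passing the
end-to-end recovery tests shows the cascade's plumbing, determinism and
ranking algebra are correct and that it can exploit strong lexical topical
signal — it says nothing about retrieval quality on real scientific prose,
which depends on trained embedders and extractors outside this package's
scope.

## Problem sizes

The test suite and acceptance script are sized for a single CPU: the
end-to-end corpus is 5 topics × 100 documents (≈1,700 paragraph units),
metric oracle checks use 20 random fixtures of up to ~6 topics × 200
documents, and the ANN recall check uses a 5,000-vector store. The whole
suite runs in a few seconds; the acceptance script in under ten.

## Known limitations

- The TF-IDF channel scores only documents with at least one query term in
  the capped vocabulary; recall beyond that relies on the dense and BM25
  channels.
- BM25 postings are kept in memory; no compression or skip lists. The index
  persists as plain JSON, chosen for portability over compactness.
- `Q = 1.1^N` is uncapped, so a document matching many distinct spans can be
  boosted arbitrarily; with the keyword extractor N is bounded by the number
  of long query tokens, but a generative extractor could warrant a cap.
- The summary-match score assumes the summary is embedded with the same
  embedder as the paragraph store (the store's fingerprint records this).
- Whether queries, questions, or both feed the engine is a config choice
  (`field_policy`, default query+question); results depend on it and runs
  record it in their manifest.
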