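import pytest

from fusionsearch.config import PipelineConfig
from fusionsearch.corpus import CitationEntry, Document, Paragraph, Topic
from fusionsearch.synthetic import SynthParams, generate


def make_doc(doc_id: str, para_texts, captions=(), bib=(), cited=()):
    """Small hand-built document; ``cited`` is per-paragraph key tuples."""
    cited = list(cited) + [()] * (len(para_texts) - len(cited))
    return Document(
        doc_id=doc_id,
        title=f"title of {doc_id}",
        abstract=f"abstract of {doc_id}",
        paragraphs=[
            Paragraph(doc_id, i, text, tuple(keys))
            for i, (text, keys) in enumerate(zip(para_texts, cited))
        ],
        captions=list(captions),
        bibliography=[CitationEntry(k, t) for k, t in bib],
    )


@pytest.fixture
def tiny_corpus():
    """Three documents with citations, captions and shared vocabulary."""
    return [
        make_doc(
            "doc-a",
            ["The spike protein binds the ACE2 receptor. This drives entry.",
             "Antiviral drug repurposing screens identify inhibitors."],
            captions=["Figure of spike protein structure"],
            bib=[("b1", "Receptor binding of coronaviruses"),
                 ("b2", "Drug repurposing for viral disease")],
            cited=[("b1",), ("b2",)],
        ),
        make_doc(
            "doc-b",
            ["Mental health outcomes worsened during lockdown periods."],
            bib=[("b1", "Pandemic stress and anxiety")],
            cited=[("b1",)],
        ),
        make_doc(
            "doc-c",
            ["Vaccine trials report efficacy. Spike antigens are common targets.",
             "Cold chain logistics constrain vaccine distribution."],
        ),
    ]


@pytest.fixture(scope="session")
def small_synth():
    """A small planted-cluster corpus shared across test modules."""
    params = SynthParams(n_topics=3, docs_per_topic=20, seed=7)
    docs, topics, qrels = generate(params)
    return params, docs, topics, qrels


@pytest.fixture(scope="session")
def small_config():
    # min_df relaxed for the small corpus; every other constant at default
    return PipelineConfig(tfidf_min_df=2, seed=7)


@pytest.fixture
def sample_topic():
    return Topic(
        topic_id=1,
        query="coronavirus drug repurposing",
        question=("which SARS-CoV-2 proteins-human proteins interactions "
                  "indicate potential for drug targets"),
        narrative="protein-protein interactions for structural proteins",
    )
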