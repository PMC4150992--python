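"""Shared fixtures: a small synthetic study environment and hand-built pieces."""

from __future__ import annotations

import pytest

from litgo.corpus_io import Article, GeneRef, Ontology, Sentence, TermRecord
from litgo.synthetic_fixtures import Fixture, FixtureSpec, make_fixture


@pytest.fixture(scope="session")
def small_spec() -> FixtureSpec:
    """Scaled-down study conditions for fast unit/property tests."""
    return FixtureSpec(
        seed=7,
        n_articles=30,
        n_genes=12,
        n_go_terms=13,
        vocab_size=120,
        n_reference_docs=60,
        n_generif=400,
    )


@pytest.fixture(scope="session")
def small_fixture(small_spec) -> Fixture:
    return make_fixture(small_spec)


@pytest.fixture(scope="session")
def default_fixture() -> Fixture:
    """The generator's default study conditions (seed 7, 200 articles)."""
    return make_fixture(FixtureSpec())


@pytest.fixture()
def chain_ontology() -> Ontology:
    """Three-term is_a chain: root -> a -> b."""
    terms = {
        "GO:0000001": TermRecord(name="root", synonyms=(), parents=()),
        "GO:0000002": TermRecord(name="mid a", synonyms=(), parents=("GO:0000001",)),
        "GO:0000003": TermRecord(name="leaf b", synonyms=(), parents=("GO:0000002",)),
    }
    return Ontology(terms=terms, roots=("GO:0000001",))


SAMPLE_BIOC = """<?xml version="1.0" encoding="UTF-8"?>
<collection>
  <source>test</source>
  <document>
    <id>2178104</id>
    <infon key="gene">cdc-14(173945)</infon>
    <passage>
      <infon key="section-type">ABSTRACT</infon>
      <infon key="gene">cdc-14(173945)</infon>
      <infon key="go-term">phosphatase activity|GO: 0016 791</infon>
      <infon key="goevidence">NONE</infon>
      <offset>0</offset>
      <text>CeCDC-14 is a phosphatase and localizes to the central spindle and the midbody</text>
    </passage>
  </document>
</collection>
"""


@pytest.fixture()
def sample_bioc_path(tmp_path):
    path = tmp_path / "sample.xml"
    path.write_text(SAMPLE_BIOC, encoding="utf-8")
    return path


def build_article(
    doc_id: str,
    rows: list[tuple[str, str]],
    gene_list: list[GeneRef],
) -> Article:
    """Article from (section, text) rows with consecutive offsets."""
    sentences = []
    offset = 0
    for section, text in rows:
        sentences.append(Sentence(text=text, offset=offset, section=section))
        offset += len(text) + 1
    return Article(doc_id=doc_id, sentences=sentences, gene_list=gene_list)


def articles_equal(a: Article, b: Article) -> bool:
    if a.doc_id != b.doc_id or len(a.sentences) != len(b.sentences):
        return False
    if a.gene_list != b.gene_list:
        return False
    for sa, sb in zip(a.sentences, b.sentences):
        if (
            sa.text != sb.text
            or sa.offset != sb.offset
            or sa.section != sb.section
            or sa.gold_genes != sb.gold_genes
            or sa.gold_go_ids != sb.gold_go_ids
            or sa.gold_evidence_code != sb.gold_evidence_code
        ):
            return False
    return True
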