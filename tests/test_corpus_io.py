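"""Format readers/writers: BioC round-trips, gene references, OBO closure,
GeneRIF and annotation tables."""

from __future__ import annotations

from collections import deque

import numpy as np
import pytest

from conftest import articles_equal
from litgo.corpus_io import (
    AnnotationStore,
    BiocParseError,
    FormatError,
    GeneRef,
    OntologyError,
    ancestors,
    load_annotation_store,
    load_ontology,
    normalize_go_id,
    normalize_section,
    parse_gene_ref,
    read_bioc_collection,
    read_generif,
    write_bioc_collection,
    write_bioc_predictions,
)
from litgo.synthetic_fixtures import write_obo


class TestBioc:
    def test_sample_passage_gold_fields(self, sample_bioc_path):
        (article,) = read_bioc_collection(sample_bioc_path)
        assert article.doc_id == "2178104"
        (sentence,) = article.sentences
        assert sentence.text.startswith("CeCDC-14 is a phosphatase")
        assert sentence.length == len(sentence.text)
        assert sentence.section == "ABSTRACT"
        assert sentence.gold_genes == [GeneRef("cdc-14", "173945")]
        assert sentence.gold_go_ids == ["GO:0016791"]
        assert sentence.gold_evidence_code == "NONE"
        assert article.gene_list == [GeneRef("cdc-14", "173945")]

    def test_empty_collection(self, tmp_path):
        path = tmp_path / "empty.xml"
        path.write_text("<collection><source>t</source></collection>")
        assert read_bioc_collection(path) == []

    def test_malformed_xml_raises(self, tmp_path):
        path = tmp_path / "bad.xml"
        path.write_text("<collection><document>")
        with pytest.raises(BiocParseError):
            read_bioc_collection(path)

    def test_passage_without_text_raises(self, tmp_path):
        path = tmp_path / "notext.xml"
        path.write_text(
            "<collection><document><id>d1</id>"
            "<passage><offset>0</offset></passage></document></collection>"
        )
        with pytest.raises(BiocParseError):
            read_bioc_collection(path)

    def test_write_read_round_trip(self, small_fixture, tmp_path):
        path = tmp_path / "corpus.xml"
        write_bioc_collection(small_fixture.articles, path)
        reread = read_bioc_collection(path)
        assert len(reread) == len(small_fixture.articles)
        for a, b in zip(small_fixture.articles, reread):
            assert articles_equal(a, b)

    def test_predictions_round_trip_and_infons(self, small_fixture, tmp_path):
        article = small_fixture.articles[0]
        gene = article.gene_list[0]
        sentence = article.sentences[0]
        path = tmp_path / "pred.xml"
        write_bioc_predictions(
            [article], [(gene, sentence)], [(article.doc_id, gene.gene_id, "GO:0000003")], path
        )
        (reread,) = read_bioc_collection(path)
        assert articles_equal(article, reread)
        from lxml import etree

        tree = etree.parse(str(path))
        assert len(tree.findall(".//infon[@key='a-gene']")) == 1
        assert len(tree.findall(".//infon[@key='b-annotation']")) == 1

    def test_dangling_prediction_rejected(self, small_fixture, tmp_path):
        article = small_fixture.articles[0]
        stray = small_fixture.articles[1].sentences[0]
        with pytest.raises(FormatError):
            write_bioc_predictions(
                [article], [(article.gene_list[0], stray)], [], tmp_path / "x.xml"
            )
        with pytest.raises(FormatError):
            write_bioc_predictions(
                [article], [], [("no-such-doc", "1", "GO:0000003")], tmp_path / "y.xml"
            )


class TestGeneRef:
    @pytest.mark.parametrize(
        ("raw", "symbol", "gene_id"),
        [
            ("cdc-14(173945)", "cdc-14", "173945"),
            ("a(1)", "a", "1"),
            ("abc(2)(173)", "abc(2)", "173"),  # final parenthesized group wins
        ],
    )
    def test_parse(self, raw, symbol, gene_id):
        ref = parse_gene_ref(raw)
        assert (ref.symbol, ref.gene_id) == (symbol, gene_id)
        assert ref.render() == raw

    @pytest.mark.parametrize("raw", ["abc", "abc(", "(1)", "", "abc()"])
    def test_parse_errors(self, raw):
        with pytest.raises(FormatError):
            parse_gene_ref(raw)


class TestNormalization:
    def test_go_id_whitespace_deleted(self):
        assert normalize_go_id("phosphatase activity|GO: 0016 791") == "GO:0016791"
        assert normalize_go_id("GO:0008150") == "GO:0008150"

    def test_section_mapping(self):
        assert normalize_section("introduction") == "INTRO"
        assert normalize_section("Methods") == "METHODS"
        assert normalize_section("acknowledgements") == "OTHER"
        assert normalize_section(None) == "OTHER"


class TestOntology:
    def test_chain_closure(self, chain_ontology):
        assert ancestors(chain_ontology, "GO:0000003") == {
            "GO:0000003", "GO:0000002", "GO:0000001",
        }
        assert ancestors(chain_ontology, "GO:0000001") == {"GO:0000001"}
        assert ancestors(chain_ontology, "GO:0000003", exclude_roots=True) == {
            "GO:0000003", "GO:0000002",
        }

    def test_closure_is_idempotent(self, small_fixture):
        onto = small_fixture.ontology
        for goid in onto.terms:
            closure = onto.ancestors(goid)
            expanded = set()
            for g in closure:
                expanded |= onto.ancestors(g)
            assert expanded == closure

    def test_random_dag_matches_bruteforce_bfs(self):
        rng = np.random.default_rng(11)
        n = 50
        ids = [f"GO:{i:07d}" for i in range(1, n + 1)]
        parents = {ids[0]: []}
        for i in range(1, n):
            k = int(rng.integers(1, 3))
            parents[ids[i]] = list(
                {ids[int(j)] for j in rng.integers(0, i, size=k)}
            )
        obo = ["format-version: 1.2", "ontology: test"]
        for goid in ids:
            obo.append(f"\n[Term]\nid: {goid}\nname: n{goid[-2:]}")
            for p in parents[goid]:
                obo.append(f"is_a: {p}")
        import tempfile, os

        with tempfile.TemporaryDirectory() as d:
            path = os.path.join(d, "dag.obo")
            with open(path, "w") as fh:
                fh.write("\n".join(obo) + "\n")
            onto = load_ontology(path)
        for goid in ids:
            # independent brute-force BFS over the parent lists
            seen = {goid}
            queue = deque([goid])
            while queue:
                cur = queue.popleft()
                for p in parents[cur]:
                    if p not in seen:
                        seen.add(p)
                        queue.append(p)
            assert onto.ancestors(goid) == seen

    def test_cycle_detected(self, tmp_path):
        path = tmp_path / "cycle.obo"
        path.write_text(
            "format-version: 1.2\nontology: test\n\n"
            "[Term]\nid: GO:0000001\nname: a\nis_a: GO:0000002\n\n"
            "[Term]\nid: GO:0000002\nname: b\nis_a: GO:0000001\n"
        )
        with pytest.raises(OntologyError, match="cycle"):
            load_ontology(path)

    def test_fixture_gold_goids_resolve(self, small_fixture):
        onto = small_fixture.ontology
        for article in small_fixture.articles:
            for s in article.sentences:
                for goid in s.gold_go_ids:
                    assert goid in onto.terms
                    assert small_fixture.manifest["ontology"]["root"] in onto.ancestors(goid)

    def test_write_obo_round_trip(self, small_fixture, tmp_path):
        path = tmp_path / "onto.obo"
        write_obo(small_fixture.ontology, path)
        reread = load_ontology(path)
        assert set(reread.terms) == set(small_fixture.ontology.terms)
        for goid, rec in small_fixture.ontology.terms.items():
            got = reread.terms[goid]
            assert got.name == rec.name
            assert got.synonyms == rec.synonyms
            assert got.parents == rec.parents
        assert reread.roots == small_fixture.ontology.roots


class TestGeneRIF:
    def test_taxon_filter(self, tmp_path):
        path = tmp_path / "rif.tsv"
        path.write_text(
            "9606\tG1\tP1\t2024-01-01\talpha text\n"
            "10090\tG2\tP2\t2024-01-01\tbeta text\n"
            "9606\tG3\tP3\t2024-01-01\tgamma text\n"
        )
        human = read_generif(path, taxon_filter=9606)
        assert [r.gene_id for r in human] == ["G1", "G3"]
        assert len(read_generif(path)) == 3
        assert human[0].text == "alpha text"

    def test_short_rows_skipped(self, tmp_path):
        path = tmp_path / "rif.tsv"
        path.write_text("9606\tG1\tP1\ttext only four cols\nbadrow\n")
        records = read_generif(path)
        assert len(records) == 1
        assert records[0].text == "text only four cols"

    def test_fixture_round_trip_matches_manifest(self, small_fixture, tmp_path):
        from litgo.synthetic_fixtures import write_fixture_dir

        paths = write_fixture_dir(small_fixture, tmp_path / "fx")
        records = read_generif(paths["generif"])
        assert records == small_fixture.generif


class TestAnnotationStore:
    def test_pmid_projection(self, tmp_path):
        gg = tmp_path / "gg.tsv"
        gg.write_text("G1\tS1\n")
        tri = tmp_path / "tri.tsv"
        tri.write_text("S1\tGO:1\tP1\nS1\tGO:2\tP1\nS1\tGO:1\tP1\n")
        store = load_annotation_store(gg, tri)
        assert store.pmid_to_goids == {"P1": {"GO:1", "GO:2"}}
        assert len(store.goslim_go_pmid) == 2  # duplicate row deduplicated
        assert store.gene_to_goslim == {"G1": {"S1"}}

    def test_empty_files(self, tmp_path):
        gg = tmp_path / "gg.tsv"
        gg.write_text("")
        tri = tmp_path / "tri.tsv"
        tri.write_text("")
        store = load_annotation_store(gg, tri)
        assert store.gene_to_goslim == {}
        assert store.pmid_to_goids == {}

    def test_arity_error_names_line(self, tmp_path):
        gg = tmp_path / "gg.tsv"
        gg.write_text("G1\tS1\nG2\tS2\textra\n")
        tri = tmp_path / "tri.tsv"
        tri.write_text("")
        with pytest.raises(FormatError, match=":2"):
            load_annotation_store(gg, tri)

    def test_fixture_store_round_trip(self, small_fixture, tmp_path):
        from litgo.synthetic_fixtures import write_fixture_dir

        paths = write_fixture_dir(small_fixture, tmp_path / "fx")
        store = load_annotation_store(
            paths["gene_goslim"], paths["goslim_go_pmid"], paths["sentence_goid"]
        )
        assert store.gene_to_goslim == small_fixture.store.gene_to_goslim
        assert store.goslim_go_pmid == small_fixture.store.goslim_go_pmid
        assert store.sentence_goid_pairs == small_fixture.store.sentence_goid_pairs


def test_goa_pmids_is_triplet_projection():
    store = AnnotationStore(
        gene_to_goslim={},
        goslim_go_pmid={("S1", "G1", "P1"), ("S2", "G2", "P2")},
        sentence_goid_pairs=[],
    )
    assert store.goa_pmids == {"P1", "P2"}
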