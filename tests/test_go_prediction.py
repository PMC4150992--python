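"""GOID scoring/aggregation for the three assignment systems."""

from __future__ import annotations

import pytest

from litgo import pipeline
from litgo.corpus_io import Ontology, TermRecord
from litgo.go_prediction import (
    B1Params,
    B2Params,
    B3Params,
    ConfigurationError,
    BResources,
    b1_aggregate_article,
    b1_score_goes,
    b2_aggregate_gene,
    b2_select_goids,
    b3_jaccard_match,
    run_system,
)
from litgo.retrieval import ScoredDocument
from litgo.textfeat import tokenize_stem


class TestB1Scoring:
    def test_single_doc_full_weight(self):
        ranked = [ScoredDocument("P1", -3.0)]
        out = b1_score_goes(ranked, {"P1": {"GO:2", "GO:1"}}, k=7, m=10)
        assert out == [("GO:1", 1.0), ("GO:2", 1.0)]

    def test_equal_score_docs_split_weight(self):
        ranked = [ScoredDocument("P1", -2.0), ScoredDocument("P2", -2.0)]
        out = b1_score_goes(
            ranked, {"P1": {"GO:1"}, "P2": {"GO:1", "GO:2"}}, k=7, m=10
        )
        assert out[0] == ("GO:1", pytest.approx(1.0))
        assert out[1] == ("GO:2", pytest.approx(0.5))

    def test_m_truncates(self):
        ranked = [ScoredDocument("P1", 0.0)]
        out = b1_score_goes(ranked, {"P1": {"GO:1", "GO:2", "GO:3"}}, k=7, m=2)
        assert len(out) == 2

    def test_empty_ranking(self):
        assert b1_score_goes([], {}, k=7, m=10) == []

    def test_weight_conservation(self):
        ranked = [ScoredDocument(f"P{i}", -float(i)) for i in range(5)]
        annotations = {f"P{i}": {f"GO:{i}", "GO:shared"} for i in range(5)}
        out = dict(b1_score_goes(ranked, annotations, k=5, m=100))
        # every doc contributes weight to exactly 2 GOIDs; totals sum to 2
        assert sum(out.values()) == pytest.approx(2.0)


class TestB1Aggregation:
    def test_strict_cutoff_boundary(self):
        lists = [["GO:1"]] * 5 + [["GO:2"]] * 4
        assert b1_aggregate_article(lists, p=4) == ["GO:1"]  # 5 > 4 kept, 4 dropped

    def test_counts_once_per_goes(self):
        lists = [["GO:1", "GO:1", "GO:1"], ["GO:1"]]
        assert b1_aggregate_article(lists, p=1) == ["GO:1"]
        assert b1_aggregate_article(lists, p=2) == []

    def test_few_goes_cannot_pass_cutoff(self):
        lists = [["GO:1", "GO:2"]] * 4  # only 4 lists, p=4 needs >4
        assert b1_aggregate_article(lists, p=4) == []

    def test_ranking_by_count_then_goid(self):
        lists = [["GO:2", "GO:1"], ["GO:2", "GO:1"], ["GO:2"]]
        assert b1_aggregate_article(lists, p=1) == ["GO:2", "GO:1"]


class TestB2Selection:
    def test_hand_walk(self):
        ranked = [
            ScoredDocument("s1", -4.00),
            ScoredDocument("s2", -4.05),
            ScoredDocument("s3", -4.30),
        ]
        goids = {"s1": {"GO:1"}, "s2": {"GO:2"}, "s3": {"GO:3"}}
        out = b2_select_goids(ranked, goids, k=5, h=0.1)
        assert out == ["GO:1", "GO:2"]  # gaps 0 and 0.05 pass; 0.30 stops

    def test_all_equal_scores_selects_topk(self):
        ranked = [ScoredDocument(f"s{i}", -1.0) for i in range(8)]
        goids = {f"s{i}": {f"GO:{i}"} for i in range(8)}
        assert len(b2_select_goids(ranked, goids, k=5, h=0.1)) == 5

    def test_empty_ranking(self):
        assert b2_select_goids([], {}, k=5, h=0.1) == []

    def test_output_is_prefix_of_topk_list(self):
        ranked = [ScoredDocument(f"s{i}", -0.07 * i) for i in range(10)]
        goids = {f"s{i}": {f"GO:{i:02d}"} for i in range(10)}
        full = [f"GO:{i:02d}" for i in range(5)]
        out = b2_select_goids(ranked, goids, k=5, h=0.1)
        assert out == full[: len(out)]

    def test_goid_inherits_best_sentence_score(self):
        ranked = [
            ScoredDocument("s1", -1.0),
            ScoredDocument("s2", -1.05),
            ScoredDocument("s3", -5.0),  # same GOID as s1, ignored as duplicate
        ]
        goids = {"s1": {"GO:1"}, "s2": {"GO:2"}, "s3": {"GO:1"}}
        assert b2_select_goids(ranked, goids, k=5, h=0.1) == ["GO:1", "GO:2"]


class TestB2Aggregation:
    def test_frequency_ranking(self):
        sels = [["GO:1"], ["GO:1", "GO:2"], ["GO:1"]]
        assert b2_aggregate_gene(sels, m=3) == ["GO:1", "GO:2"]

    def test_length_bounded_by_m(self):
        sels = [[f"GO:{i}" for i in range(10)]]
        assert len(b2_aggregate_gene(sels, m=3)) == 3


@pytest.fixture()
def tiny_ontology():
    terms = {
        "GO:0000001": TermRecord(name="root", synonyms=(), parents=()),
        "GO:0016791": TermRecord(
            name="phosphatase activity", synonyms=("phosphatases",),
            parents=("GO:0000001",),
        ),
        "GO:0000010": TermRecord(
            name="alpha beta gamma delta epsilon zeta eta", synonyms=(),
            parents=("GO:0000001",),
        ),
    }
    return Ontology(terms=terms, roots=("GO:0000001",))


class TestB3Jaccard:
    def test_exact_name_match_assigned(self, tiny_ontology):
        out = b3_jaccard_match(
            "the enzyme shows phosphatase activity in vitro", tiny_ontology
        )
        assert [(a.goid, a.score) for a in out if a.goid == "GO:0016791"] == [
            ("GO:0016791", 1.0)
        ]

    def test_three_of_seven_overlap_rejected(self, tiny_ontology):
        out = b3_jaccard_match("alpha beta gamma observed", tiny_ontology)
        assert all(a.goid != "GO:0000010" for a in out)  # 3/7 < 0.75

    def test_self_match_at_threshold_one(self, tiny_ontology):
        for goid, rec in tiny_ontology.terms.items():
            out = b3_jaccard_match(rec.name, tiny_ontology, B3Params(threshold=1.0))
            assert goid in {a.goid for a in out}

    def test_distance_mode(self, tiny_ontology):
        out = b3_jaccard_match(
            "alpha beta gamma observed",
            tiny_ontology,
            B3Params(threshold=0.75, mode="distance"),
        )
        # distance 1 - 3/7 = 0.571 <= 0.75 -> accepted in distance mode
        assert "GO:0000010" in {a.goid for a in out}

    def test_matches_bruteforce_overlap_scan(self, small_fixture):
        import numpy as np

        onto = small_fixture.ontology
        rng = np.random.default_rng(6)
        sentences = [s for a in small_fixture.articles[:10] for s in a.sentences]
        for _ in range(200):
            s = sentences[int(rng.integers(len(sentences)))]
            stems = set(tokenize_stem(s.text))
            expected = set()
            for goid, rec in onto.terms.items():
                best = 0.0
                for label in (rec.name, *rec.synonyms):
                    T = set(tokenize_stem(label))
                    if T:
                        best = max(best, len(stems & T) / len(T))
                if best >= 0.75 and best > 0:
                    expected.add(goid)
            got = {a.goid for a in b3_jaccard_match(s, onto)}
            assert got == expected


@pytest.fixture(scope="module")
def b_setup(small_fixture):
    resources = pipeline.build_b_resources(
        small_fixture.ontology, small_fixture.store, small_fixture.reference_docs
    )
    articles = small_fixture.articles[:10]
    pairs = pipeline.gold_goes_pairs(articles)
    return articles, pairs, resources


class TestMonotonicity:
    """Tightening any system's selectivity parameter never adds assignments."""

    def test_b1_p(self, b_setup):
        articles, pairs, resources = b_setup
        n = [
            len(run_system(articles, pairs, resources, "B1", B1Params(p=p)))
            for p in (1, 2, 3)
        ]
        assert n[0] >= n[1] >= n[2]

    def test_b2_h(self, b_setup):
        articles, pairs, resources = b_setup
        n = [
            len(run_system(articles, pairs, resources, "B2", B2Params(h=h)))
            for h in (1.0, 0.1, 1e-9)
        ]
        assert n[0] >= n[1] >= n[2]

    def test_b3_threshold(self, b_setup):
        articles, pairs, resources = b_setup
        n = [
            len(run_system(articles, pairs, resources, "B3", B3Params(threshold=t)))
            for t in (0.5, 0.75, 1.0)
        ]
        assert n[0] >= n[1] >= n[2]


class TestRunSystem:
    def test_zero_pairs_zero_assignments(self, small_fixture):
        resources = pipeline.build_b_resources(
            small_fixture.ontology, small_fixture.store, small_fixture.reference_docs
        )
        for system in ("B1", "B2", "B3"):
            assert run_system(small_fixture.articles[:2], [], resources, system) == []

    def test_missing_resources_raise(self, small_fixture):
        empty = BResources()
        pairs = pipeline.gold_goes_pairs(small_fixture.articles[:2])
        for system in ("B1", "B2", "B3"):
            with pytest.raises(ConfigurationError):
                run_system(small_fixture.articles[:2], pairs, empty, system)
        with pytest.raises(ConfigurationError):
            run_system(small_fixture.articles[:2], pairs, empty, "B9")

    def test_assigned_genes_belong_to_article(self, small_fixture):
        resources = pipeline.build_b_resources(
            small_fixture.ontology, small_fixture.store, small_fixture.reference_docs
        )
        articles = small_fixture.articles[:10]
        pairs = pipeline.gold_goes_pairs(articles)
        by_doc = {a.doc_id: {g.gene_id for g in a.gene_list} for a in articles}
        for system, params in (
            ("B1", B1Params(p=1)), ("B2", B2Params()), ("B3", B3Params()),
        ):
            for doc_id, assignment in run_system(articles, pairs, resources, system, params):
                assert assignment.gene.gene_id in by_doc[doc_id]
                assert assignment.goid in small_fixture.ontology.terms
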