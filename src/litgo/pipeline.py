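"""End-to-end orchestration shared by the CLI, the examples and the
acceptance script: train/predict for subtask A, resource assembly and
system runs for subtask B, and gold-standard extraction for both."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus_io import AnnotationStore, Article, GeneRef, Ontology, Sentence
from .evaluation import EvalResult, eval_task_a, eval_task_b_flat, eval_task_b_hierarchical
from .gene_assembly import GeneSentencePair, assemble_pairs
from .go_prediction import BResources, GOAssignment, run_system
from .goes_model import GoesClassifier, is_gold_goes, train_goes_classifier
from .retrieval import DirichletParams, build_index
from .textfeat import load_stopwords

__all__ = [
    "split_articles", "gold_task_a_items", "gold_task_b_items", "gold_goes_pairs",
    "predict_task_a", "task_a_metrics", "build_b_resources", "predict_task_b",
    "task_b_metrics", "assignments_to_items",
]


def split_articles(
    articles: list[Article], train_fraction: float = 0.7, seed: int = 0
) -> tuple[list[Article], list[Article]]:
    """Deterministic train/test split of an article collection."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(articles))
    n_train = int(round(train_fraction * len(articles)))
    train = [articles[i] for i in sorted(order[:n_train])]
    test = [articles[i] for i in sorted(order[n_train:])]
    return train, test


def gold_task_a_items(articles: list[Article]) -> set[tuple[str, str, tuple[int, int]]]:
    return {
        (a.doc_id, g.gene_id, s.span)
        for a in articles
        for s in a.sentences
        for g in s.gold_genes
    }


def gold_task_b_items(articles: list[Article]) -> set[tuple[str, str, str]]:
    out = set()
    for a in articles:
        for s in a.sentences:
            for g in s.gold_genes:
                for goid in s.gold_go_ids:
                    out.add((a.doc_id, g.gene_id, goid))
    return out


def gold_goes_pairs(articles: list[Article]) -> list[tuple[str, GeneRef, Sentence]]:
    """Gold (doc, gene, evidence sentence) triples, e.g. to feed subtask B."""
    return [
        (a.doc_id, g, s)
        for a in articles
        for s in a.sentences
        if is_gold_goes(s)
        for g in s.gold_genes
    ]


def predict_task_a(
    classifier: GoesClassifier, articles: list[Article]
) -> list[tuple[str, GeneSentencePair]]:
    """Classify sentences and assemble gene–sentence pairs per article."""
    out: list[tuple[str, GeneSentencePair]] = []
    for article in articles:
        scored = classifier.predict_article(article)
        probabilities = {s: p for s, p, _pos in scored}
        positives = [s for s, _p, pos in scored if pos]
        for pair in assemble_pairs(article, positives, probabilities):
            out.append((article.doc_id, pair))
    return out


def task_a_metrics(
    predictions: list[tuple[str, GeneSentencePair]], articles: list[Article]
) -> dict[str, EvalResult]:
    pred_items = {
        (doc_id, pair.gene.gene_id, pair.sentence.span)
        for doc_id, pair in predictions
    }
    gold = gold_task_a_items(articles)
    return {
        "exact": eval_task_a(pred_items, gold, mode="exact"),
        "overlap": eval_task_a(pred_items, gold, mode="overlap"),
    }


def build_b_resources(
    ontology: Ontology,
    store: AnnotationStore,
    reference_docs: dict[str, str] | None = None,
    mu: float = 2500.0,
) -> BResources:
    """Index the reference collections and bundle everything the systems need."""
    sentence_goids: dict[str, set[str]] = {}
    sentence_docs: dict[str, str] = {}
    for i, (text, goid) in enumerate(store.sentence_goid_pairs):
        sid = f"S{i:06d}"
        sentence_docs[sid] = text
        sentence_goids.setdefault(sid, set()).add(goid)
    return BResources(
        ontology=ontology,
        store=store,
        doc_index=build_index(reference_docs) if reference_docs else None,
        sentence_index=build_index(sentence_docs) if sentence_docs else None,
        sentence_goids=sentence_goids,
        stoplist=load_stopwords(),
        dirichlet=DirichletParams(mu=mu),
    )


def predict_task_b(
    articles: list[Article],
    goes_pairs: list[tuple[str, GeneRef, Sentence]],
    resources: BResources,
    system: str,
    params=None,
) -> list[tuple[str, GOAssignment]]:
    return run_system(articles, goes_pairs, resources, system, params)


def assignments_to_items(
    assignments: list[tuple[str, GOAssignment]]
) -> set[tuple[str, str, str]]:
    return {(doc_id, a.gene.gene_id, a.goid) for doc_id, a in assignments}


def task_b_metrics(
    assignments: list[tuple[str, GOAssignment]],
    articles: list[Article],
    ontology: Ontology,
) -> dict[str, EvalResult]:
    pred = assignments_to_items(assignments)
    gold = gold_task_b_items(articles)
    return {
        "flat": eval_task_b_flat(pred, gold),
        "hierarchical": eval_task_b_hierarchical(pred, gold, ontology),
    }
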