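"""Inverted index and Dirichlet-smoothed query-likelihood retrieval.

A document D is scored for query Q = q_1..q_n by

    score(D, Q) = sum_i ln( (tf_{qi,D} + mu * tf_{qi,C} / |C|) / (|D| + mu) )

where tf_{.,D} and tf_{.,C} are document and collection term frequencies,
|D| and |C| the document and collection lengths in tokens, and mu the
Dirichlet smoothing parameter.  Natural logarithms throughout — ranking is
base-invariant but downstream score-gap thresholds are not, so the base is
fixed and documented.  Query terms with zero collection frequency are
dropped before scoring; a query empty after that is a no-score signal.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

from .corpus_io import AnnotationStore, GeneRef, Sentence
from .textfeat import remove_stopwords, tokenize_stem

__all__ = [
    "InvertedIndex", "DirichletParams", "ScoredDocument", "build_index",
    "dirichlet_score", "formulate_query", "build_candidate_pmids", "search",
]

Query = list[str]


@dataclass
class DirichletParams:
    """Dirichlet smoothing parameter mu (> 0); 2500 is a conventional default."""

    mu: float = 2500.0

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be positive")


class ScoredDocument(NamedTuple):
    doc_id: str
    score: float


@dataclass
class InvertedIndex:
    """Term statistics supporting query-likelihood scoring."""

    postings: dict[str, dict[str, int]] = field(default_factory=dict)
    doc_len: dict[str, int] = field(default_factory=dict)
    collection_len: int = 0
    collection_tf: dict[str, int] = field(default_factory=dict)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "format": "litgo-index-v1",
                    "postings": self.postings,
                    "doc_len": self.doc_len,
                    "collection_len": self.collection_len,
                    "collection_tf": self.collection_tf,
                },
                fh,
            )

    @classmethod
    def load(cls, path) -> "InvertedIndex":
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        if data.get("format") != "litgo-index-v1":
            raise ValueError(f"unsupported index file {path}")
        return cls(
            postings=data["postings"],
            doc_len=data["doc_len"],
            collection_len=data["collection_len"],
            collection_tf=data["collection_tf"],
        )


def build_index(docs: Mapping[str, str]) -> InvertedIndex:
    """Index a doc_id → text mapping with the shared stemming tokenizer."""
    index = InvertedIndex()
    for doc_id, text in docs.items():
        tokens = tokenize_stem(text)
        index.doc_len[doc_id] = len(tokens)
        index.collection_len += len(tokens)
        for t in tokens:
            index.postings.setdefault(t, {})
            index.postings[t][doc_id] = index.postings[t].get(doc_id, 0) + 1
            index.collection_tf[t] = index.collection_tf.get(t, 0) + 1
    return index


def dirichlet_score(
    query: Query,
    doc_id: str,
    index: InvertedIndex,
    params: DirichletParams | None = None,
) -> float | None:
    """Query-likelihood log score; None when no query term is in the collection."""
    params = params or DirichletParams()
    if doc_id not in index.doc_len:
        raise KeyError(f"unknown document {doc_id!r}")
    terms = [t for t in query if index.collection_tf.get(t, 0) > 0]
    if not terms:
        return None
    mu = params.mu
    dlen = index.doc_len[doc_id]
    clen = index.collection_len
    score = 0.0
    for t in terms:
        tf_d = index.postings.get(t, {}).get(doc_id, 0)
        tf_c = index.collection_tf[t]
        score += math.log((tf_d + mu * tf_c / clen) / (dlen + mu))
    return score


def formulate_query(
    goes_sentence: Sentence | str, stoplist: frozenset[str] | set[str]
) -> Query:
    """Stem the evidence sentence and drop stopwords; duplicates are kept."""
    text = goes_sentence.text if isinstance(goes_sentence, Sentence) else goes_sentence
    return remove_stopwords(tokenize_stem(text), stoplist)


def build_candidate_pmids(gene: GeneRef, store: AnnotationStore) -> set[str]:
    """The reduced PMID search list for a gene via its GO-Slim categories."""
    slims = store.gene_to_goslim.get(gene.gene_id, set())
    return {
        pmid for slim, _goid, pmid in store.goslim_go_pmid if slim in slims
    }


def search(
    query: Query,
    index: InvertedIndex,
    restrict_to: Iterable[str] | None = None,
    top_k: int = 10,
    params: DirichletParams | None = None,
) -> list[ScoredDocument]:
    """Rank documents by query likelihood, descending; ties by doc_id ascending."""
    if top_k < 1:
        raise ValueError("top_k must be at least 1")
    if restrict_to is None:
        candidates = index.doc_len.keys()
    else:
        candidates = [d for d in restrict_to if d in index.doc_len]
    scored = []
    for doc_id in candidates:
        s = dirichlet_score(query, doc_id, index, params)
        if s is not None:
            scored.append(ScoredDocument(doc_id, s))
    scored.sort(key=lambda sd: (-sd.score, sd.doc_id))
    return scored[:top_k]
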