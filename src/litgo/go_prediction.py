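"""Three GO-term assignment systems over detected evidence sentences.

* **B1** — retrieve annotated reference documents for each evidence
  sentence (restricted to the gene's GO-Slim candidate PMID list), weight
  each retrieved document's GOIDs by a softmax of the retrieval scores,
  keep the top *m* GOIDs per sentence, then keep GOIDs occurring in more
  than *p* of the gene's sentences.  Defaults ⟨k, m, p⟩ = ⟨7, 10, 4⟩.
* **B2** — retrieve annotated GeneRIF sentences, convert the ranking to a
  GOID list, truncate it where the log-score gap to the top exceeds *h*,
  and keep the *m* most frequent GOIDs per gene.  Defaults ⟨k, h, m⟩ =
  ⟨5, 0.1, 3⟩.
* **B3** — dictionary matching: assign a GO term when the fraction of its
  name/synonym word stems found in the sentence (a Jaccard overlap, since
  the matched set is contained in the term's word set) reaches 0.75.

All ties break by GOID ascending for determinism.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from math import exp

from .corpus_io import AnnotationStore, Article, GeneRef, Ontology, Sentence
from .retrieval import (
    DirichletParams,
    InvertedIndex,
    ScoredDocument,
    build_candidate_pmids,
    formulate_query,
    search,
)
from .textfeat import tokenize_stem

__all__ = [
    "B1Params", "B2Params", "B3Params", "GOAssignment", "BResources",
    "ConfigurationError", "b1_score_goes", "b1_aggregate_article",
    "b2_select_goids", "b2_aggregate_gene", "b3_jaccard_match", "run_system",
]


class ConfigurationError(ValueError):
    """A system was invoked without the resources it needs."""


@dataclass
class B1Params:
    k: int = 7   # top documents per evidence sentence
    m: int = 10  # top GOIDs per evidence sentence
    p: int = 4   # occurrence cutoff (keep GOIDs occurring in > p sentences)

    def __post_init__(self) -> None:
        if min(self.k, self.m, self.p) < 1:
            raise ValueError("B1 parameters must all be >= 1")


@dataclass
class B2Params:
    k: int = 5     # initial GOID list size
    h: float = 0.1  # log-score gap threshold
    m: int = 3     # top GOIDs per gene

    def __post_init__(self) -> None:
        if self.k < 1 or self.m < 1 or self.h <= 0:
            raise ValueError("invalid B2 parameters")


@dataclass
class B3Params:
    threshold: float = 0.75
    # "similarity": assign iff overlap >= threshold (default);
    # "distance":  assign iff 1 - overlap <= threshold.
    mode: str = "similarity"

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold <= 1.0:
            raise ValueError("threshold must lie in (0, 1]")
        if self.mode not in ("similarity", "distance"):
            raise ValueError("mode must be 'similarity' or 'distance'")


@dataclass(frozen=True)
class GOAssignment:
    gene: GeneRef | None
    goid: str
    score: float
    system: str  # B1 | B2 | B3


def b1_score_goes(
    ranked_docs: list[ScoredDocument],
    pmid_to_goids: dict[str, set[str]],
    k: int,
    m: int,
) -> list[tuple[str, float]]:
    """Weight the GOIDs of the top-k documents and keep the top m.

    Document weights are exponentiated max-shifted retrieval scores
    normalized to sum one (a softmax), so they are positive and monotone
    in the score; each GOID of a document accrues its full weight.
    """
    top = ranked_docs[:k]
    if not top:
        return []
    max_score = max(sd.score for sd in top)
    raw = [exp(sd.score - max_score) for sd in top]
    total = sum(raw)
    weights: dict[str, float] = {}
    for sd, w in zip(top, raw):
        for goid in pmid_to_goids.get(sd.doc_id, ()):
            weights[goid] = weights.get(goid, 0.0) + w / total
    ranked = sorted(weights.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:m]


def b1_aggregate_article(per_goes_lists: list[list[str]], p: int) -> list[str]:
    """Keep GOIDs present in strictly more than p of the per-sentence lists."""
    counts = Counter()
    for goids in per_goes_lists:
        counts.update(set(goids))
    kept = [(goid, c) for goid, c in counts.items() if c > p]
    kept.sort(key=lambda kv: (-kv[1], kv[0]))
    return [goid for goid, _c in kept]


def b2_select_goids(
    ranked_sentences: list[ScoredDocument],
    sentence_goids: dict[str, set[str] | str],
    k: int,
    h: float,
) -> list[str]:
    """Walk the top-k GOID list from the top while the score gap stays <= h.

    The sentence ranking is converted to a GOID ranking (a GOID inherits
    the score of its best-ranked sentence); selection stops at the first
    GOID whose gap to the topmost exceeds h, so the output is always a
    prefix of the top-k list.
    """
    goid_list: list[tuple[str, float]] = []
    seen: set[str] = set()
    for sd in ranked_sentences:
        goids = sentence_goids.get(sd.doc_id, ())
        if isinstance(goids, str):
            goids = (goids,)
        for goid in sorted(goids):
            if goid not in seen:
                seen.add(goid)
                goid_list.append((goid, sd.score))
    goid_list = goid_list[:k]
    if not goid_list:
        return []
    top_score = goid_list[0][1]
    selected: list[str] = []
    for goid, score in goid_list:
        if top_score - score > h:
            break
        selected.append(goid)
    return selected


def b2_aggregate_gene(per_goes_selections: list[list[str]], m: int) -> list[str]:
    """Rank GOIDs by frequency across a gene's selections; keep the top m."""
    counts = Counter()
    for sel in per_goes_selections:
        counts.update(sel)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [goid for goid, _c in ranked[:m]]


def b3_jaccard_match(
    sentence: Sentence | str,
    ontology: Ontology,
    params: B3Params | None = None,
) -> list[GOAssignment]:
    """Assign GO terms whose name/synonym stems overlap the sentence enough.

    For a term word-stem set T and sentence stems S, the matched set is
    M = S ∩ T, and the Jaccard similarity |M ∩ T| / |M ∪ T| reduces to
    |M| / |T|.  The best similarity over a term's name and synonyms is the
    assignment score.
    """
    params = params or B3Params()
    text = sentence.text if isinstance(sentence, Sentence) else sentence
    stems = set(tokenize_stem(text))
    out: list[GOAssignment] = []
    for goid in sorted(ontology.terms):
        rec = ontology.terms[goid]
        best = 0.0
        for label in (rec.name, *rec.synonyms):
            T = set(tokenize_stem(label))
            if not T:
                continue
            j = len(stems & T) / len(T)
            best = max(best, j)
        if params.mode == "similarity":
            ok = best >= params.threshold
        else:
            ok = (1.0 - best) <= params.threshold
        if ok and best > 0.0:
            out.append(GOAssignment(gene=None, goid=goid, score=best, system="B3"))
    out.sort(key=lambda a: (-a.score, a.goid))
    return out


@dataclass
class BResources:
    """Everything the three systems may need, loaded once."""

    ontology: Ontology | None = None
    store: AnnotationStore | None = None
    doc_index: InvertedIndex | None = None       # B1: reference documents
    sentence_index: InvertedIndex | None = None  # B2: annotated sentences
    sentence_goids: dict[str, set[str]] = field(default_factory=dict)
    stoplist: frozenset[str] = frozenset()
    dirichlet: DirichletParams = field(default_factory=DirichletParams)
    fallback_unrestricted: bool = True  # empty candidate list -> whole collection


GoesPair = tuple[str, GeneRef, Sentence]  # (doc_id, gene, evidence sentence)


def _group_pairs(goes_pairs: list[GoesPair]) -> dict[tuple[str, str], list[GoesPair]]:
    grouped: dict[tuple[str, str], list[GoesPair]] = {}
    for doc_id, gene, sentence in goes_pairs:
        grouped.setdefault((doc_id, gene.gene_id), []).append((doc_id, gene, sentence))
    return grouped


def run_system(
    articles: list[Article],
    goes_pairs: list[GoesPair],
    resources: BResources,
    system: str,
    params: B1Params | B2Params | B3Params | None = None,
) -> list[tuple[str, GOAssignment]]:
    """Run one assignment system; returns (doc_id, assignment) records.

    Assignments are aggregated per (article, gene) — the unit the flat and
    hierarchical metrics are defined on.
    """
    system = system.upper()
    if system == "B1":
        params = params or B1Params()
        if resources.doc_index is None or resources.store is None:
            raise ConfigurationError("B1 requires a document index and annotation store")
        return _run_b1(goes_pairs, resources, params)
    if system == "B2":
        params = params or B2Params()
        if resources.sentence_index is None or not resources.sentence_goids:
            raise ConfigurationError(
                "B2 requires a sentence index and sentence→GOID mapping"
            )
        return _run_b2(goes_pairs, resources, params)
    if system == "B3":
        params = params or B3Params()
        if resources.ontology is None:
            raise ConfigurationError("B3 requires an ontology")
        return _run_b3(goes_pairs, resources, params)
    raise ConfigurationError(f"unknown system {system!r}")


def _run_b1(goes_pairs, resources: BResources, params: B1Params):
    store = resources.store
    pmid_to_goids = store.pmid_to_goids
    out: list[tuple[str, GOAssignment]] = []
    for (doc_id, _gid), pairs in sorted(_group_pairs(goes_pairs).items()):
        gene = pairs[0][1]
        candidates = build_candidate_pmids(gene, store)
        restrict = candidates if candidates else None
        if restrict is None and not resources.fallback_unrestricted:
            continue
        lists: list[list[str]] = []
        for _d, _g, sentence in pairs:
            query = formulate_query(sentence, resources.stoplist)
            ranked = search(
                query, resources.doc_index, restrict_to=restrict,
                top_k=params.k, params=resources.dirichlet,
            )
            lists.append(
                [goid for goid, _w in b1_score_goes(ranked, pmid_to_goids, params.k, params.m)]
            )
        counts = Counter()
        for goids in lists:
            counts.update(set(goids))
        for goid in b1_aggregate_article(lists, params.p):
            out.append(
                (doc_id, GOAssignment(gene=gene, goid=goid, score=float(counts[goid]), system="B1"))
            )
    return out


def _run_b2(goes_pairs, resources: BResources, params: B2Params):
    out: list[tuple[str, GOAssignment]] = []
    fetch = max(50, 10 * params.k)
    for (doc_id, _gid), pairs in sorted(_group_pairs(goes_pairs).items()):
        gene = pairs[0][1]
        selections: list[list[str]] = []
        for _d, _g, sentence in pairs:
            query = formulate_query(sentence, resources.stoplist)
            ranked = search(
                query, resources.sentence_index, top_k=fetch,
                params=resources.dirichlet,
            )
            selections.append(
                b2_select_goids(ranked, resources.sentence_goids, params.k, params.h)
            )
        counts = Counter()
        for sel in selections:
            counts.update(sel)
        for goid in b2_aggregate_gene(selections, params.m):
            out.append(
                (doc_id, GOAssignment(gene=gene, goid=goid, score=float(counts[goid]), system="B2"))
            )
    return out


def _run_b3(goes_pairs, resources: BResources, params: B3Params):
    best: dict[tuple[str, str, str], tuple[GeneRef, float]] = {}
    for doc_id, gene, sentence in goes_pairs:
        for a in b3_jaccard_match(sentence, resources.ontology, params):
            key = (doc_id, gene.gene_id, a.goid)
            if key not in best or a.score > best[key][1]:
                best[key] = (gene, a.score)
    out = [
        (doc_id, GOAssignment(gene=gene, goid=goid, score=score, system="B3"))
        for (doc_id, _gid, goid), (gene, score) in sorted(best.items())
    ]
    return out
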