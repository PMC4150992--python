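"""Greedy association of relevant genes with predicted evidence sentences.

Four steps, applied in order:

1. direct dictionary lookup of gene symbols in the sentence;
2. gene-family mentions (plural forms of a shared symbol stem) assigning
   every family member;
3. proximity — inherit the gene hits of the nearest prior sentence in the
   same section;
4. fallback per still-unassigned gene — the sentence mentioning the gene
   with the largest classifier probability.

Matching is case-insensitive substring by default (the task's gold data
pairs the text "CeCDC-14" with the gene symbol "cdc-14", an embedded
match); a word-boundary-anchored mode is available.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .corpus_io import Article, GeneRef, Sentence

__all__ = [
    "FamilyDictionary", "GeneSentencePair", "match_gene",
    "build_family_dictionary", "step2_family_match", "step3_proximity_assign",
    "step4_fallback_assign", "assemble_pairs",
]

FamilyDictionary = dict[str, frozenset[GeneRef]]


def match_gene(sentence_text: str, gene: GeneRef, anchored: bool = False) -> bool:
    """True iff the gene symbol occurs (case-insensitively) in the text."""
    symbol = gene.symbol.lower()
    text = sentence_text.lower()
    if not anchored:
        return symbol in text
    return re.search(rf"\b{re.escape(symbol)}\b", text) is not None


_FAMILY_SUFFIX = re.compile(r"(?:-\d+|\d+)$")


def family_stem(symbol: str) -> str:
    """Symbol with one trailing digit / hyphen-digit suffix removed, lowercased."""
    return _FAMILY_SUFFIX.sub("", symbol.lower())


def build_family_dictionary(gene_list: list[GeneRef]) -> FamilyDictionary:
    """Group genes sharing a symbol stem; singleton stems are excluded."""
    groups: dict[str, set[GeneRef]] = {}
    for g in gene_list:
        stem = family_stem(g.symbol)
        if stem and stem != g.symbol.lower():
            groups.setdefault(stem, set()).add(g)
    return {
        name: frozenset(members)
        for name, members in groups.items()
        if len(members) >= 2
    }


def step2_family_match(sentence_text: str, family_dict: FamilyDictionary) -> set[GeneRef]:
    """Genes of every family whose name (singular, +s, +es) appears in the text."""
    text = sentence_text.lower()
    hits: set[GeneRef] = set()
    for name, members in family_dict.items():
        if any(form in text for form in (name, name + "s", name + "es")):
            hits.update(members)
    return hits


def _gene_hits(
    sentence_text: str,
    gene_list: list[GeneRef],
    family_dict: FamilyDictionary,
    anchored: bool = False,
) -> set[GeneRef]:
    hits = {g for g in gene_list if match_gene(sentence_text, g, anchored)}
    hits |= step2_family_match(sentence_text, family_dict)
    return hits


def step3_proximity_assign(
    target: Sentence,
    article: Article,
    gene_list: list[GeneRef],
    family_dict: FamilyDictionary,
    anchored: bool = False,
) -> set[GeneRef]:
    """Gene hits of the closest prior same-section sentence with any hit."""
    try:
        idx = next(
            i for i, s in enumerate(article.sentences) if s is target
        )
    except StopIteration:
        raise ValueError("target sentence is not part of the article") from None
    for i in range(idx - 1, -1, -1):
        prior = article.sentences[i]
        if prior.section != target.section:
            continue
        hits = _gene_hits(prior.text, gene_list, family_dict, anchored)
        if hits:
            return hits
    return set()


def step4_fallback_assign(
    gene: GeneRef,
    article: Article,
    probabilities: dict[Sentence, float],
    family_dict: FamilyDictionary | None = None,
    candidates: list[Sentence] | None = None,
    anchored: bool = False,
) -> Sentence | None:
    """The gene-mentioning sentence with the largest positive probability.

    ``candidates`` restricts the pool (e.g. to predicted positives); by
    default every article sentence is considered.  Ties break toward the
    smaller offset.  Returns None when the gene never appears.
    """
    family_dict = family_dict or {}
    pool = candidates if candidates is not None else article.sentences
    families = [
        name for name, members in family_dict.items() if gene in members
    ]
    best: Sentence | None = None
    best_key: tuple[float, int] | None = None
    for s in pool:
        text = s.text.lower()
        mentioned = match_gene(s.text, gene, anchored) or any(
            form in text
            for name in families
            for form in (name, name + "s", name + "es")
        )
        if not mentioned:
            continue
        key = (-probabilities.get(s, 0.0), s.offset)
        if best_key is None or key < best_key:
            best_key = key
            best = s
    return best


@dataclass(frozen=True)
class GeneSentencePair:
    """An assembled (gene, evidence sentence) association with provenance."""

    gene: GeneRef
    sentence: Sentence
    provenance: str  # STEP1 | STEP2 | STEP3 | STEP4
    probability: float


def assemble_pairs(
    article: Article,
    positive_sentences: list[Sentence],
    probabilities: dict[Sentence, float],
    step4_all_sentences: bool = True,
    anchored: bool = False,
) -> list[GeneSentencePair]:
    """Run the four assembly steps over an article's predicted positives.

    Steps 1–3 attach genes to each positive sentence in document order;
    Step 4 then gives every still-unassigned relevant gene its best-scoring
    mentioning sentence (over all sentences by default, positives only when
    ``step4_all_sentences`` is False).  Output is deduplicated on
    (gene, sentence) and sorted by sentence offset then gene id.
    """
    family_dict = build_family_dictionary(article.gene_list)
    pairs: dict[tuple[str, int], GeneSentencePair] = {}

    def add(gene: GeneRef, sentence: Sentence, provenance: str) -> None:
        key = (gene.gene_id, id(sentence))
        if key not in pairs:
            pairs[key] = GeneSentencePair(
                gene=gene,
                sentence=sentence,
                provenance=provenance,
                probability=probabilities.get(sentence, 0.0),
            )

    ordered_positives = sorted(positive_sentences, key=lambda s: s.offset)
    for s in ordered_positives:
        hits1 = {g for g in article.gene_list if match_gene(s.text, g, anchored)}
        hits2 = step2_family_match(s.text, family_dict) - hits1
        for g in hits1:
            add(g, s, "STEP1")
        for g in hits2:
            add(g, s, "STEP2")
        if not hits1 and not hits2:
            for g in step3_proximity_assign(s, article, article.gene_list, family_dict, anchored):
                add(g, s, "STEP3")

    assigned = {p.gene.gene_id for p in pairs.values()}
    candidates = None if step4_all_sentences else ordered_positives
    for gene in article.gene_list:
        if gene.gene_id in assigned:
            continue
        s = step4_fallback_assign(
            gene, article, probabilities, family_dict, candidates, anchored
        )
        if s is not None:
            add(gene, s, "STEP4")

    return sorted(
        pairs.values(), key=lambda p: (p.sentence.offset, p.gene.gene_id)
    )
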