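"""Synthetic study data: everything the pipeline consumes, plus ground truth.

The generator emulates the task's inputs at desk scale: a toy rooted GO
DAG whose leaf terms own disjoint vocabulary blocks, full-text articles
with planted evidence sentences (gene mention + term vocabulary mixed with
background words at ``topic_purity``), per-article relevant-gene lists with
gene families, annotated reference document/sentence collections sharing
vocabulary with their GOIDs, GO-Slim tables wired so candidate-list
reduction works, and a GeneRIF pool containing both GOA-linked and
GOA-free PMIDs to exercise the noisy-negative sampler.

Every generator is a pure function of the spec (all randomness flows from
``spec.seed``); a JSON-serializable manifest records the planted truth.
"""

from __future__ import annotations

import json
import string
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .corpus_io import (
    AnnotationStore,
    Article,
    GeneRef,
    GeneRIFRecord,
    Ontology,
    Sentence,
    TermRecord,
)

__all__ = [
    "FixtureSpec", "Fixture", "make_toy_ontology", "make_corpus",
    "make_reference_resources", "make_fixture", "write_fixture_dir",
    "write_obo",
]

_SECTIONS = ("INTRO", "METHODS", "RESULTS", "DISCUSSION")


@dataclass
class FixtureSpec:
    """Study conditions for the synthetic data (defaults are the conditions
    under which the pipeline's behavior is characterized)."""

    seed: int = 7
    n_articles: int = 200
    sentences_per_article: int = 12
    n_genes: int = 30
    n_go_terms: int = 31          # 1 root + slim layer + leaf terms
    goes_rate: float = 1 / 3      # planted evidence sentences per article
    vocab_size: int = 300         # background vocabulary
    topic_purity: float = 0.8     # P(evidence token drawn from term vocabulary)
    n_reference_docs: int = 120
    n_generif: int = 4000
    genes_per_article: int = 2
    goes_per_annotation: int = 2  # evidence sentences per (gene, GOID) planting
    family_fraction: float = 0.2  # fraction of genes organized in 2-member families
    taxon: int = 9606

    def validate(self) -> None:
        counts = (
            self.n_articles, self.sentences_per_article, self.n_genes,
            self.n_go_terms, self.vocab_size, self.n_reference_docs,
            self.n_generif, self.genes_per_article, self.goes_per_annotation,
        )
        if any(c < 1 for c in counts):
            raise ValueError("all fixture counts must be >= 1")
        if self.n_go_terms < 3:
            raise ValueError("n_go_terms must be >= 3")
        for rate in (self.goes_rate, self.topic_purity):
            if not 0.0 < rate < 1.0:
                raise ValueError("rates must lie in (0, 1)")


def _goid(i: int) -> str:
    return f"GO:{i:07d}"


def _letters(i: int, width: int = 2) -> str:
    out = []
    for _ in range(width):
        out.append(string.ascii_lowercase[i % 26])
        i //= 26
    return "".join(reversed(out))


def _background_vocab(spec: FixtureSpec) -> list[str]:
    return [f"bg{i}x" for i in range(spec.vocab_size)]


def make_toy_ontology(spec: FixtureSpec) -> tuple[Ontology, dict]:
    """A root, a layer of GO-Slim category terms, and annotatable leaves.

    Each leaf owns a six-word vocabulary block (words carry digits so they
    are invariant under stemming); the term name and synonym are drawn
    from that block, which is what makes dictionary matching and retrieval
    recoverable by construction.
    """
    spec.validate()
    rng = np.random.default_rng([spec.seed, 1])
    n_slims = max(1, (spec.n_go_terms - 1) // 3)
    n_leaves = spec.n_go_terms - 1 - n_slims
    if n_leaves < 1:
        n_slims = spec.n_go_terms - 2
        n_leaves = 1
    terms: dict[str, TermRecord] = {}
    root = _goid(1)
    terms[root] = TermRecord(name="biological root", synonyms=(), parents=())
    slims = [_goid(2 + i) for i in range(n_slims)]
    for i, slim in enumerate(slims):
        terms[slim] = TermRecord(
            name=f"slim category {_letters(i)}", synonyms=(), parents=(root,)
        )
    leaves = [_goid(2 + n_slims + i) for i in range(n_leaves)]
    vocab: dict[str, list[str]] = {}
    slim_of: dict[str, str] = {}
    for i, leaf in enumerate(leaves):
        words = [f"t{i:02d}w{j}q" for j in range(6)]
        vocab[leaf] = words
        primary = slims[i % n_slims]
        parents = [primary]
        if n_slims > 1 and rng.random() < 0.1:
            extra = slims[int(rng.integers(n_slims))]
            if extra != primary:
                parents.append(extra)
        slim_of[leaf] = primary
        name = " ".join(words[:2])
        synonym = " ".join(words[2:4])
        terms[leaf] = TermRecord(
            name=name, synonyms=(synonym,), parents=tuple(sorted(parents))
        )
    ontology = Ontology(terms=terms, roots=(root,))
    manifest = {
        "root": root,
        "slims": slims,
        "leaves": leaves,
        "term_vocab": vocab,
        "slim_of": slim_of,
    }
    return ontology, manifest


def _make_genes(spec: FixtureSpec) -> list[GeneRef]:
    genes: list[GeneRef] = []
    n_family_genes = 2 * round(spec.family_fraction * spec.n_genes / 2)
    for f in range(n_family_genes // 2):
        base = f"fm{_letters(f)}"
        for member in (1, 2):
            genes.append(GeneRef(symbol=f"{base}-{member}", gene_id=str(173000 + len(genes))))
    i = 0
    while len(genes) < spec.n_genes:
        genes.append(GeneRef(symbol=f"gx{_letters(i)}", gene_id=str(173000 + len(genes))))
        i += 1
    return genes


def _draw_tokens(
    rng: np.random.Generator,
    n: int,
    term_words: list[str] | None,
    background: list[str],
    purity: float,
) -> list[str]:
    out = []
    for _ in range(n):
        if term_words is not None and rng.random() < purity:
            out.append(term_words[int(rng.integers(len(term_words)))])
        else:
            out.append(background[int(rng.integers(len(background)))])
    return out


def make_corpus(
    spec: FixtureSpec, ontology: Ontology, onto_manifest: dict
) -> tuple[list[Article], dict]:
    """Articles with planted evidence sentences and their truth manifest.

    Each article receives ``genes_per_article`` relevant genes, each
    annotated with one leaf GOID and ``goes_per_annotation`` planted
    evidence sentences.  A quarter of the planted sentences omit the gene
    symbol but are preceded in the same section by a sentence that
    mentions it (exercising proximity assignment); the rest embed the
    symbol, randomly case-mangled (exercising case-insensitive lookup).
    """
    spec.validate()
    rng = np.random.default_rng([spec.seed, 2])
    genes = _make_genes(spec)
    leaves: list[str] = onto_manifest["leaves"]
    vocab: dict[str, list[str]] = onto_manifest["term_vocab"]
    background = _background_vocab(spec)
    n_goes = round(spec.goes_rate * spec.sentences_per_article)

    articles: list[Article] = []
    planted: list[dict] = []
    for a in range(spec.n_articles):
        doc_id = f"100{a:04d}"
        picked_idx = rng.choice(len(genes), size=spec.genes_per_article, replace=False)
        gene_list = [genes[int(i)] for i in picked_idx]
        annotations = [
            (g, leaves[int(rng.integers(len(leaves)))]) for g in gene_list
        ]
        # spread n_goes evidence slots round-robin over the annotations
        slots: list[tuple[GeneRef, str]] = []
        while len(slots) < n_goes:
            slots.extend(annotations)
        slots = slots[:n_goes]

        n_sent = spec.sentences_per_article
        goes_positions = sorted(
            int(i) for i in rng.choice(n_sent, size=len(slots), replace=False)
        )
        block = max(1, n_sent // len(_SECTIONS))
        sections = [
            _SECTIONS[min(i // block, len(_SECTIONS) - 1)] for i in range(n_sent)
        ]

        token_lists: list[list[str]] = [
            _draw_tokens(rng, 10, None, background, 0.0) for _ in range(n_sent)
        ]
        gold: list[tuple[int, GeneRef, str]] = []
        for pos, (gene, goid) in zip(goes_positions, slots):
            tokens = _draw_tokens(rng, 9, vocab[goid], background, spec.topic_purity)
            mention = gene.symbol.upper() if rng.random() < 0.5 else gene.symbol
            hide = rng.random() < 0.25
            prior_same_section = [
                i for i in range(pos) if sections[i] == sections[pos]
            ]
            if hide and prior_same_section:
                # plant the mention in the closest prior same-section sentence
                token_lists[prior_same_section[-1]].insert(0, mention)
            else:
                tokens.insert(int(rng.integers(len(tokens) + 1)), mention)
            token_lists[pos] = tokens
            gold.append((pos, gene, goid))

        sentences: list[Sentence] = []
        offset = 0
        gold_by_pos = {}
        for pos, gene, goid in gold:
            gold_by_pos.setdefault(pos, []).append((gene, goid))
        for i, tokens in enumerate(token_lists):
            text = " ".join(tokens) + "."
            anns = gold_by_pos.get(i, [])
            sentences.append(
                Sentence(
                    text=text,
                    offset=offset,
                    section=sections[i],
                    gold_genes=[g for g, _ in anns],
                    gold_go_ids=[goid for _, goid in anns],
                    gold_evidence_code="IMP" if anns else None,
                )
            )
            offset += len(text) + 1
        article = Article(doc_id=doc_id, sentences=sentences, gene_list=gene_list)
        article.validate()
        articles.append(article)
        for pos, gene, goid in gold:
            planted.append(
                {
                    "doc_id": doc_id,
                    "gene_id": gene.gene_id,
                    "symbol": gene.symbol,
                    "goid": goid,
                    "sentence_index": pos,
                }
            )
    manifest = {
        "genes": [{"symbol": g.symbol, "gene_id": g.gene_id} for g in genes],
        "planted": planted,
    }
    return articles, manifest


def make_reference_resources(
    spec: FixtureSpec, ontology: Ontology, onto_manifest: dict, corpus_manifest: dict
) -> tuple[dict[str, str], AnnotationStore, list[GeneRIFRecord], dict]:
    """Reference docs, annotation tables and a GeneRIF pool, plus manifest.

    Reference documents are generated from the vocabularies of their
    annotated GOIDs; the ⟨GOSlimID, GOID, PMID⟩ triplets are exactly the
    document annotations; gene→GO-Slim rows cover each corpus gene's
    planted GOIDs.  The GeneRIF pool draws from a disjoint gene-id space
    (plus one GOA-free record per corpus gene) with ~30% of PMIDs inside
    the GOA set, so the exclusion rule of the negative sampler bites.
    """
    rng = np.random.default_rng([spec.seed, 3])
    leaves: list[str] = onto_manifest["leaves"]
    vocab: dict[str, list[str]] = onto_manifest["term_vocab"]
    slim_of: dict[str, str] = onto_manifest["slim_of"]
    background = _background_vocab(spec)

    docs: dict[str, str] = {}
    doc_goids: dict[str, list[str]] = {}
    triplets: set[tuple[str, str, str]] = set()
    for i in range(spec.n_reference_docs):
        pmid = f"90{i:05d}"
        goids = [leaves[i % len(leaves)]]
        if rng.random() < 0.1:
            extra = leaves[int(rng.integers(len(leaves)))]
            if extra not in goids:
                goids.append(extra)
        words: list[str] = []
        for goid in goids:
            words.extend(
                _draw_tokens(rng, 40 // len(goids), vocab[goid], background, spec.topic_purity)
            )
        docs[pmid] = " ".join(words)
        doc_goids[pmid] = goids
        for goid in goids:
            triplets.add((slim_of[goid], goid, pmid))

    gene_to_goslim: dict[str, set[str]] = {}
    for row in corpus_manifest["planted"]:
        gene_to_goslim.setdefault(row["gene_id"], set()).add(slim_of[row["goid"]])

    # annotated sentence collection for the sentence-retrieval system
    sentence_goid_pairs: list[tuple[str, str]] = []
    for goid in leaves:
        for _ in range(4):
            tokens = _draw_tokens(rng, 8, vocab[goid], background, spec.topic_purity)
            sentence_goid_pairs.append((" ".join(tokens), goid))

    goa_pmids = {pmid for _s, _g, pmid in triplets}
    goa_list = sorted(goa_pmids)
    generif: list[GeneRIFRecord] = []
    pool_gene = 500000
    fresh = 0
    while len(generif) < spec.n_generif:
        gene_id = str(pool_gene)
        pool_gene += 1
        for _ in range(2):
            if len(generif) >= spec.n_generif:
                break
            taxon = spec.taxon if rng.random() < 0.85 else 10090
            if rng.random() < 0.3:
                pmid = goa_list[int(rng.integers(len(goa_list)))]
            else:
                pmid = f"80{fresh:05d}"
                fresh += 1
            text = " ".join(_draw_tokens(rng, 10, None, background, 0.0))
            generif.append(
                GeneRIFRecord(taxon_id=taxon, gene_id=gene_id, pmid=pmid, text=text)
            )
    for g in corpus_manifest["genes"]:
        pmid = f"80{fresh:05d}"
        fresh += 1
        text = " ".join(_draw_tokens(rng, 10, None, background, 0.0))
        generif.append(
            GeneRIFRecord(
                taxon_id=spec.taxon, gene_id=g["gene_id"], pmid=pmid, text=text
            )
        )

    store = AnnotationStore(
        gene_to_goslim=gene_to_goslim,
        goslim_go_pmid=triplets,
        sentence_goid_pairs=sentence_goid_pairs,
    )
    manifest = {
        "doc_goids": doc_goids,
        "goa_pmids": sorted(goa_pmids),
        "n_generif": len(generif),
    }
    return docs, store, generif, manifest


@dataclass
class Fixture:
    """A fully generated study environment."""

    spec: FixtureSpec
    ontology: Ontology
    articles: list[Article]
    reference_docs: dict[str, str]
    store: AnnotationStore
    generif: list[GeneRIFRecord]
    manifest: dict


def make_fixture(spec: FixtureSpec | None = None) -> Fixture:
    """Generate the complete fixture from one spec (pure in spec.seed)."""
    spec = spec or FixtureSpec()
    ontology, onto_manifest = make_toy_ontology(spec)
    articles, corpus_manifest = make_corpus(spec, ontology, onto_manifest)
    docs, store, generif, res_manifest = make_reference_resources(
        spec, ontology, onto_manifest, corpus_manifest
    )
    manifest = {
        "spec": asdict(spec),
        "ontology": onto_manifest,
        "corpus": corpus_manifest,
        "resources": res_manifest,
    }
    return Fixture(
        spec=spec,
        ontology=ontology,
        articles=articles,
        reference_docs=docs,
        store=store,
        generif=generif,
        manifest=manifest,
    )


def write_obo(ontology: Ontology, path) -> None:
    """Serialize an ontology to an OBO 1.2 flat file."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\nontology: litgo-fixture\n")
        for goid in sorted(ontology.terms):
            rec = ontology.terms[goid]
            fh.write(f"\n[Term]\nid: {goid}\nname: {rec.name}\n")
            for syn in rec.synonyms:
                fh.write(f'synonym: "{syn}" EXACT []\n')
            for parent in rec.parents:
                fh.write(f"is_a: {parent} ! {ontology.terms[parent].name}\n")


def write_fixture_dir(fixture: Fixture, outdir) -> dict[str, Path]:
    """Emit every file format the readers consume, plus the truth manifest."""
    from .corpus_io import write_bioc_collection

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "corpus": outdir / "corpus.xml",
        "ontology": outdir / "ontology.obo",
        "gene_goslim": outdir / "gene_goslim.tsv",
        "goslim_go_pmid": outdir / "goslim_go_pmid.tsv",
        "sentence_goid": outdir / "sentence_goid.tsv",
        "generif": outdir / "generif.tsv",
        "refdocs": outdir / "refdocs.tsv",
        "manifest": outdir / "manifest.json",
    }
    write_bioc_collection(fixture.articles, paths["corpus"])
    write_obo(fixture.ontology, paths["ontology"])
    with open(paths["gene_goslim"], "w", encoding="utf-8") as fh:
        for gene_id in sorted(fixture.store.gene_to_goslim):
            for slim in sorted(fixture.store.gene_to_goslim[gene_id]):
                fh.write(f"{gene_id}\t{slim}\n")
    with open(paths["goslim_go_pmid"], "w", encoding="utf-8") as fh:
        for slim, goid, pmid in sorted(fixture.store.goslim_go_pmid):
            fh.write(f"{slim}\t{goid}\t{pmid}\n")
    with open(paths["sentence_goid"], "w", encoding="utf-8") as fh:
        for text, goid in fixture.store.sentence_goid_pairs:
            fh.write(f"{text}\t{goid}\n")
    with open(paths["generif"], "w", encoding="utf-8") as fh:
        for r in fixture.generif:
            fh.write(f"{r.taxon_id}\t{r.gene_id}\t{r.pmid}\t2024-01-01\t{r.text}\n")
    with open(paths["refdocs"], "w", encoding="utf-8") as fh:
        for pmid in sorted(fixture.reference_docs):
            fh.write(f"{pmid}\t{fixture.reference_docs[pmid]}\n")
    with open(paths["manifest"], "w", encoding="utf-8") as fh:
        json.dump(fixture.manifest, fh, indent=1, sort_keys=True)
    return paths
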