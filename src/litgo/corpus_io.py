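"""Readers and writers for the external formats the pipeline consumes.

Covers BioC-style XML article collections (documents → passages → infons),
OBO 1.2 ontologies, tab-delimited GeneRIF records, and the annotation
resource tables (gene→GO-Slim pairs, ⟨GOSlimID, GOID, PMID⟩ triplets and
⟨sentence, GOID⟩ pairs) used for candidate reduction and GOID lookup.

Conventions: passages are the sentence unit (no further sentence splitting);
offsets are 0-based character offsets with half-open spans; gold GO-term
infons of the form ``"name|GO: 0016 791"`` are normalized by deleting
whitespace inside the identifier.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import networkx as nx
import obonet
from lxml import etree

logger = logging.getLogger(__name__)

__all__ = [
    "GeneRef", "Sentence", "Article", "GeneRIFRecord", "Ontology",
    "AnnotationStore", "BiocParseError", "FormatError", "OntologyError",
    "SECTION_VOCAB", "normalize_section", "normalize_go_id", "parse_gene_ref",
    "read_bioc_collection", "write_bioc_collection", "write_bioc_predictions",
    "load_ontology", "ancestors", "read_generif", "load_annotation_store",
]


class BiocParseError(ValueError):
    """Raised for malformed BioC XML input."""


class FormatError(ValueError):
    """Raised for malformed tabular/record input."""


class OntologyError(ValueError):
    """Raised for structurally invalid ontologies (cycles, dangling parents)."""


# Closed section vocabulary; anything else maps to OTHER.
SECTION_VOCAB = (
    "TITLE", "ABSTRACT", "INTRO", "METHODS", "RESULTS",
    "DISCUSSION", "TABLE", "FIG", "OTHER",
)

_SECTION_ALIASES = {
    "INTRODUCTION": "INTRO",
    "BACKGROUND": "INTRO",
    "METHOD": "METHODS",
    "MATERIALS AND METHODS": "METHODS",
    "RESULT": "RESULTS",
    "CONCLUSION": "DISCUSSION",
    "CONCLUSIONS": "DISCUSSION",
    "FIGURE": "FIG",
}


def normalize_section(label: str | None) -> str:
    """Map a raw section-type label into the closed section vocabulary."""
    if not label:
        return "OTHER"
    up = label.strip().upper()
    up = _SECTION_ALIASES.get(up, up)
    return up if up in SECTION_VOCAB else "OTHER"


def normalize_go_id(raw: str) -> str:
    """Normalize a GO-term infon value to a bare ``GO:NNNNNNN`` identifier.

    The infon may carry a term name before a ``|`` separator, and the
    identifier may contain stray internal whitespace.
    """
    ident = raw.rsplit("|", 1)[-1]
    return re.sub(r"\s+", "", ident)


@dataclass(frozen=True)
class GeneRef:
    """A relevant gene: display symbol plus database identifier."""

    symbol: str
    gene_id: str

    def __post_init__(self) -> None:
        if not self.symbol or not self.gene_id:
            raise FormatError(f"empty field in gene reference {self!r}")

    def render(self) -> str:
        return f"{self.symbol}({self.gene_id})"


def parse_gene_ref(raw: str) -> GeneRef:
    """Parse a ``symbol(gene_id)`` rendering; the final parenthesized group wins."""
    raw = raw.strip()
    if not raw.endswith(")"):
        raise FormatError(f"gene reference {raw!r} lacks a parenthesized identifier")
    i = raw.rfind("(")
    if i <= 0:
        raise FormatError(f"gene reference {raw!r} lacks a parenthesized identifier")
    return GeneRef(symbol=raw[:i], gene_id=raw[i + 1 : -1])


@dataclass(eq=False)
class Sentence:
    """A passage-level text unit with its gold annotations.

    ``eq=False`` keeps identity semantics so sentences can key dictionaries
    (e.g. the classifier's probability map) even when texts repeat.
    """

    text: str
    offset: int
    section: str = "OTHER"
    gold_genes: list[GeneRef] = field(default_factory=list)
    gold_go_ids: list[str] = field(default_factory=list)
    gold_evidence_code: str | None = None

    @property
    def length(self) -> int:
        return len(self.text)

    @property
    def span(self) -> tuple[int, int]:
        """Half-open character span [offset, offset+length)."""
        return (self.offset, self.offset + self.length)


@dataclass
class Article:
    """A full-text article: ordered sentences plus its relevant-gene list."""

    doc_id: str
    sentences: list[Sentence] = field(default_factory=list)
    gene_list: list[GeneRef] = field(default_factory=list)

    def validate(self) -> None:
        prev_end = -1
        for s in self.sentences:
            if s.offset <= prev_end:
                raise BiocParseError(
                    f"document {self.doc_id}: sentence offsets overlap or are "
                    f"non-increasing at offset {s.offset}"
                )
            prev_end = s.offset + s.length - 1
        known = {g.gene_id for g in self.gene_list}
        for s in self.sentences:
            for g in s.gold_genes:
                if g.gene_id not in known:
                    raise BiocParseError(
                        f"document {self.doc_id}: gold gene {g.render()} not in gene list"
                    )


@dataclass(frozen=True)
class GeneRIFRecord:
    """One GeneRIF entry: taxon, gene, source article, text excerpt."""

    taxon_id: int
    gene_id: str
    pmid: str
    text: str


# ---------------------------------------------------------------------------
# BioC XML


def _collect_infons(elem) -> dict[str, list[str]]:
    infons: dict[str, list[str]] = {}
    for node in elem.findall("infon"):
        key = node.get("key", "")
        infons.setdefault(key, []).append(node.text or "")
    return infons


def read_bioc_collection(path) -> list[Article]:
    """Read a BioC-style collection; one :class:`Article` per document."""
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise BiocParseError(f"malformed XML in {path}: {exc}") from exc
    articles: list[Article] = []
    for doc in tree.getroot().findall("document"):
        doc_id = (doc.findtext("id") or "").strip()
        doc_infons = _collect_infons(doc)
        gene_list = [parse_gene_ref(v) for v in doc_infons.get("gene", [])]
        seen_ids = {g.gene_id for g in gene_list}
        sentences: list[Sentence] = []
        for passage in doc.findall("passage"):
            text_node = passage.find("text")
            if text_node is None or text_node.text is None:
                raise BiocParseError(
                    f"document {doc_id}: passage without a text element"
                )
            infons = _collect_infons(passage)
            offset = int((passage.findtext("offset") or "0").strip())
            golds = [parse_gene_ref(v) for v in infons.get("gene", [])]
            go_ids = [normalize_go_id(v) for v in infons.get("go-term", [])]
            evid = infons.get("goevidence", [None])[0]
            sentences.append(
                Sentence(
                    text=text_node.text,
                    offset=offset,
                    section=normalize_section(infons.get("section-type", [None])[0]),
                    gold_genes=golds,
                    gold_go_ids=go_ids,
                    gold_evidence_code=evid,
                )
            )
            for g in golds:
                if g.gene_id not in seen_ids:
                    gene_list.append(g)
                    seen_ids.add(g.gene_id)
        article = Article(doc_id=doc_id, sentences=sentences, gene_list=gene_list)
        article.validate()
        articles.append(article)
    return articles


def _append_infon(parent, key: str, value: str) -> None:
    node = etree.SubElement(parent, "infon", key=key)
    node.text = value


def _emit_document(root, article: Article) -> dict[int, etree._Element]:
    doc = etree.SubElement(root, "document")
    idn = etree.SubElement(doc, "id")
    idn.text = article.doc_id
    for g in article.gene_list:
        _append_infon(doc, "gene", g.render())
    passage_by_sentence: dict[int, etree._Element] = {}
    for s in article.sentences:
        p = etree.SubElement(doc, "passage")
        _append_infon(p, "section-type", s.section)
        for g in s.gold_genes:
            _append_infon(p, "gene", g.render())
        for goid in s.gold_go_ids:
            _append_infon(p, "go-term", goid)
        if s.gold_evidence_code is not None:
            _append_infon(p, "goevidence", s.gold_evidence_code)
        off = etree.SubElement(p, "offset")
        off.text = str(s.offset)
        txt = etree.SubElement(p, "text")
        txt.text = s.text
        passage_by_sentence[id(s)] = p
    return passage_by_sentence


def write_bioc_collection(articles: list[Article], path) -> None:
    """Write articles back to the BioC dialect read by :func:`read_bioc_collection`."""
    write_bioc_predictions(articles, [], [], path)


def write_bioc_predictions(
    articles: list[Article],
    task_a: list[tuple[GeneRef, Sentence]],
    task_b: list[tuple[str, str, str]],
    path,
) -> None:
    """Write a collection with predictions embedded as infons.

    ``task_a`` holds (gene, sentence) evidence pairs — each sentence must be
    one of the article sentence objects; ``task_b`` holds (doc_id, gene_id,
    GOID) assignments.  Output re-parses with :func:`read_bioc_collection`.
    """
    root = etree.Element("collection")
    src = etree.SubElement(root, "source")
    src.text = "litgo"
    passage_map: dict[int, etree._Element] = {}
    doc_map: dict[str, etree._Element] = {}
    known_genes: dict[int, set[str]] = {}
    for article in articles:
        pm = _emit_document(root, article)
        passage_map.update(pm)
        doc_map[article.doc_id] = root.findall("document")[-1]
        known_genes[id(article)] = {g.gene_id for g in article.gene_list}
    sentence_owner = {
        id(s): article for article in articles for s in article.sentences
    }
    for gene, sentence in task_a:
        article = sentence_owner.get(id(sentence))
        if article is None:
            raise FormatError(
                f"prediction references a sentence not in any article: "
                f"{sentence.text[:40]!r}"
            )
        if gene.gene_id not in known_genes[id(article)]:
            raise FormatError(
                f"prediction gene {gene.render()} not in gene list of "
                f"document {article.doc_id}"
            )
        _append_infon(passage_map[id(sentence)], "a-gene", gene.render())
    for doc_id, gene_id, goid in task_b:
        doc = doc_map.get(doc_id)
        if doc is None:
            raise FormatError(f"prediction references unknown document {doc_id!r}")
        _append_infon(doc, "b-annotation", f"{gene_id}|{goid}")
    etree.ElementTree(root).write(
        str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


# ---------------------------------------------------------------------------
# Ontology


@dataclass(frozen=True)
class TermRecord:
    name: str
    synonyms: tuple[str, ...]
    parents: tuple[str, ...]


_SYNONYM_RE = re.compile(r'"([^"]*)"')


def _parse_synonym(raw: str) -> str:
    m = _SYNONYM_RE.match(raw.strip())
    return m.group(1) if m else raw.strip()


@dataclass
class Ontology:
    """GO terms with names, synonyms and is_a parents; acyclic by contract."""

    terms: dict[str, TermRecord]
    roots: tuple[str, ...]

    def ancestors(self, goid: str, exclude_roots: bool = False) -> set[str]:
        """Reflexive transitive closure over is_a edges."""
        if goid not in self.terms:
            raise OntologyError(f"unknown GO identifier {goid!r}")
        out: set[str] = set()
        stack = [goid]
        while stack:
            cur = stack.pop()
            if cur in out:
                continue
            out.add(cur)
            stack.extend(self.terms[cur].parents)
        if exclude_roots:
            out -= set(self.roots)
        return out


def load_ontology(obo_path) -> Ontology:
    """Load an OBO 1.2 flat file into an :class:`Ontology`."""
    graph = obonet.read_obo(str(obo_path))
    terms: dict[str, TermRecord] = {}
    for node, data in graph.nodes(data=True):
        parents = tuple(sorted(data.get("is_a", [])))
        synonyms = tuple(_parse_synonym(s) for s in data.get("synonym", []))
        terms[node] = TermRecord(
            name=data.get("name", ""), synonyms=synonyms, parents=parents
        )
    for goid, rec in terms.items():
        for p in rec.parents:
            if p not in terms:
                raise OntologyError(f"term {goid} has unknown parent {p}")
    isa = nx.DiGraph(
        (goid, p) for goid, rec in terms.items() for p in rec.parents
    )
    try:
        cycle = nx.find_cycle(isa)
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle:
        raise OntologyError(f"is_a cycle detected: {cycle}")
    roots = tuple(sorted(g for g, rec in terms.items() if not rec.parents))
    return Ontology(terms=terms, roots=roots)


def ancestors(ontology: Ontology, goid: str, exclude_roots: bool = False) -> set[str]:
    """Module-level alias for :meth:`Ontology.ancestors`."""
    return ontology.ancestors(goid, exclude_roots=exclude_roots)


# ---------------------------------------------------------------------------
# GeneRIF and annotation tables


def read_generif(path, taxon_filter: int | None = None) -> list[GeneRIFRecord]:
    """Read tab-delimited GeneRIF records (taxid, GeneID, PMID[, timestamp], text).

    Rows with fewer than four columns are skipped with a logged warning.
    With five or more columns the fourth (timestamp) is ignored and the
    remaining columns are joined as text.
    """
    records: list[GeneRIFRecord] = []
    skipped = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                skipped += 1
                continue
            text = cols[3] if len(cols) == 4 else "\t".join(cols[4:])
            try:
                taxon = int(cols[0])
            except ValueError:
                skipped += 1
                continue
            if taxon_filter is not None and taxon != taxon_filter:
                continue
            records.append(
                GeneRIFRecord(taxon_id=taxon, gene_id=cols[1], pmid=cols[2], text=text)
            )
    if skipped:
        logger.warning("read_generif: skipped %d malformed rows in %s", skipped, path)
    return records


@dataclass
class AnnotationStore:
    """The resource tables backing candidate reduction and GOID lookup."""

    gene_to_goslim: dict[str, set[str]]
    goslim_go_pmid: set[tuple[str, str, str]]
    sentence_goid_pairs: list[tuple[str, str]]

    @property
    def pmid_to_goids(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for _slim, goid, pmid in self.goslim_go_pmid:
            out.setdefault(pmid, set()).add(goid)
        return out

    @property
    def goa_pmids(self) -> set[str]:
        return {pmid for _s, _g, pmid in self.goslim_go_pmid}


def _read_tsv(path, arity: int) -> list[tuple[str, ...]]:
    rows: list[tuple[str, ...]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = tuple(line.split("\t"))
            if len(cols) != arity:
                raise FormatError(
                    f"{path}:{lineno}: expected {arity} columns, got {len(cols)}"
                )
            if any(not c for c in cols):
                raise FormatError(f"{path}:{lineno}: empty field")
            rows.append(cols)
    return rows


def load_annotation_store(
    gene_goslim_path, goslim_go_pmid_path, sentence_goid_path=None
) -> AnnotationStore:
    """Load the ⟨GeneID,GOSlimID⟩ / ⟨GOSlimID,GOID,PMID⟩ / ⟨sentence,GOID⟩ tables."""
    gene_to_goslim: dict[str, set[str]] = {}
    for gene_id, slim in _read_tsv(gene_goslim_path, 2):
        gene_to_goslim.setdefault(gene_id, set()).add(slim)
    triplets = set(_read_tsv(goslim_go_pmid_path, 3))
    pairs: list[tuple[str, str]] = []
    if sentence_goid_path is not None:
        seen = set()
        for row in _read_tsv(sentence_goid_path, 2):
            if row not in seen:
                seen.add(row)
                pairs.append(row)
    return AnnotationStore(
        gene_to_goslim=gene_to_goslim,
        goslim_go_pmid=triplets,
        sentence_goid_pairs=pairs,
    )
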