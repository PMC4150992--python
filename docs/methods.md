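# Methods

`litgo` annotates genes with Gene Ontology (GO) terms from full-text
articles in two stages: it first detects *evidence sentences* — sentences
that support a GO annotation for one of the article's relevant genes — and
associates each with a gene; it then predicts GO terms for each gene from
its evidence sentences. This note describes the models, the parameters
that matter, the synthetic data the package is characterized on, and the
design choices made where the design was genuinely open.

## Evidence-sentence detection

### Distant supervision

Sentence-level evidence labels are scarce, and positives and negatives
drawn from the same small pool of articles invite overfitting. The
training set is therefore supplemented with *noisy negatives*: GeneRIF
excerpts (short functional statements about genes, each tied to a taxon,
GeneID and PMID) whose source articles carry no GO annotation. The
assumption is that an excerpt from an article absent from the GO
annotation corpus is unlikely to be GO evidence — GeneRIF's scope
(phenotypes, disease) is broader than GO's. The labels are not guaranteed
true negatives and are used as-is, with no instance weighting.

The sampler draws up to 20 000 excerpts uniformly at random (seeded) from
records matching the configured taxon (default 9606, human) whose PMIDs
fall outside the GO-annotation PMID set, capped at 2 per GeneID so heavily
studied genes are not over-represented. A short pool returns every
eligible record. Two samples with different seeds give different
classifiers — this is deliberately exposed (it is the mechanism behind
run-to-run variation), and run outputs can be merged by set union.

### Features

Five families, concatenated in disjoint namespaces over a vocabulary
frozen at training time (unseen features are dropped at prediction time,
not hashed):

* **bow:** term counts of lowercase Porter-stemmed tokens. The tokenizer
  splits on maximal runs of non-alphanumeric characters; tokens containing
  digits bypass the stemmer, which is defined for alphabetic words.
* **bg:** adjacent-stem bigrams plus two boundary bigrams `SOS_w1` and
  `wn_EOS`; a sentence of *n* tokens contributes exactly *n*+1 bigram
  occurrences.
* **sec:** a one-hot section indicator over a closed vocabulary
  {TITLE, ABSTRACT, INTRO, METHODS, RESULTS, DISCUSSION, TABLE, FIG,
  OTHER}; unknown labels map to OTHER.
* **top:** the sentence's topic distribution under an LDA model
  (default 100 topics, deterministic for a fixed seed). The model is
  trained on sentences — the classification unit — rather than whole
  documents. Sentences with no in-vocabulary token get the uniform
  distribution. Topic vectors are simplex-valued by construction.
* **gene:** a binary flag set when any of the article's relevant genes
  matches the sentence under the same rule the assembly step uses.

GeneRIF excerpts have no section or article context; they receive section
OTHER, gene flag 0, and topic features inferred from the shared
sentence-trained model.

### Classifier

L2-regularized (ridge) logistic regression with an **unpenalized
intercept**:

    minimize  Σ_i log(1 + exp(−s_i (w·x_i + b))) + (λ/2)‖w‖²,   s_i = ±1

optimized with L-BFGS on the analytic gradient to a tight gradient-norm
tolerance (the returned weights satisfy ‖∇‖ ≤ 1e-6 on the test problems).
λ defaults to 1.0 and is configurable. As λ → ∞ the weights shrink to
zero and the intercept carries the class prior, so predicted
probabilities collapse to the class prevalence — a useful closed-form
check of the implementation.

Class imbalance (evidence sentences are a small minority) is handled only
by the decision threshold: a sentence is positive when its probability is
**strictly greater than** 0.1. Lowering the threshold never shrinks the
positive set.

## Gene assembly

Relevant genes are given per article; the task is to attach them to the
predicted positive sentences. Four greedy steps, in order:

1. **Direct lookup** — a gene is attached to a positive sentence when its
   symbol occurs in the text. Matching is case-insensitive *substring*
   matching without word-boundary anchoring, because gold data pairs text
   like "CeCDC-14" with the symbol "cdc-14" — an embedded match. A
   boundary-anchored mode is available for cleaner nomenclatures.
2. **Family names** — genes sharing a symbol stem (the symbol with one
   trailing digit or hyphen-digit suffix removed; stems with fewer than
   two members are discarded) form a family; a mention of the family name
   (singular, +s, +es) attaches *all* members. The stem rule is an
   interpretation: family grouping must be derived from the provided
   mentions somehow, and suffix stripping is the convention that fits
   symbol series like `abc-1`, `abc-2`.
3. **Proximity** — a positive sentence with no hit inherits the gene hits
   of the *closest prior sentence in the same section* that has any
   (step-1 or step-2 style) hit. Distance is the difference in sentence
   indices, so ties cannot occur. Positive sentences that still have no
   gene are dropped.
4. **Fallback** — each relevant gene still unassigned gets the sentence
   mentioning it (directly or via family) with the largest classifier
   probability; ties break to the smaller offset. All article sentences
   are eligible by default — the fallback's purpose is recall for genes
   the classifier missed — with a flag restricting to positives only. A
   gene that never appears gets nothing.

Steps 1–3 only ever attach genes to predicted-positive sentences; step 4
may attach a gene to a non-positive sentence. Output is deduplicated on
(gene, sentence), carries a provenance label per pair, and is
deterministic given its inputs.

## GO-term prediction

All three systems consume (gene, evidence sentence) pairs and emit
(gene, GO term, score) assignments per article. Ties anywhere break by
GOID ascending.

### Retrieval core (B1, B2)

Documents are ranked by Dirichlet-smoothed query likelihood:

    score(D, Q) = Σ_i ln( (tf_{qi,D} + μ·tf_{qi,C}/|C|) / (|D| + μ) )

with document/collection term frequencies and lengths from an inverted
index built with the shared stemming tokenizer. Natural logarithms are
used throughout: ranking is base-invariant, but the B2 score-*gap*
threshold is not, so the base is fixed and documented. μ defaults to
2500, a conventional Dirichlet value for full-text collections; it is
config-exposed. Query terms with zero collection frequency are dropped
before scoring (avoiding log 0); a query that loses all its terms
contributes no results. Duplicate query terms contribute once per
occurrence. Queries are the stemmed, stopword-filtered evidence-sentence
tokens; the stopword list ships with the package so results are
reproducible.

### B1 — document retrieval with GO-Slim candidate reduction

Per gene, a *candidate PMID list* is built by joining the gene's GO-Slim
categories against ⟨GOSlimID, GOID, PMID⟩ annotation triplets; retrieval
for that gene's evidence sentences is restricted to the list (an empty
list falls back to the whole collection by default, since a "reduced
search list" does not define the empty case). For each evidence sentence,
the top *k* documents are weighted by exponentiated, max-shifted,
normalized scores — a softmax. Raw query-likelihood scores are negative
log-probabilities, so "weight by relevance score" needs a transform that
is positive and monotone in score; the softmax is the standard choice
that preserves the ranking semantics. Each retrieved document's GOIDs
accrue its weight; the top *m* GOIDs per sentence survive. Finally GOIDs
are counted across the gene's sentences (once per sentence) and kept when
they occur in **strictly more than** *p* of them, ranked by count.
Defaults ⟨k, m, p⟩ = ⟨7, 10, 4⟩. Aggregation is per (article, gene) — the
unit the metrics are defined on and the unit the sentence-granular system
explicitly uses. No fallback exists when a gene has ≤ p evidence
sentences; the cutoff is allowed to empty the output.

### B2 — annotated-sentence retrieval with score-gap selection

An index over ⟨sentence, GOID⟩ pairs (GeneRIF sentences cited as GO
evidence) is searched per evidence sentence; the sentence ranking becomes
a GOID ranking in which each GOID inherits the score of its best-ranked
sentence. Walking the top-*k* GOID list from the top, GOIDs are selected
while the gap to the topmost score is ≤ *h* (the output is always a
prefix of the list); selections are then frequency-ranked across the
gene's sentences and the top *m* kept. Defaults ⟨k, h, m⟩ = ⟨5, 0.1, 3⟩,
with *h* applied to natural-log score differences.

### B3 — dictionary matching

For each GO term, the term's name and synonyms are stemmed into a word
set T; the sentence's matched set is M = S ∩ T for sentence stems S. The
Jaccard index |M ∩ T| / |M ∪ T| then reduces to |M| / |T| — the fraction
of the term's words present. A term is assigned when this reaches 0.75;
the best value over name and synonyms is the score. A stated *distance*
threshold of 0.75 read literally (distance ≤ 0.75) would accept
25%-overlap matches, inconsistent with a precision-oriented string
baseline, so the default reads the cutoff as similarity ≥ 0.75
(equivalently distance ≤ 0.25); both directions are selectable. A
sentence consisting exactly of a term's words always matches it at any
threshold ≤ 1.

## Evaluation

* **Evidence pairs** — micro-averaged P/R/F1 over (document, gene, span)
  items under (i) exact span identity and (ii) partial overlap, with
  greedy one-to-one matching in prediction order so a gold item satisfies
  at most one prediction. Relaxing exact to overlap can only grow TP, so
  overlap-F1 bounds exact-F1 from above.
* **Flat terms** — set-intersection P/R/F1 over (article, gene, GOID)
  triples.
* **Hierarchical terms** — "shares a common ancestor" is degenerate over
  a rooted ontology (every pair of terms shares the root), so the default
  is the standard ancestor-closure formulation: per (article, gene), both
  term sets expand to their reflexive is_a closures (roots excluded), and
  hP = |∩|/|closure(pred)|, hR = |∩|/|closure(gold)| with counts summed
  over all (article, gene) keys before the ratios. The literal
  any-common-ancestor relaxation remains available as a flag.

## Synthetic study data

Nothing in the package requires external corpora: the generator emits
every input format the readers consume, with a manifest of planted truth.

* A toy ontology: one root, a layer of GO-Slim category terms (children
  of the root, also serving as the slim table's categories), and leaf
  terms, each leaf owning a disjoint 6-word vocabulary block from which
  its name and synonym are drawn. Words carry digits so they are
  invariant under stemming and never collide with each other.
* Articles: per article, 2 relevant genes, each annotated with one leaf
  term and 2 planted evidence sentences mixing the gene symbol (randomly
  case-mangled) with term vocabulary at probability `topic_purity` (0.8)
  per token against a shared background vocabulary; negatives draw from
  background only. A quarter of planted sentences omit the symbol but are
  preceded in-section by a sentence that mentions it, exercising the
  proximity step; 20% of genes come in two-member families sharing a
  symbol stem, exercising the family step.
* Reference resources: documents generated from the vocabularies of their
  annotated GOIDs (the annotation triplets are exactly the document
  annotations), an annotated-sentence pool per GOID, a gene→GO-Slim table
  covering each gene's planted terms, and a GeneRIF pool over a disjoint
  gene-id space with ~30% of PMIDs inside the GO-annotation set — so the
  negative sampler's exclusion rule and per-gene cap both bite.

Defaults: 200 articles × 12 sentences (evidence rate 1/3, i.e. 4 planted
evidence sentences per article), 30 genes, 31 GO terms, 300 background
words, 120 reference documents, a 4000-record GeneRIF pool, seed 7.
These sizes keep a full end-to-end run (generation, LDA with 100 topics,
ridge LR on ~2000 sentences plus 2000 sampled negatives, all three
assignment systems, both metric families) in the tens of seconds while
leaving every mechanism observable: 2 evidence sentences per annotation
make an occurrence cutoff of 1 the scaled analogue of the production
default 4, and slim categories of ~2 leaf terms make candidate-list
reduction consequential.

All generators are pure functions of the spec and its seed.

**What the generator does not emulate** — and hence what passing tests do
*not* establish about real literature: real English syntax and anaphora
(token-level lexical separation stands in for topical coherence), gene
name ambiguity and nomenclature collisions (symbols are substring-unique
by construction), the true GO DAG's depth and fan-out, real section-label
priors on evidence location, OCR/encoding noise, and the much harsher
class imbalance and vocabulary overlap of genuine full-text corpora. On
the synthetic conditions the classifier separates classes almost
perfectly and the retrieval systems recover most planted annotations;
those are checks of mechanism correctness, not performance forecasts.

## Numerical choices and degenerate inputs

* Optimizer: L-BFGS, analytic gradient, `gtol=1e-8`, `ftol=1e-14`,
  stable `logaddexp` loss; single-class training data is rejected.
* Topic inference renormalizes the LDA posterior row to sum exactly 1;
  empty sentences get the uniform distribution.
* Empty query after stopword/out-of-vocabulary filtering → the sentence
  contributes no retrieval results (no score is invented).
* Offsets are 0-based character offsets; spans half-open; gold GO-term
  identifiers are normalized by deleting internal whitespace
  (`"GO: 0016 791"` → `GO:0016791`); the final parenthesized group of a
  `symbol(id)` rendering is the identifier, so symbols may themselves
  contain parentheses.
* Ontology loading rejects is_a cycles (reporting the cycle) and dangling
  parents; ancestor closures are reflexive.
* All rankings break ties deterministically (score, then identifier).

## Known limitations

* The family-stem rule and the softmax document weighting are reasonable
  interpretations of under-specified conventions; alternatives (explicit
  family lexicons, rank-based weights) may behave differently on real
  nomenclatures.
* Substring gene matching is deliberately permissive and will over-attach
  short symbols inside longer words on real text; the anchored mode
  trades recall for precision.
* The evidence-code field is parsed but never predicted.
* The retrieval engine implements only the query-likelihood model — no
  phrase operators, relevance feedback, or BM25.
* Model persistence uses Python pickle (with a format tag); artifacts are
  not portable across incompatible library versions.
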