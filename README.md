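# litgo

Literature-based Gene Ontology annotation: find the sentences in a
full-text article that constitute evidence for a gene's GO annotation,
and predict GO terms for each gene from those sentences.

Manual GO curation is expensive; tools that surface candidate evidence
sentences and candidate terms let curators verify instead of read. Given
an article and its list of relevant genes, `litgo`:

1. **detects evidence sentences** with a logistic-regression classifier
   over bag-of-words, bigram, section, LDA-topic and gene-presence
   features, trained with *distant supervision* — gold evidence sentences
   as positives, the remaining sentences plus GeneRIF excerpts from
   articles without GO annotations as (noisy) negatives — and a low
   decision threshold (p > 0.1) for the skewed class balance;
2. **attaches genes** to positive sentences with a four-step greedy
   algorithm: direct symbol lookup, gene-family mentions, same-section
   proximity, and a per-gene best-probability fallback;
3. **predicts GO terms** per gene by one of three systems:
   * **B1** — retrieve annotated reference *documents* for each evidence
     sentence (search restricted to a GO-Slim-derived candidate PMID
     list), aggregate the retrieved documents' GOIDs with softmax score
     weights, keep GOIDs occurring in more than *p* sentences;
   * **B2** — retrieve annotated *sentences*, truncate the GOID ranking
     at a score gap *h*, keep each gene's *m* most frequent GOIDs;
   * **B3** — assign a term when ≥ 75% of its name/synonym word stems
     appear in the sentence (Jaccard dictionary matching);
4. **evaluates** both stages: exact and overlapping span matching for
   evidence pairs, flat and hierarchical (ancestor-closure) P/R/F1 for
   term assignments.

Documents are ranked with the Dirichlet-smoothed query-likelihood model

    score(D, Q) = Σᵢ ln( (tf_{qᵢ,D} + μ·tf_{qᵢ,C}/|C|) / (|D| + μ) )

over an inverted index with Porter stemming; hierarchical metrics use
hP = |A(pred) ∩ A(gold)| / |A(pred)| and hR = … / |A(gold)| where A(·) is
the reflexive is_a ancestor closure with roots excluded.

A synthetic-fixture generator produces every input the pipeline consumes
(BioC-style XML articles with planted evidence, an OBO ontology,
GeneRIF and annotation tables, reference collections) with a manifest of
planted truth, so the whole system is testable end to end without
external data. See `docs/methods.md` for models, parameters and
limitations.

## Worked example

`examples/predict_go_terms.py` generates a 40-article fixture, feeds the
gold evidence sentences to all three systems and scores them:

```
160 gold (gene, evidence sentence) pairs from 40 articles

system   assignments   flat F1   hier F1
B1                80     1.000     1.000
B2                89     0.947     0.945
B3                76     0.974     0.975
```

Flat F1 requires exact term identity; hierarchical F1 grants partial
credit through shared ancestors. On this fixture the reference documents
share vocabulary with their annotated terms, so the retrieval systems
recover the planted annotations almost perfectly — a correctness check of
the machinery, not a forecast for real corpora. The other examples show
evidence-sentence detection plus gene assembly
(`detect_evidence_sentences.py`) and hand-checkable query-likelihood
scores (`score_with_query_likelihood.py`); each prints what its numbers
mean.

The same pipeline is scriptable from the shell:

```bash
litgo fixtures --out fx --seed 7
litgo train-a  --corpus fx/corpus.xml --generif fx/generif.tsv \
               --goslim-go-pmid fx/goslim_go_pmid.tsv --out model.pkl
litgo predict-a --model model.pkl --corpus fx/corpus.xml --out outa
litgo predict-b --system B1 --p 1 --corpus fx/corpus.xml --pairs outa/pairs.tsv \
               --ontology fx/ontology.obo --gene-goslim fx/gene_goslim.tsv \
               --goslim-go-pmid fx/goslim_go_pmid.tsv --refdocs fx/refdocs.tsv \
               --out outb
litgo evaluate --task b --corpus fx/corpus.xml \
               --assignments outb/assignments.tsv --ontology fx/ontology.obo
```

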