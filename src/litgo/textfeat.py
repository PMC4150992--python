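"""Tokenization, stemming, stopword filtering and the five sentence
feature families used by the evidence-sentence classifier.

The five families are bag-of-words (``bow:``), bigrams with sentence
boundary markers (``bg:``), a one-hot section indicator (``sec:``), an LDA
topic distribution (``top:``), and a binary relevant-gene-presence flag
(``gene:``).  Namespaces are disjoint so the families can be concatenated
into one sparse vector over a vocabulary frozen at training time.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy import sparse
from sklearn.decomposition import LatentDirichletAllocation

from ._porter import porter_stem
from .corpus_io import GeneRef, SECTION_VOCAB, Sentence, normalize_section

__all__ = [
    "tokenize_stem", "remove_stopwords", "load_stopwords",
    "bow_features", "bigram_features", "section_feature",
    "TopicModel", "train_topic_model", "topic_features", "topic_features_batch",
    "gene_presence_feature", "FeatureContext", "assemble_features",
]

FeatureVector = dict[str, float]

_TOKEN_SPLIT = re.compile(r"[^0-9a-z]+")


def tokenize_stem(text: str) -> list[str]:
    """Lowercase, split on runs of non-alphanumerics, Porter-stem each token.

    Tokens containing digits are kept verbatim (the stemmer is defined for
    alphabetic words only).
    """
    tokens = [t for t in _TOKEN_SPLIT.split(text.lower()) if t]
    return [porter_stem(t) if t.isalpha() else t for t in tokens]


def remove_stopwords(tokens: list[str], stoplist: frozenset[str] | set[str]) -> list[str]:
    """Order-preserving removal of stoplist members."""
    return [t for t in tokens if t not in stoplist]


def load_stopwords() -> frozenset[str]:
    """The packaged stopword list, passed through the same stem pipeline."""
    text = (resources.files("litgo") / "data" / "stopwords.txt").read_text("utf-8")
    out: set[str] = set()
    for line in text.splitlines():
        word = line.strip()
        if word:
            out.update(tokenize_stem(word))
    return frozenset(out)


def bow_features(tokens: list[str], vocab: frozenset[str] | None = None) -> FeatureVector:
    """Term counts over the (optionally frozen) vocabulary, ``bow:`` namespace."""
    counts = Counter(tokens)
    return {
        f"bow:{t}": float(c)
        for t, c in counts.items()
        if vocab is None or f"bow:{t}" in vocab
    }


def bigram_features(tokens: list[str], vocab: frozenset[str] | None = None) -> FeatureVector:
    """Adjacent-token bigrams plus SOS/EOS boundary bigrams, ``bg:`` namespace.

    A nonempty sentence of n tokens yields exactly n+1 bigram occurrences.
    """
    if not tokens:
        return {}
    grams = ["SOS_" + tokens[0]]
    grams += [f"{a}_{b}" for a, b in zip(tokens, tokens[1:])]
    grams.append(tokens[-1] + "_EOS")
    counts = Counter(grams)
    return {
        f"bg:{g}": float(c)
        for g, c in counts.items()
        if vocab is None or f"bg:{g}" in vocab
    }


def section_feature(sentence: Sentence) -> FeatureVector:
    """One-hot indicator over the closed section vocabulary, ``sec:`` namespace."""
    label = normalize_section(sentence.section)
    assert label in SECTION_VOCAB
    return {f"sec:{label}": 1.0}


@dataclass
class TopicModel:
    """A fitted LDA model over a frozen token vocabulary."""

    lda: LatentDirichletAllocation
    vocab_index: dict[str, int]
    n_topics: int
    seed: int

    @property
    def topic_word_(self) -> np.ndarray:
        """Row-normalized topic-word distributions (each row sums to 1)."""
        comp = self.lda.components_
        return comp / comp.sum(axis=1, keepdims=True)


def _count_matrix(corpus: list[list[str]], vocab_index: dict[str, int]) -> sparse.csr_matrix:
    rows, cols, vals = [], [], []
    for i, tokens in enumerate(corpus):
        counts = Counter(t for t in tokens if t in vocab_index)
        for t, c in counts.items():
            rows.append(i)
            cols.append(vocab_index[t])
            vals.append(c)
    return sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(corpus), len(vocab_index)), dtype=np.float64
    )


def train_topic_model(
    corpus: list[list[str]], n_topics: int = 100, seed: int = 0, max_iter: int = 15
) -> TopicModel:
    """Fit LDA on tokenized sentences (the classification unit).

    The number of topics defaults to 100; inference is deterministic for a
    fixed seed.
    """
    if not corpus:
        raise ValueError("topic model requires a nonempty corpus")
    if n_topics < 2:
        raise ValueError("n_topics must be at least 2")
    vocab = sorted({t for tokens in corpus for t in tokens})
    vocab_index = {t: i for i, t in enumerate(vocab)}
    X = _count_matrix(corpus, vocab_index)
    lda = LatentDirichletAllocation(
        n_components=n_topics, random_state=seed, max_iter=max_iter
    )
    lda.fit(X)
    return TopicModel(lda=lda, vocab_index=vocab_index, n_topics=n_topics, seed=seed)


def topic_features_batch(model: TopicModel, corpus: list[list[str]]) -> np.ndarray:
    """Per-sentence topic distributions, one simplex row per input sentence.

    Sentences with no in-vocabulary tokens get the uniform distribution.
    """
    X = _count_matrix(corpus, model.vocab_index)
    out = np.full((len(corpus), model.n_topics), 1.0 / model.n_topics)
    nonempty = np.asarray(X.sum(axis=1)).ravel() > 0
    if nonempty.any():
        theta = model.lda.transform(X[nonempty])
        theta = theta / theta.sum(axis=1, keepdims=True)
        out[nonempty] = theta
    return out


def topic_features(model: TopicModel, tokens: list[str]) -> FeatureVector:
    """Topic distribution for one sentence in the ``top:`` namespace."""
    theta = topic_features_batch(model, [tokens])[0]
    return {f"top:{i:03d}": float(v) for i, v in enumerate(theta)}


def gene_presence_feature(sentence_text: str, gene_list: list[GeneRef]) -> FeatureVector:
    """Binary flag: does any relevant gene match the sentence text?

    Uses the same matching rule as the gene-assembly dictionary lookup.
    """
    from .gene_assembly import match_gene

    hit = any(match_gene(sentence_text, g) for g in gene_list)
    return {"gene:present": 1.0 if hit else 0.0}


@dataclass
class FeatureContext:
    """Frozen training-time state needed to featurize a sentence."""

    topic_model: TopicModel
    vocab: frozenset[str] | None = None  # frozen bow:/bg: feature names


def assemble_features(
    sentence: Sentence,
    gene_list: list[GeneRef],
    context: FeatureContext,
    topic_row: np.ndarray | None = None,
) -> FeatureVector:
    """Concatenate the five feature families into one sparse vector.

    ``topic_row`` lets callers reuse a batch topic inference; otherwise the
    distribution is inferred here.  Unseen bow/bigram features are dropped
    when the context carries a frozen vocabulary.
    """
    tokens = tokenize_stem(sentence.text)
    fv: FeatureVector = {}
    fv.update(bow_features(tokens, context.vocab))
    fv.update(bigram_features(tokens, context.vocab))
    fv.update(section_feature(sentence))
    if topic_row is None:
        fv.update(topic_features(context.topic_model, tokens))
    else:
        fv.update({f"top:{i:03d}": float(v) for i, v in enumerate(topic_row)})
    fv.update(gene_presence_feature(sentence.text, gene_list))
    return fv
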