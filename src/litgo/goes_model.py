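"""Evidence-sentence classification with distant supervision.

Gold evidence sentences are positives; the remaining sentences of the
training articles are negatives, supplemented with randomly sampled
GeneRIF excerpts whose source articles carry no GO annotation — a noisy
negative pool (the labels are not guaranteed true negatives and are taken
at face value).  The classifier is an L2-regularized logistic regression
with an unpenalized intercept, optimized to a tight gradient-norm
tolerance; class imbalance is handled only by a low decision threshold
(default 0.1, strict inequality).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, sparse

from .corpus_io import Article, GeneRIFRecord, Sentence
from .textfeat import (
    FeatureContext,
    FeatureVector,
    assemble_features,
    bigram_features,
    bow_features,
    tokenize_stem,
    topic_features_batch,
    train_topic_model,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SamplerConfig", "ClassifierConfig", "RidgeLRModel",
    "sample_noisy_negatives", "train_ridge_lr", "predict_goes",
    "combine_runs", "GoesClassifier", "train_goes_classifier",
]


@dataclass
class SamplerConfig:
    """Noisy-negative sampling: 20 000 excerpts, at most two per gene,
    human records only, source articles outside the GOA PMID set."""

    n_excerpts: int = 20000
    max_per_gene: int = 2
    taxon: int = 9606
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_excerpts < 0 or self.max_per_gene < 1:
            raise ValueError("invalid sampler configuration")


@dataclass
class ClassifierConfig:
    """Decision threshold on the positive-class probability (strict >)."""

    threshold: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie strictly between 0 and 1")


def sample_noisy_negatives(
    records: list[GeneRIFRecord],
    goa_pmids: set[str],
    config: SamplerConfig,
) -> list[GeneRIFRecord]:
    """Uniformly sample eligible GeneRIF excerpts under the per-gene cap.

    Eligible records match the configured taxon and cite a PMID absent
    from the GO-annotation set.  If the eligible pool is smaller than
    requested, every admissible record is returned.
    """
    eligible = [
        r
        for r in records
        if r.taxon_id == config.taxon and r.pmid not in goa_pmids
    ]
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(eligible))
    per_gene: dict[str, int] = {}
    sampled: list[GeneRIFRecord] = []
    for i in order:
        r = eligible[i]
        if per_gene.get(r.gene_id, 0) >= config.max_per_gene:
            continue
        per_gene[r.gene_id] = per_gene.get(r.gene_id, 0) + 1
        sampled.append(r)
        if len(sampled) >= config.n_excerpts:
            break
    if len(sampled) < config.n_excerpts:
        logger.info(
            "noisy-negative pool exhausted: %d of %d requested",
            len(sampled), config.n_excerpts,
        )
    return sampled


@dataclass
class RidgeLRModel:
    """Logistic regression with an L2 penalty on the weights only."""

    feature_index: dict[str, int]
    weights: np.ndarray
    intercept: float
    lam: float

    def decision(self, fv: FeatureVector) -> float:
        z = self.intercept
        for name, value in fv.items():
            j = self.feature_index.get(name)
            if j is not None:
                z += self.weights[j] * value
        return z

    def predict_proba(self, fv: FeatureVector) -> float:
        z = self.decision(fv)
        if z >= 0:
            return float(1.0 / (1.0 + np.exp(-z)))
        ez = np.exp(z)
        return float(ez / (1.0 + ez))


def vectors_to_csr(
    X: list[FeatureVector], feature_index: dict[str, int]
) -> sparse.csr_matrix:
    rows, cols, vals = [], [], []
    for i, fv in enumerate(X):
        for name, value in fv.items():
            j = feature_index.get(name)
            if j is not None:
                rows.append(i)
                cols.append(j)
                vals.append(value)
    return sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(X), len(feature_index)), dtype=np.float64
    )


def train_ridge_lr(
    X: list[FeatureVector],
    y: list[int] | np.ndarray,
    lam: float = 1.0,
    gtol: float = 1e-8,
    max_iter: int = 2000,
) -> RidgeLRModel:
    """Minimize the L2-penalized logistic loss (intercept unpenalized).

    Objective: sum_i log(1 + exp(-s_i z_i)) + (lam/2)·||w||², s_i = ±1.
    """
    y = np.asarray(y, dtype=np.float64)
    if lam <= 0:
        raise ValueError("lam must be positive")
    if len(set(y.tolist())) < 2:
        raise ValueError("training data must contain both classes")
    names = sorted({name for fv in X for name in fv})
    feature_index = {name: j for j, name in enumerate(names)}
    A = vectors_to_csr(X, feature_index)
    s = 2.0 * y - 1.0
    d = len(names)

    def objective(theta: np.ndarray):
        w, b = theta[:d], theta[d]
        z = s * (A @ w + b)
        # log(1+exp(-z)) computed stably
        loss = np.logaddexp(0.0, -z).sum() + 0.5 * lam * w @ w
        p = 1.0 / (1.0 + np.exp(np.abs(z)))  # sigmoid(-|z|)
        g_z = -np.where(z >= 0, p, 1.0 - p)  # d loss_i / d z_i
        gs = s * g_z
        grad_w = A.T @ gs + lam * w
        grad_b = gs.sum()
        return loss, np.concatenate([grad_w, [grad_b]])

    result = optimize.minimize(
        objective,
        np.zeros(d + 1),
        jac=True,
        method="L-BFGS-B",
        options={"gtol": gtol, "ftol": 1e-14, "maxiter": max_iter, "maxfun": 10 * max_iter},
    )
    theta = result.x
    return RidgeLRModel(
        feature_index=feature_index,
        weights=theta[:d],
        intercept=float(theta[d]),
        lam=lam,
    )


def predict_goes(
    model: RidgeLRModel,
    sentences: list[Sentence],
    features: list[FeatureVector],
    config: ClassifierConfig | None = None,
) -> list[tuple[Sentence, float, bool]]:
    """Score sentences; positive iff probability strictly exceeds the threshold."""
    config = config or ClassifierConfig()
    out = []
    for sentence, fv in zip(sentences, features, strict=True):
        p = model.predict_proba(fv)
        out.append((sentence, p, bool(p > config.threshold)))
    return out


def combine_runs(run1: set, run2: set) -> set:
    """Union of two runs' (gene, sentence) pair sets (the A3 combination)."""
    return set(run1) | set(run2)


# ---------------------------------------------------------------------------
# End-to-end trainer


@dataclass
class GoesClassifier:
    """A trained classifier bundled with its frozen feature context."""

    model: RidgeLRModel
    context: FeatureContext
    config: ClassifierConfig = field(default_factory=ClassifierConfig)

    def featurize_article(self, article: Article) -> list[FeatureVector]:
        tokens = [tokenize_stem(s.text) for s in article.sentences]
        theta = topic_features_batch(self.context.topic_model, tokens)
        return [
            assemble_features(s, article.gene_list, self.context, topic_row=theta[i])
            for i, s in enumerate(article.sentences)
        ]

    def predict_article(self, article: Article) -> list[tuple[Sentence, float, bool]]:
        return predict_goes(
            self.model, article.sentences, self.featurize_article(article), self.config
        )


def is_gold_goes(sentence: Sentence) -> bool:
    """Gold evidence sentences carry a gold gene or GO-term annotation."""
    return bool(sentence.gold_genes or sentence.gold_go_ids)


def _generif_feature(
    record: GeneRIFRecord, context: FeatureContext, topic_row: np.ndarray
) -> FeatureVector:
    tokens = tokenize_stem(record.text)
    fv: FeatureVector = {}
    fv.update(bow_features(tokens, context.vocab))
    fv.update(bigram_features(tokens, context.vocab))
    fv["sec:OTHER"] = 1.0
    fv.update({f"top:{i:03d}": float(v) for i, v in enumerate(topic_row)})
    fv["gene:present"] = 0.0
    return fv


def train_goes_classifier(
    articles: list[Article],
    generif_negatives: list[GeneRIFRecord] | None = None,
    lam: float = 1.0,
    n_topics: int = 100,
    seed: int = 0,
    threshold: float = 0.1,
) -> GoesClassifier:
    """Train the full pipeline: topic model, frozen vocabulary, ridge LR.

    Positives are the gold evidence sentences of the training articles;
    negatives are every other sentence plus (optionally) sampled GeneRIF
    excerpts, which receive section OTHER, no gene-presence hit, and topic
    features inferred from the shared sentence-trained model.
    """
    generif_negatives = generif_negatives or []
    sent_tokens = [
        tokenize_stem(s.text) for a in articles for s in a.sentences
    ]
    topic_model = train_topic_model(sent_tokens, n_topics=n_topics, seed=seed)

    vocab: set[str] = set()
    for tokens in sent_tokens:
        vocab.update(bow_features(tokens))
        vocab.update(bigram_features(tokens))
    context = FeatureContext(topic_model=topic_model, vocab=frozenset(vocab))

    X: list[FeatureVector] = []
    y: list[int] = []
    cursor = 0
    all_theta = topic_features_batch(topic_model, sent_tokens)
    for article in articles:
        for s in article.sentences:
            X.append(
                assemble_features(
                    s, article.gene_list, context, topic_row=all_theta[cursor]
                )
            )
            y.append(1 if is_gold_goes(s) else 0)
            cursor += 1
    if generif_negatives:
        rif_tokens = [tokenize_stem(r.text) for r in generif_negatives]
        rif_theta = topic_features_batch(topic_model, rif_tokens)
        for record, theta in zip(generif_negatives, rif_theta):
            X.append(_generif_feature(record, context, theta))
            y.append(0)

    model = train_ridge_lr(X, y, lam=lam)
    return GoesClassifier(
        model=model, context=context, config=ClassifierConfig(threshold=threshold)
    )
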