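"""Precision / recall / F1 for both subtasks.

Task A compares (gene, sentence-span) pairs under exact span identity or
partial span overlap.  Task B compares (article, gene, GO term) triples
either flat (exact term identity) or hierarchically.  "Shares a common
ancestor" is degenerate over a rooted ontology — every pair of terms
shares the root — so the hierarchical mode uses the standard ancestor-
closure precision/recall with roots excluded by default; the literal
common-ancestor relaxation is available as a flag.  All metrics are
micro-averaged over the corpus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .corpus_io import Ontology

__all__ = [
    "EvalResult", "eval_task_a", "eval_task_b_flat", "eval_task_b_hierarchical",
]

Span = tuple[int, int]
TaskAItem = tuple[str, str, Span]      # (doc_id, gene_id, half-open span)
TaskBItem = tuple[str, str, str]       # (doc_id, gene_id, GOID)


@dataclass(frozen=True)
class EvalResult:
    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    fn: int


def _result(tp: int, fp: int, fn: int) -> EvalResult:
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return EvalResult(precision=p, recall=r, f1=f1, tp=tp, fp=fp, fn=fn)


def _overlaps(a: Span, b: Span) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def eval_task_a(
    pred: Iterable[TaskAItem], gold: Iterable[TaskAItem], mode: str = "exact"
) -> EvalResult:
    """Evidence-pair metrics under exact or overlapping span matching.

    Overlap matching is greedy one-to-one in prediction order: each gold
    item can satisfy at most one prediction.
    """
    pred = sorted(set(pred))
    gold_set = set(gold)
    if mode == "exact":
        tp = len([x for x in pred if x in gold_set])
    elif mode == "overlap":
        unmatched = set(gold_set)
        tp = 0
        for doc, gene, span in pred:
            hit = next(
                (
                    g
                    for g in sorted(unmatched)
                    if g[0] == doc and g[1] == gene and _overlaps(span, g[2])
                ),
                None,
            )
            if hit is not None:
                unmatched.discard(hit)
                tp += 1
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return _result(tp, len(pred) - tp, len(gold_set) - tp)


def eval_task_b_flat(
    pred: Iterable[TaskBItem], gold: Iterable[TaskBItem]
) -> EvalResult:
    """Exact GO-term identity over (article, gene, GOID) triples."""
    pred_set, gold_set = set(pred), set(gold)
    tp = len(pred_set & gold_set)
    return _result(tp, len(pred_set) - tp, len(gold_set) - tp)


def _closure(goids: set[str], ontology: Ontology, exclude_roots: bool) -> set[str]:
    out: set[str] = set()
    for g in goids:
        out |= ontology.ancestors(g, exclude_roots=exclude_roots)
    return out


def eval_task_b_hierarchical(
    pred: Iterable[TaskBItem],
    gold: Iterable[TaskBItem],
    ontology: Ontology,
    exclude_roots: bool = True,
    mode: str = "closure",
) -> EvalResult:
    """Hierarchical metrics over ancestor closures, micro-aggregated.

    Per (article, gene): expand both GOID sets to their reflexive is_a
    closures, then hP = |∩| / |closure(pred)| and hR = |∩| / |closure(gold)|,
    with intersection and denominator counts summed over all (article,
    gene) keys before the ratio.  ``mode="common-ancestor"`` instead counts
    a term as matched when it shares any (non-root, unless included)
    ancestor with a term on the other side; its tp/fp are prediction-side
    counts and fn is the unmatched-gold count.
    """
    by_key_pred: dict[tuple[str, str], set[str]] = {}
    by_key_gold: dict[tuple[str, str], set[str]] = {}
    for doc, gene, goid in pred:
        by_key_pred.setdefault((doc, gene), set()).add(goid)
    for doc, gene, goid in gold:
        by_key_gold.setdefault((doc, gene), set()).add(goid)
    keys = set(by_key_pred) | set(by_key_gold)

    if mode == "closure":
        inter = pred_total = gold_total = 0
        for key in keys:
            cp = _closure(by_key_pred.get(key, set()), ontology, exclude_roots)
            cg = _closure(by_key_gold.get(key, set()), ontology, exclude_roots)
            inter += len(cp & cg)
            pred_total += len(cp)
            gold_total += len(cg)
        return _result(inter, pred_total - inter, gold_total - inter)

    if mode == "common-ancestor":
        matched_pred = total_pred = matched_gold = total_gold = 0
        for key in keys:
            pred_anc = {
                g: ontology.ancestors(g, exclude_roots=exclude_roots)
                for g in by_key_pred.get(key, set())
            }
            gold_anc = {
                g: ontology.ancestors(g, exclude_roots=exclude_roots)
                for g in by_key_gold.get(key, set())
            }
            total_pred += len(pred_anc)
            total_gold += len(gold_anc)
            matched_pred += sum(
                1
                for anc in pred_anc.values()
                if any(anc & ganc for ganc in gold_anc.values())
            )
            matched_gold += sum(
                1
                for ganc in gold_anc.values()
                if any(ganc & anc for anc in pred_anc.values())
            )
        p = matched_pred / total_pred if total_pred else 0.0
        r = matched_gold / total_gold if total_gold else 0.0
        f1 = 2 * p * r / (p + r) if p + r else 0.0
        return EvalResult(
            precision=p, recall=r, f1=f1,
            tp=matched_pred,
            fp=total_pred - matched_pred,
            fn=total_gold - matched_gold,
        )

    raise ValueError(f"unknown mode {mode!r}")
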