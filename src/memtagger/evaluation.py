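"""Entity-level micro precision/recall/F1 and multi-seed aggregation.

Scoring follows the CoNLL convention: predicted BIO tags are decoded to
typed spans, and a predicted span is a true positive only if its start,
end, and entity type all exactly match a gold span.  Counts are pooled
over the whole corpus (micro-averaging).  A precision or recall with a
zero denominator is 0.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from .corpus import LabeledCorpus, spans_from_bio

__all__ = ["PRF", "RunAggregate", "entity_prf", "aggregate_runs"]


@dataclass(frozen=True)
class PRF:
    """Precision, recall and F1 as fractions in [0, 1]."""

    precision: float
    recall: float
    f1: float
    tp: int = 0
    n_pred: int = 0
    n_gold: int = 0

    def as_percentages(self) -> dict[str, float]:
        return {
            "precision": 100.0 * self.precision,
            "recall": 100.0 * self.recall,
            "f1": 100.0 * self.f1,
        }


@dataclass(frozen=True)
class RunAggregate:
    """Mean and spread of F1 over repeated runs with different seeds."""

    f1_scores: tuple[float, ...]
    mean: float
    std: float


def _prf(tp: int, n_pred: int, n_gold: int) -> PRF:
    p = tp / n_pred if n_pred else 0.0
    r = tp / n_gold if n_gold else 0.0
    f1 = 2 * p * r / (p + r) if p + r > 0 else 0.0
    return PRF(p, r, f1, tp, n_pred, n_gold)


def entity_prf(gold: LabeledCorpus, pred: LabeledCorpus) -> PRF:
    """Micro-averaged exact-match entity P/R/F1 of ``pred`` against ``gold``.

    Both corpora must have identical sentence and token structure.
    """
    if len(gold) != len(pred):
        raise ValueError(f"{len(gold)} gold vs {len(pred)} predicted sentences")
    tp = n_pred = n_gold = 0
    for i, (g, p) in enumerate(zip(gold, pred)):
        if g.words != p.words:
            raise ValueError(f"sentence {i}: token mismatch between gold and pred")
        if g.tags is None or p.tags is None:
            raise ValueError(f"sentence {i}: missing tags")
        gspans = set(spans_from_bio(g.tags))
        pspans = set(spans_from_bio(p.tags))
        tp += len(gspans & pspans)
        n_pred += len(pspans)
        n_gold += len(gspans)
    return _prf(tp, n_pred, n_gold)


def entity_prf_by_type(gold: LabeledCorpus, pred: LabeledCorpus) -> dict[str, PRF]:
    """Per-entity-type breakdown with the same matching rule."""
    tp: Counter = Counter()
    n_pred: Counter = Counter()
    n_gold: Counter = Counter()
    for g, p in zip(gold, pred):
        gspans = set(spans_from_bio(g.tags or []))
        pspans = set(spans_from_bio(p.tags or []))
        for sp in gspans:
            n_gold[sp.etype] += 1
        for sp in pspans:
            n_pred[sp.etype] += 1
        for sp in gspans & pspans:
            tp[sp.etype] += 1
    return {t: _prf(tp[t], n_pred[t], n_gold[t])
            for t in sorted(set(n_gold) | set(n_pred))}


def aggregate_runs(f1_scores: Sequence[float], ddof: int = 0) -> RunAggregate:
    """Mean and standard deviation of per-seed F1 scores.

    ``ddof=0`` (default) gives the population standard deviation; a single
    run has std 0.
    """
    if len(f1_scores) == 0:
        raise ValueError("need at least one F1 score")
    n = len(f1_scores)
    mean = sum(f1_scores) / n
    if n - ddof <= 0:
        std = 0.0
    else:
        std = math.sqrt(sum((x - mean) ** 2 for x in f1_scores) / (n - ddof))
    return RunAggregate(tuple(f1_scores), mean, std)
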