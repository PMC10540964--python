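"""Ranked-retrieval evaluation: precision, average precision, mAP, and
the max/min/avg summary, plus the phantom ground-truth relevance rule.

Precision is TP/(TP+FP) over the returned list. Average precision is the
mean, over the ranks RK at which relevant items appear, of the precision
of the list truncated at RK; mAP averages AP over queries. A query whose
ranking contains no relevant item gets AP = 0 by convention (the ratio
is 0/0 there).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Sequence, Tuple


class ValidationError(ValueError):
    pass


@dataclass
class RankedJudgment:
    """A query's ranked result ids with binary relevance flags."""

    query_id: str
    ranked_ids: List[int]
    relevance: List[int]

    def __post_init__(self) -> None:
        if len(self.ranked_ids) != len(self.relevance):
            raise ValidationError("ranked_ids and relevance lengths differ")
        if any(r not in (0, 1) for r in self.relevance):
            raise ValidationError("relevance flags must be 0 or 1")


def precision(judgment: RankedJudgment) -> float:
    """TP / (TP + FP) over the whole returned list."""
    n = len(judgment.relevance)
    if n == 0:
        raise ValidationError("precision of an empty result list is undefined")
    return sum(judgment.relevance) / n


def average_precision(judgment: RankedJudgment, denominator: str = "relevant") -> float:
    """Mean precision-at-RK over the ranks RK of the relevant items.

    ``denominator='relevant'`` (the standard reading) divides by the
    number of relevant retrieved items; ``'list'`` divides by the list
    length instead, an alternative reading of the same formula.
    """
    if len(judgment.relevance) == 0:
        raise ValidationError("empty result list")
    if denominator not in ("relevant", "list"):
        raise ValidationError(f"unknown denominator {denominator!r}")
    hits = 0
    prec_sum = 0.0
    for rank, rel in enumerate(judgment.relevance, start=1):
        if rel:
            hits += 1
            prec_sum += hits / rank
    if hits == 0:
        warnings.warn(f"query {judgment.query_id!r}: no relevant item retrieved; AP=0",
                      stacklevel=2)
        return 0.0
    denom = hits if denominator == "relevant" else len(judgment.relevance)
    return prec_sum / denom


def mean_ap(judgments: Sequence[RankedJudgment], **kwargs) -> float:
    """Arithmetic mean of per-query average precisions."""
    if len(judgments) == 0:
        raise ValidationError("mean_ap of zero queries")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sum(average_precision(j, **kwargs) for j in judgments) / len(judgments)


def summarize(values: Sequence[float]) -> Tuple[float, float, float]:
    """(max, min, avg) of a non-empty collection of scores."""
    vals = list(values)
    if not vals:
        raise ValidationError("summarize of an empty collection")
    return max(vals), min(vals), sum(vals) / len(vals)


def phantom_relevance(query_case: str, query_layer: int, result_case: str,
                      result_layer: int, max_gap: int = 2) -> int:
    """Ground truth for phantom experiments: relevant iff the result comes
    from the same case within ``max_gap`` layers of the query."""
    return int(query_case == result_case and abs(query_layer - result_layer) <= max_gap)
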