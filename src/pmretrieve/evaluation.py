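"""Rank-quality metrics with trec_eval-compatible conventions.

Metrics: precision at fixed cutoffs (P@k for k in 5..1000), R-precision,
average precision (AP/MAP), and NDCG with exponential gain ``2^grade - 1``
and ``log2(rank + 1)`` discount evaluated at the full run depth.
Conventions: documents not present in the qrels count as non-relevant;
binary metrics treat grade >= 1 as relevant while NDCG uses the raw grades;
per-topic values are macro-averaged.  The composite index
``P@10 x R-Prec`` (the product of the two means) summarizes the
precision/recall trade-off the way F1 summarizes precision and recall.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .corpus import QrelEntry, RunEntry

__all__ = [
    "MetricReport", "DEFAULT_CUTOFFS",
    "precision_at_k", "recall_at_k", "r_precision", "average_precision",
    "ndcg", "pr_curve", "report", "group_run", "group_qrels",
]

DEFAULT_CUTOFFS = (5, 10, 15, 20, 30, 100, 200, 500, 1000)


def precision_at_k(ranked: Sequence[str], relevant: set[str], k: int) -> float:
    """|top-k ∩ relevant| / k; a run shorter than k is padded with
    non-relevant slots (unjudged-as-irrelevant convention)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return sum(1 for pmid in ranked[:k] if pmid in relevant) / k


def recall_at_k(ranked: Sequence[str], relevant: set[str], k: int) -> float:
    if not relevant:
        return 0.0
    return sum(1 for pmid in ranked[:k] if pmid in relevant) / len(relevant)


def r_precision(ranked: Sequence[str], relevant: set[str]) -> float:
    """Precision at depth R = number of relevant documents; 0 when R = 0."""
    if not relevant:
        return 0.0
    r = len(relevant)
    return sum(1 for pmid in ranked[:r] if pmid in relevant) / r


def average_precision(ranked: Sequence[str], relevant: set[str]) -> float:
    """Mean over relevant documents of the precision at their rank;
    relevant documents never retrieved contribute 0 (division by R)."""
    if not relevant:
        return 0.0
    hits = 0
    total = 0.0
    for rank, pmid in enumerate(ranked, start=1):
        if pmid in relevant:
            hits += 1
            total += hits / rank
    return total / len(relevant)


def ndcg(ranked: Sequence[str], grades: Mapping[str, int]) -> float:
    """Normalized DCG at the full run depth with gain 2^grade - 1 and
    log2(rank+1) discount; the ideal ranking orders all judged documents by
    descending grade."""
    def gain(grade: int) -> float:
        return (2 ** grade) - 1

    dcg = sum(gain(grades.get(pmid, 0)) / math.log2(rank + 1)
              for rank, pmid in enumerate(ranked, start=1))
    ideal_grades = sorted((g for g in grades.values() if g > 0), reverse=True)
    idcg = sum(gain(g) / math.log2(rank + 1)
               for rank, g in enumerate(ideal_grades, start=1))
    return dcg / idcg if idcg > 0 else 0.0


@dataclass
class MetricReport:
    """Per-topic and mean metric values for one run."""

    per_topic: dict[str, dict[str, float]] = field(default_factory=dict)
    mean: dict[str, float] = field(default_factory=dict)

    @property
    def p10_x_rprec(self) -> float:
        return self.mean.get("p10", 0.0) * self.mean.get("rprec", 0.0)

    def to_dict(self) -> dict:
        payload = {"mean": dict(self.mean), "per_topic": self.per_topic}
        payload["mean"]["p10_x_rprec"] = self.p10_x_rprec
        return payload


def group_run(entries: Iterable[RunEntry]) -> dict[str, list[str]]:
    """Run entries -> per-topic pmid lists in rank order."""
    by_topic: dict[str, list[RunEntry]] = {}
    for entry in entries:
        by_topic.setdefault(entry.topic_id, []).append(entry)
    return {topic: [e.pmid for e in sorted(rows, key=lambda r: r.rank)]
            for topic, rows in by_topic.items()}


def group_qrels(entries: Iterable[QrelEntry]) -> dict[str, dict[str, int]]:
    by_topic: dict[str, dict[str, int]] = {}
    for entry in entries:
        by_topic.setdefault(entry.topic_id, {})[entry.pmid] = entry.grade
    return by_topic


def _relevant(grades: Mapping[str, int], threshold: int = 1) -> set[str]:
    return {pmid for pmid, grade in grades.items() if grade >= threshold}


def pr_curve(run: Iterable[RunEntry], qrels: Iterable[QrelEntry],
             cutoffs: Sequence[int] = DEFAULT_CUTOFFS
             ) -> list[tuple[float, float]]:
    """Mean (recall, precision) over topics at each cutoff, for PR plots."""
    ranked_by_topic = group_run(run)
    grades_by_topic = group_qrels(qrels)
    topics = [t for t in ranked_by_topic if t in grades_by_topic]
    points = []
    for k in cutoffs:
        precisions, recalls = [], []
        for topic in topics:
            relevant = _relevant(grades_by_topic[topic])
            precisions.append(precision_at_k(ranked_by_topic[topic], relevant, k))
            recalls.append(recall_at_k(ranked_by_topic[topic], relevant, k))
        points.append((_mean(recalls), _mean(precisions)))
    return points


def _mean(values: Sequence[float]) -> float:
    return sum(values) / len(values) if values else 0.0


def report(run: Iterable[RunEntry], qrels: Iterable[QrelEntry],
           cutoffs: Sequence[int] = DEFAULT_CUTOFFS) -> MetricReport:
    """Aggregate all metrics for a run against qrels.

    Topics present in the run but absent from the qrels are skipped with a
    warning; means are macro-averages over evaluated topics.
    """
    ranked_by_topic = group_run(run)
    grades_by_topic = group_qrels(qrels)
    result = MetricReport()
    skipped = [t for t in ranked_by_topic if t not in grades_by_topic]
    if skipped:
        warnings.warn(f"topics absent from qrels skipped: {sorted(skipped)}",
                      stacklevel=2)
    for topic in sorted(set(ranked_by_topic) & set(grades_by_topic)):
        ranked = ranked_by_topic[topic]
        grades = grades_by_topic[topic]
        relevant = _relevant(grades)
        row = {
            "rprec": r_precision(ranked, relevant),
            "map": average_precision(ranked, relevant),
            "ndcg": ndcg(ranked, grades),
        }
        for k in cutoffs:
            row[f"p{k}"] = precision_at_k(ranked, relevant, k)
            row[f"recall{k}"] = recall_at_k(ranked, relevant, k)
        result.per_topic[topic] = row
    if result.per_topic:
        keys = next(iter(result.per_topic.values())).keys()
        result.mean = {key: _mean([row[key] for row in result.per_topic.values()])
                       for key in keys}
    return result
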