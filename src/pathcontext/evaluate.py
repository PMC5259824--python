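"""Evaluation of a ranked pathway list against a relevant set π*.

Three complementary views:

* **PSEA** — a GSEA-style running sum over the ranked list.  Walking ranks
  i = 1..n, the sum rises by r_i / Σr when the i-th pathway is relevant
  (r_i = n − i + 1, the impact of rank i; Σr is the total of r_i over the
  ranks relevant pathways occupy) and falls by 1/|π−| otherwise.  Up-moves
  and down-moves each total 1, so RS(n) = 0 and the Enrichment Score
  ES = max RS lies in [0, 1], hitting 1 exactly when every relevant
  pathway precedes every irrelevant one.
* **KS D** — the two-sample Kolmogorov–Smirnov distance between the rank
  positions of π* and π−: how separated the two groups are in the list.
* **F1** — precision/recall of a significant set against π*.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import RelevanceLabelSet

__all__ = [
    "PSEATrace",
    "KSResult",
    "ClassificationMetrics",
    "psea_trace",
    "enrichment_score",
    "ks_separation",
    "f1_metrics",
]


@dataclass(frozen=True)
class PSEATrace:
    """Running-sum trajectory RS(0..n), its maximum ES, and the Σr used."""

    rs: tuple[float, ...]
    es: float
    increments_basis: float


@dataclass(frozen=True)
class KSResult:
    d: float


@dataclass(frozen=True)
class ClassificationMetrics:
    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    fn: int


def _check_groups(ranked: Sequence[str], labels: RelevanceLabelSet) -> None:
    if set(ranked) != set(labels.universe):
        raise ValueError("ranked list must cover exactly the label universe")
    if not labels.relevant_ids or not labels.irrelevant_ids:
        raise ValueError("both π* and π− must be non-empty")


def psea_trace(ranked: Sequence[str], labels: RelevanceLabelSet) -> PSEATrace:
    """Running sum over the ranked list; see the module docstring."""
    _check_groups(ranked, labels)
    n = len(ranked)
    relevant = labels.relevant_ids
    sum_r = float(sum(n - i + 1 for i, pid in enumerate(ranked, start=1) if pid in relevant))
    down = 1.0 / len(labels.irrelevant_ids)
    rs = [0.0]
    for i, pid in enumerate(ranked, start=1):
        step = (n - i + 1) / sum_r if pid in relevant else -down
        rs.append(rs[-1] + step)
    trace = tuple(rs)
    return PSEATrace(rs=trace, es=max(trace), increments_basis=sum_r)


def enrichment_score(trace: PSEATrace) -> float:
    """ES = max_i RS(i), i = 0..n."""
    return max(trace.rs)


def ks_separation(ranked: Sequence[str], labels: RelevanceLabelSet) -> KSResult:
    """Two-sample KS D between rank positions of π* and π−.

    D = max over rank cutoffs x of |F*(x) − F−(x)|, where F* and F− are the
    empirical distribution functions of the 1-based rank positions of the
    two groups.  Computed by a direct sweep over the n cutoffs.
    """
    _check_groups(ranked, labels)
    n = len(ranked)
    rel = np.fromiter((pid in labels.relevant_ids for pid in ranked), dtype=bool, count=n)
    f_star = np.cumsum(rel) / rel.sum()
    f_minus = np.cumsum(~rel) / (~rel).sum()
    return KSResult(d=float(np.max(np.abs(f_star - f_minus))))


def f1_metrics(predicted: set[str], labels: RelevanceLabelSet) -> ClassificationMetrics:
    """Precision, recall and F1 of a predicted-significant set against π*.

    Conventions: an empty prediction has precision 0, an empty π* would
    have recall 0, and F1 is 0 whenever precision + recall is 0.
    """
    extra = predicted - labels.universe
    if extra:
        raise ValueError(f"predicted ids outside universe: {sorted(extra)}")
    tp = len(predicted & labels.relevant_ids)
    fp = len(predicted - labels.relevant_ids)
    fn = len(labels.relevant_ids - predicted)
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    return ClassificationMetrics(precision=precision, recall=recall, f1=f1, tp=tp, fp=fp, fn=fn)
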