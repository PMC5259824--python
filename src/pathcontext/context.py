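"""Context Scores: posterior relevance of each pathway to a keyword.

Literature entity scores are unbounded nonnegative reals.  They are mapped
to probability-like quantities with a logarithm whose base is tied to the
maximum observed score:

    P(k | π_i) = log_b(s_i + 1),   b = s_max + 2

so the largest score maps just below 1 and a zero score maps exactly to 0.
The same transform applied to total evidence t_i gives the prior P(π_i),
and Bayes' rule combines the two into the Context Score

    CS(π_i, k) = P(π_i) P(k|π_i) / Σ_j P(π_j) P(k|π_j).

The log transform is concave, deliberately: densely packed small scores
are spread apart while very large scores stay comparable, which keeps one
heavily-published pathway from swamping the posterior.

With several context keywords, per-keyword posteriors are averaged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .io import EntityScoreTable, PriorEvidenceTable

__all__ = [
    "LikelihoodVector",
    "PriorVector",
    "ContextScoreVector",
    "likelihood_from_entity_scores",
    "prior_from_evidence",
    "posterior_context_scores",
    "average_context_scores",
    "context_scores",
]


@dataclass(frozen=True)
class LikelihoodVector:
    """P(k|π_i) per pathway, with the log base b = s_max + 2 used."""

    values: Mapping[str, float]
    base_used: float


@dataclass(frozen=True)
class PriorVector:
    """P(π_i) per pathway, with the log base b = t_max + 2 used."""

    values: Mapping[str, float]
    base_used: float


@dataclass(frozen=True)
class ContextScoreVector:
    """CS(π_i, k) per pathway; a posterior for one keyword, or a mean of
    posteriors for several."""

    values: Mapping[str, float]

    def __getitem__(self, pathway_id: str) -> float:
        return self.values[pathway_id]


def _log_transform(raw: Mapping[str, float], universe: Sequence[str]) -> tuple[dict[str, float], float]:
    mx = max((float(raw.get(pid, 0.0)) for pid in universe), default=0.0)
    base = mx + 2.0
    log_base = math.log(base)
    # log1p keeps tiny-but-nonzero scores strictly positive
    return {pid: math.log1p(float(raw.get(pid, 0.0))) / log_base for pid in universe}, base


def likelihood_from_entity_scores(
    scores: EntityScoreTable, universe: Sequence[str]
) -> LikelihoodVector:
    """Map entity scores to likelihoods log_b(s_i + 1), b = s_max + 2.

    s_max is taken over the analysis universe; pathways missing from the
    table contribute s_i = 0.  When every score is zero the base is 2 and
    all likelihoods are exactly 0.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    values, base = _log_transform(scores.scores, universe)
    return LikelihoodVector(values=values, base_used=base)


def prior_from_evidence(totals: PriorEvidenceTable, universe: Sequence[str]) -> PriorVector:
    """Map total evidence to priors log_b(t_i + 1), b = t_max + 2."""
    if not universe:
        raise ValueError("universe must be non-empty")
    values, base = _log_transform(totals.totals, universe)
    return PriorVector(values=values, base_used=base)


def posterior_context_scores(
    likelihood: LikelihoodVector, prior: PriorVector
) -> ContextScoreVector:
    """Bayes posterior CS_i = P(π_i)P(k|π_i) / Σ_j P(π_j)P(k|π_j).

    A zero denominator (no literature signal at all) yields the all-zero
    vector rather than an error, so the pipeline degrades gracefully to a
    pure expression ranking.
    """
    if set(likelihood.values) != set(prior.values):
        raise ValueError("likelihood and prior must cover the same universe")
    num = {pid: prior.values[pid] * likelihood.values[pid] for pid in likelihood.values}
    denom = sum(num.values())
    if denom <= 0.0:
        return ContextScoreVector(values={pid: 0.0 for pid in num})
    return ContextScoreVector(values={pid: v / denom for pid, v in num.items()})


def average_context_scores(per_keyword: Sequence[ContextScoreVector]) -> ContextScoreVector:
    """Arithmetic mean of per-keyword Context Score vectors."""
    if not per_keyword:
        raise ValueError("need at least one Context Score vector")
    universe = set(per_keyword[0].values)
    for vec in per_keyword[1:]:
        if set(vec.values) != universe:
            raise ValueError("all Context Score vectors must share one universe")
    k = len(per_keyword)
    return ContextScoreVector(
        values={pid: sum(vec.values[pid] for vec in per_keyword) / k for pid in universe}
    )


def context_scores(
    entity_tables: Sequence[EntityScoreTable],
    prior_table: PriorEvidenceTable,
    universe: Sequence[str],
) -> ContextScoreVector:
    """Full context channel: per-keyword posteriors, averaged.

    Convenience wrapper chaining likelihood, prior, posterior and the
    multi-keyword mean; the prior is shared across keywords.
    """
    prior = prior_from_evidence(prior_table, universe)
    per_keyword = [
        posterior_context_scores(likelihood_from_entity_scores(tbl, universe), prior)
        for tbl in entity_tables
    ]
    return average_context_scores(per_keyword)
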