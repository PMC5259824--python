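"""Discovery-rate weighting, score combination, ranking, permutation p-values.

The Discovery rate w_θ is the fraction of pathways the expression analysis
misses (p > θ) but the literature supports (CS > 0).  It weights the linear
combination

    Score(π_i) = w·CS(π_i) + (1 − w)·IS(π_i),

so contexts rich in literature coverage lean on CS and poorly covered
contexts fall back on the expression channel.

Significance of a combined score is assessed against the permutation null
built from all n² ordered (CS_a, IS_b) recombinations across pathways.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .context import ContextScoreVector
from .impact import ImpactScoreVector
from .io import PathwaySignificanceTable

__all__ = [
    "DiscoveryRate",
    "CombinedScoreVector",
    "PermutationPValues",
    "discovery_rate",
    "combine",
    "rank",
    "permutation_pvalues",
    "select_significant",
]

#: above this universe size the n^2 null is subsampled instead of enumerated
EXACT_NULL_MAX_N = 3000


@dataclass(frozen=True)
class DiscoveryRate:
    w: float
    theta: float
    qualifying_count: int


@dataclass(frozen=True)
class CombinedScoreVector:
    values: Mapping[str, float]
    weight: float


@dataclass(frozen=True)
class PermutationPValues:
    values: Mapping[str, float]
    null_size: int


def discovery_rate(
    pvalues: PathwaySignificanceTable,
    cs: ContextScoreVector,
    theta: float = 0.05,
) -> DiscoveryRate:
    """w_θ = |{i : p_i > θ and CS_i > 0}| / n.

    Strict inequalities throughout: CS_i is exactly zero whenever the
    entity score is zero, so no epsilon is needed.
    """
    if not (0.0 < theta < 1.0):
        raise ValueError(f"theta must be in (0, 1), got {theta}")
    pv = pvalues.pvalues
    if set(pv) != set(cs.values):
        raise ValueError("p-value table and CS vector must cover the same universe")
    count = sum(1 for pid, p in pv.items() if p > theta and cs.values[pid] > 0.0)
    return DiscoveryRate(w=count / len(pv), theta=theta, qualifying_count=count)


def combine(
    cs: ContextScoreVector, is_: ImpactScoreVector, w: DiscoveryRate | float
) -> CombinedScoreVector:
    """Score_i = w·CS_i + (1 − w)·IS_i."""
    weight = w.w if isinstance(w, DiscoveryRate) else float(w)
    if not (0.0 <= weight <= 1.0):
        raise ValueError(f"weight must be in [0, 1], got {weight}")
    if set(cs.values) != set(is_.values):
        raise ValueError("CS and IS vectors must cover the same universe")
    values = {
        pid: weight * cs.values[pid] + (1.0 - weight) * is_.values[pid] for pid in cs.values
    }
    return CombinedScoreVector(values=values, weight=weight)


def rank(scores: CombinedScoreVector) -> list[str]:
    """Pathways sorted by score non-increasing; ties broken by id ascending."""
    return sorted(scores.values, key=lambda pid: (-scores.values[pid], pid))


def permutation_pvalues(
    cs: ContextScoreVector,
    is_: ImpactScoreVector,
    w: DiscoveryRate | float,
    *,
    max_exact_n: int = EXACT_NULL_MAX_N,
    n_subsample: int = 1_000_000,
    rng: np.random.Generator | None = None,
) -> PermutationPValues:
    """Permutation p-value per pathway against the recombination null.

    The null is {w·CS_a + (1−w)·IS_b} over all n² ordered pairs (a, b),
    the observed pairings included, and p_i is the fraction of null scores
    ≥ the observed Score_i.  Including the observed pair makes the minimum
    attainable p exactly 1/n².  Enumeration is exact up to ``max_exact_n``
    pathways; beyond that a seeded subsample of pairs is used.
    """
    weight = w.w if isinstance(w, DiscoveryRate) else float(w)
    if set(cs.values) != set(is_.values):
        raise ValueError("CS and IS vectors must cover the same universe")
    ids = sorted(cs.values)
    n = len(ids)
    cs_arr = np.array([cs.values[pid] for pid in ids])
    is_arr = np.array([is_.values[pid] for pid in ids])
    observed = weight * cs_arr + (1.0 - weight) * is_arr

    if n <= max_exact_n:
        null = (weight * cs_arr[:, None] + (1.0 - weight) * is_arr[None, :]).ravel()
        null_size = n * n
    else:
        rng = np.random.default_rng() if rng is None else rng
        a = rng.integers(0, n, size=n_subsample)
        b = rng.integers(0, n, size=n_subsample)
        null = np.concatenate([weight * cs_arr[a] + (1.0 - weight) * is_arr[b], observed])
        null_size = null.size

    null.sort()
    # count of null values >= observed score, via first index not below it
    ge_counts = null_size - np.searchsorted(null, observed, side="left")
    pvals = ge_counts / null_size
    return PermutationPValues(
        values={pid: float(p) for pid, p in zip(ids, pvals)}, null_size=null_size
    )


def select_significant(perm: PermutationPValues, alpha: float = 0.05) -> set[str]:
    """Pathways with permutation p strictly below ``alpha``."""
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    return {pid for pid, p in perm.values.items() if p < alpha}
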