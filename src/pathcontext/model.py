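"""Model/Results surface tying the scoring stages together.

:class:`PathwayPriorityModel` is constructed from the three input tables
(p-values, per-keyword entity scores, prior evidence); ``fit()`` runs the
full chain — likelihood/prior → posterior Context Scores (averaged over
keywords) → Impact Scores → Discovery-rate weight → combined scores →
ranking → permutation p-values — and returns a
:class:`PathwayPriorityResults` holding every intermediate quantity, a
``summary()`` table, evaluation against a relevance label set, and a PSEA
plot.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import context as _context
from . import evaluate as _evaluate
from . import impact as _impact
from . import integrate as _integrate
from .io import (
    EntityScoreTable,
    PathwaySignificanceTable,
    PriorEvidenceTable,
    RankedResult,
    RelevanceLabelSet,
    parse_label_set,
    parse_pvalue_table,
    parse_score_map,
    write_result_table,
)

__all__ = ["PathwayPriorityModel", "PathwayPriorityResults", "EvaluationReport"]


@dataclass(frozen=True)
class EvaluationReport:
    """PSEA/KS/F1 evaluation of one fitted ranking against π*."""

    trace: _evaluate.PSEATrace
    es: float
    ks_d: float
    metrics: _evaluate.ClassificationMetrics

    def summary(self) -> str:
        m = self.metrics
        lines = [
            "Evaluation against relevance labels",
            f"  Enrichment Score (ES)   {self.es:.4f}",
            f"  KS separation D         {self.ks_d:.4f}",
            f"  precision / recall / F1 {m.precision:.4f} / {m.recall:.4f} / {m.f1:.4f}",
            f"  tp / fp / fn            {m.tp} / {m.fp} / {m.fn}",
        ]
        return "\n".join(lines)


class PathwayPriorityModel:
    """Pathway prioritization combining expression p-values with literature
    context relevance.

    Parameters
    ----------
    pvalues
        Per-pathway p-values from any upstream pathway analysis.
    entity_tables
        One literature entity-score table per context keyword.
    prior
        Total literature evidence per pathway (the prior channel).
    theta
        P-value threshold for the Discovery rate (default 0.05).
    p_floor
        Clamp floor keeping -log10 p finite at p = 0.
    """

    def __init__(
        self,
        pvalues: PathwaySignificanceTable,
        entity_tables: Sequence[EntityScoreTable],
        prior: PriorEvidenceTable,
        *,
        theta: float = 0.05,
        p_floor: float = _impact.DEFAULT_P_FLOOR,
    ) -> None:
        if not entity_tables:
            raise ValueError("need at least one entity-score table")
        self.pvalues = pvalues
        self.entity_tables = tuple(entity_tables)
        self.prior = prior
        self.theta = theta
        self.p_floor = p_floor
        self.universe: tuple[str, ...] = pvalues.pathway_ids

    @classmethod
    def from_files(
        cls,
        pvalues_path: str | Path,
        entity_paths: Sequence[str | Path],
        prior_path: str | Path,
        **kwargs,
    ) -> "PathwayPriorityModel":
        """Build the model from the on-disk TSV/JSON formats."""
        pvalues = parse_pvalue_table(pvalues_path)
        entity_tables = [
            EntityScoreTable(keyword=Path(p).stem, scores=parse_score_map(p))
            for p in entity_paths
        ]
        prior = PriorEvidenceTable(totals=parse_score_map(prior_path))
        return cls(pvalues, entity_tables, prior, **kwargs)

    def fit(
        self,
        weight: float | None = None,
        *,
        seed: int | None = None,
    ) -> "PathwayPriorityResults":
        """Run the full scoring chain.

        ``weight`` overrides the estimated Discovery rate with a fixed
        value in [0, 1] (for weight sweeps); ``seed`` only matters for the
        subsampled permutation null at very large universe sizes.
        """
        cs = _context.context_scores(self.entity_tables, self.prior, self.universe)
        raw = _impact.raw_impact(self.pvalues, self.p_floor)
        is_ = _impact.normalize_impact(raw, cs)
        dr = _integrate.discovery_rate(self.pvalues, cs, self.theta)
        w = dr.w if weight is None else float(weight)
        scores = _integrate.combine(cs, is_, w)
        ranked = _integrate.rank(scores)
        rng = np.random.default_rng(seed) if seed is not None else None
        perm = _integrate.permutation_pvalues(cs, is_, w, rng=rng)
        return PathwayPriorityResults(
            model=self,
            context_scores=cs,
            impact_scores=is_,
            discovery_rate=dr,
            weight=w,
            combined=scores,
            ranking=tuple(ranked),
            perm_pvalues=perm,
        )


@dataclass(frozen=True)
class PathwayPriorityResults:
    """Fitted prioritization: scores, ranking and permutation p-values."""

    model: PathwayPriorityModel
    context_scores: _context.ContextScoreVector
    impact_scores: _impact.ImpactScoreVector
    discovery_rate: _integrate.DiscoveryRate
    weight: float
    combined: _integrate.CombinedScoreVector
    ranking: tuple[str, ...]
    perm_pvalues: _integrate.PermutationPValues

    @property
    def table(self) -> pd.DataFrame:
        """One row per pathway in rank order."""
        names = self.model.pvalues.names
        pv = self.model.pvalues.pvalues
        return pd.DataFrame(
            {
                "rank": range(1, len(self.ranking) + 1),
                "pathway_id": self.ranking,
                "pathway_name": [names[pid] for pid in self.ranking],
                "p_value": [pv[pid] for pid in self.ranking],
                "CS": [self.context_scores.values[pid] for pid in self.ranking],
                "IS": [self.impact_scores.values[pid] for pid in self.ranking],
                "score": [self.combined.values[pid] for pid in self.ranking],
                "perm_p": [self.perm_pvalues.values[pid] for pid in self.ranking],
            }
        )

    def significant(self, alpha: float = 0.05) -> set[str]:
        """Pathways with permutation p < alpha."""
        return _integrate.select_significant(self.perm_pvalues, alpha)

    def as_ranked_result(self) -> RankedResult:
        rows = tuple(
            (
                i,
                pid,
                self.context_scores.values[pid],
                self.impact_scores.values[pid],
                self.combined.values[pid],
                self.perm_pvalues.values[pid],
            )
            for i, pid in enumerate(self.ranking, start=1)
        )
        return RankedResult(rows=rows, weight=self.weight)

    def to_tsv(self, path: str | Path) -> None:
        write_result_table(self.as_ranked_result(), path)

    def evaluate(self, labels: RelevanceLabelSet, alpha: float = 0.05) -> EvaluationReport:
        """PSEA trace/ES, KS D, and F1 of the permutation-significant set."""
        trace = _evaluate.psea_trace(self.ranking, labels)
        ks = _evaluate.ks_separation(self.ranking, labels)
        metrics = _evaluate.f1_metrics(self.significant(alpha), labels)
        return EvaluationReport(trace=trace, es=trace.es, ks_d=ks.d, metrics=metrics)

    def evaluate_from_file(self, path: str | Path, *, strict: bool = True, alpha: float = 0.05) -> EvaluationReport:
        labels = parse_label_set(path, self.model.universe, strict=strict)
        return self.evaluate(labels, alpha=alpha)

    def summary(self, top: int = 10) -> str:
        """Human-readable fit summary: weight, θ, and the top of the ranking."""
        dr = self.discovery_rate
        head = self.table.head(top)
        lines = [
            "Pathway prioritization results",
            "==============================",
            f"pathways: {len(self.ranking)}   keywords: {len(self.model.entity_tables)}",
            f"Discovery rate w = {dr.w:.4f} ({dr.qualifying_count}/{len(self.ranking)} "
            f"with p > {dr.theta:g} and CS > 0)",
            f"weight used: {self.weight:.4f}"
            + ("  (estimated)" if self.weight == dr.w else "  (override)"),
            f"permutation null size: {self.perm_pvalues.null_size}",
            "",
            head.to_string(
                index=False,
                formatters={
                    c: (lambda v: f"{v:.4f}") for c in ("p_value", "CS", "IS", "score", "perm_p")
                },
            ),
        ]
        return "\n".join(lines)

    def plot_psea(self, labels: RelevanceLabelSet, ax=None):
        """Plot the PSEA running sum; relevant-pathway ranks are ticked."""
        import matplotlib.pyplot as plt

        trace = _evaluate.psea_trace(self.ranking, labels)
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 3.5))
        ax.plot(range(len(trace.rs)), trace.rs, lw=1.5)
        hits = [i for i, pid in enumerate(self.ranking, start=1) if pid in labels.relevant_ids]
        ax.plot(hits, [0.0] * len(hits), "|", color="crimson", ms=12)
        ax.axhline(0.0, color="grey", lw=0.5)
        ax.set_xlabel("rank")
        ax.set_ylabel("running sum RS")
        ax.set_title(f"PSEA (ES = {trace.es:.3f})")
        return ax
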