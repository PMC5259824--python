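"""Seeded synthetic benchmarks with planted context-relevant pathways.

The generator emulates the structure of a real study: a universe of
pathways scored for expression significance (p-values) and for literature
relevance (per-keyword entity scores), with a known relevant subset π*.
Relevant pathways tend to have small p-values — drawn from Beta(a_sig, 1),
the standard one-parameter alternative whose a_sig = 1 case recovers the
Uniform(0, 1) null — except for a ``miss_rate`` fraction whose p-value is
null-distributed: the pathways the expression analysis misses but the
literature still covers, which is exactly the signal the Discovery rate
is designed to detect.  Entity scores are lognormal (right-skewed, like
citation-weighted literature scores) with a higher location for relevant
pathways; prior evidence totals are drawn independently of the labels so
the posterior behaviour in tests is driven by the likelihood channel.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import (
    EntityScoreTable,
    PathwaySignificanceTable,
    PriorEvidenceTable,
    RelevanceLabelSet,
)

__all__ = ["SyntheticConfig", "SyntheticDataset", "generate", "worked_toy"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator knobs.  Defaults are the benchmark study conditions.

    ``expression_effect`` is the Beta shape a_sig for relevant p-values
    (smaller = stronger signal; 1 = null).  ``miss_rate`` is the fraction
    of relevant pathways whose p-value is drawn from the null anyway.
    ``literature_coverage`` / ``spurious_rate`` are the probabilities that
    a relevant / background pathway has a nonzero entity score, and the
    two ``*_score_scale`` values are the lognormal medians of those scores.
    """

    n_pathways: int = 200
    n_relevant: int = 15
    expression_effect: float = 0.1
    miss_rate: float = 0.3
    literature_coverage: float = 0.8
    spurious_rate: float = 0.05
    relevant_score_scale: float = 50.0
    background_score_scale: float = 5.0
    score_sigma: float = 1.0
    prior_scale: float = 20.0
    n_keywords: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.n_relevant < self.n_pathways):
            raise ValueError("need 0 < n_relevant < n_pathways")
        for name in ("miss_rate", "literature_coverage", "spurious_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not (0.0 < self.expression_effect <= 1.0):
            raise ValueError("expression_effect must be in (0, 1]")
        if self.n_keywords < 1:
            raise ValueError("need at least one keyword")


@dataclass(frozen=True)
class SyntheticDataset:
    pvalues: PathwaySignificanceTable
    entity_tables: tuple[EntityScoreTable, ...]
    prior: PriorEvidenceTable
    labels: RelevanceLabelSet
    config_used: SyntheticConfig

    def write(self, outdir: str | Path) -> None:
        """Write the dataset in the pipeline's TSV formats plus a JSON manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "pvalues.tsv", "w", encoding="utf-8") as fh:
            fh.write("pathway_id\tpathway_name\tp_value\n")
            for pid, name, p in self.pvalues.entries:
                fh.write(f"{pid}\t{name}\t{p:.8g}\n")
        for tbl in self.entity_tables:
            with open(outdir / f"entity_{tbl.keyword}.tsv", "w", encoding="utf-8") as fh:
                fh.write(f"# keyword\t{tbl.keyword}\n")
                for pid, s in sorted(tbl.scores.items()):
                    if s > 0:
                        fh.write(f"{pid}\t{s:.8g}\n")
        with open(outdir / "prior.tsv", "w", encoding="utf-8") as fh:
            for pid, t in sorted(self.prior.totals.items()):
                fh.write(f"{pid}\t{t:.8g}\n")
        with open(outdir / "labels.txt", "w", encoding="utf-8") as fh:
            for pid in sorted(self.labels.relevant_ids):
                fh.write(pid + "\n")
        with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self.config_used), fh, indent=2)
            fh.write("\n")


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Draw one dataset; fully determined by ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_pathways
    ids = [f"PW{i:04d}" for i in range(1, n + 1)]
    relevant = set(rng.choice(ids, size=config.n_relevant, replace=False).tolist())

    entries = []
    for pid in ids:
        if pid in relevant and rng.random() >= config.miss_rate:
            p = float(rng.beta(config.expression_effect, 1.0))
        else:
            p = float(rng.uniform())
        entries.append((pid, f"pathway {pid[2:]}", p))

    def entity_scores(keyword: str) -> EntityScoreTable:
        scores: dict[str, float] = {}
        for pid in ids:
            if pid in relevant:
                covered, scale = rng.random() < config.literature_coverage, config.relevant_score_scale
            else:
                covered, scale = rng.random() < config.spurious_rate, config.background_score_scale
            if covered:
                scores[pid] = float(rng.lognormal(np.log(scale), config.score_sigma))
        return EntityScoreTable(keyword=keyword, scores=scores)

    entity_tables = tuple(entity_scores(f"kw{j + 1}") for j in range(config.n_keywords))
    prior = PriorEvidenceTable(
        totals={
            pid: float(rng.lognormal(np.log(config.prior_scale), config.score_sigma))
            for pid in ids
        }
    )
    labels = RelevanceLabelSet(relevant_ids=frozenset(relevant), universe=frozenset(ids))
    return SyntheticDataset(
        pvalues=PathwaySignificanceTable(entries=tuple(entries)),
        entity_tables=entity_tables,
        prior=prior,
        labels=labels,
        config_used=config,
    )


def worked_toy() -> SyntheticDataset:
    """The fixed six-pathway fixture behind the hand-checked examples.

    P1..P6 with p = 0.001, 0.02, 0.04, 0.2, 0.5, 0.9; one keyword with
    entity scores 8, 0, 3, 6, 0, 0; a uniform prior of 5; π* = {P1, P3, P4}.
    P4 is the planted "missed by expression, found in literature" case
    (p = 0.2 > 0.05 but entity score 6), so the Discovery rate is 1/6.
    """
    ids = ["P1", "P2", "P3", "P4", "P5", "P6"]
    pvals = [0.001, 0.02, 0.04, 0.2, 0.5, 0.9]
    entries = tuple((pid, f"toy pathway {pid}", p) for pid, p in zip(ids, pvals))
    entity = EntityScoreTable(keyword="toy", scores={"P1": 8.0, "P3": 3.0, "P4": 6.0})
    prior = PriorEvidenceTable(totals={pid: 5.0 for pid in ids})
    labels = RelevanceLabelSet(
        relevant_ids=frozenset({"P1", "P3", "P4"}), universe=frozenset(ids)
    )
    config = SyntheticConfig(n_pathways=6, n_relevant=3, seed=0)
    return SyntheticDataset(
        pvalues=PathwaySignificanceTable(entries=entries),
        entity_tables=(entity,),
        prior=prior,
        labels=labels,
        config_used=config,
    )
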