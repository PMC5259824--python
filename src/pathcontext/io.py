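"""Domain types and tabular I/O.

Every table the pipeline consumes or emits is plain TSV (tab delimiter,
``#`` comment lines, UTF-8, header required where noted) or, for score
maps, an equivalent flat JSON object.  Pathway identifiers are opaque
strings; KEGG-style ids such as ``hsa04010`` are typical but nothing is
assumed about their shape.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "FormatError",
    "PathwaySignificanceTable",
    "EntityScoreTable",
    "PriorEvidenceTable",
    "RelevanceLabelSet",
    "RankedResult",
    "parse_pvalue_table",
    "parse_score_map",
    "parse_label_set",
    "write_result_table",
    "parse_result_table",
]


class FormatError(ValueError):
    """An input file violates the expected tabular format."""


@dataclass(frozen=True)
class PathwaySignificanceTable:
    """Per-pathway p-values from an upstream pathway analysis.

    ``entries`` is an ordered list of ``(pathway_id, pathway_name, p_value)``
    tuples; ``universe_size`` always equals ``len(entries)``.
    """

    entries: tuple[tuple[str, str, float], ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for pid, _, _ in self.entries:
            if pid in seen:
                raise FormatError(f"duplicate pathway_id {pid!r}")
            seen.add(pid)
        for pid, _, p in self.entries:
            if not (0.0 <= p <= 1.0) or math.isnan(p):
                raise FormatError(f"p_value {p!r} for {pid!r} outside [0, 1]")

    @property
    def universe_size(self) -> int:
        return len(self.entries)

    @property
    def pathway_ids(self) -> tuple[str, ...]:
        return tuple(e[0] for e in self.entries)

    @property
    def pvalues(self) -> dict[str, float]:
        return {e[0]: e[2] for e in self.entries}

    @property
    def names(self) -> dict[str, str]:
        return {e[0]: e[1] for e in self.entries}


@dataclass(frozen=True)
class EntityScoreTable:
    """Literature entity scores ``s_i`` for one context keyword.

    A pathway absent from ``scores`` has ``s_i = 0``: literature indexes
    rarely cover every pathway, and the scoring formulas are defined at
    zero, so missing-as-zero is the contract throughout.
    """

    keyword: str
    scores: Mapping[str, float]

    def __post_init__(self) -> None:
        for pid, s in self.scores.items():
            if s < 0 or math.isnan(s):
                raise FormatError(f"entity score {s!r} for {pid!r} is negative")

    def score(self, pathway_id: str) -> float:
        return float(self.scores.get(pathway_id, 0.0))


@dataclass(frozen=True)
class PriorEvidenceTable:
    """Total literature evidence ``t_i`` per pathway (prior channel)."""

    totals: Mapping[str, float]

    def __post_init__(self) -> None:
        for pid, t in self.totals.items():
            if t < 0 or math.isnan(t):
                raise FormatError(f"evidence total {t!r} for {pid!r} is negative")

    def total(self, pathway_id: str) -> float:
        return float(self.totals.get(pathway_id, 0.0))


@dataclass(frozen=True)
class RelevanceLabelSet:
    """The context-relevant pathway set π* within a fixed universe."""

    relevant_ids: frozenset[str]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        extra = self.relevant_ids - self.universe
        if extra:
            raise ValueError(f"relevant ids outside universe: {sorted(extra)}")

    @property
    def irrelevant_ids(self) -> frozenset[str]:
        """The complement π− = universe ∖ π*."""
        return self.universe - self.relevant_ids


@dataclass(frozen=True)
class RankedResult:
    """Final prioritized pathway list with the weight used to build it.

    ``rows``: ordered ``(rank, pathway_id, cs, is_, score, perm_p)`` tuples,
    sorted by combined score non-increasing, ranks 1..n with no gaps.
    """

    rows: tuple[tuple[int, str, float, float, float, float], ...]
    weight: float

    def __post_init__(self) -> None:
        for pos, row in enumerate(self.rows, start=1):
            if row[0] != pos:
                raise ValueError(f"ranks must be 1..n with no gaps, got {row[0]} at position {pos}")
        scores = [r[4] for r in self.rows]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise ValueError("rows must be sorted by combined score non-increasing")

    @property
    def pathway_ids(self) -> tuple[str, ...]:
        return tuple(r[1] for r in self.rows)


# ---------------------------------------------------------------------------
# parsing


def _data_lines(path: str | Path) -> Iterable[tuple[int, str]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def parse_pvalue_table(path: str | Path) -> PathwaySignificanceTable:
    """Read a pathway significance TSV with header
    ``pathway_id<TAB>pathway_name<TAB>p_value``."""
    rows = list(_data_lines(path))
    if not rows:
        raise FormatError(f"{path}: empty file, header required")
    header = rows[0][1].split("\t")
    expected = ["pathway_id", "pathway_name", "p_value"]
    if [h.strip() for h in header[:3]] != expected:
        raise FormatError(f"{path}: header must be {expected}, got {header}")
    entries: list[tuple[str, str, float]] = []
    seen: set[str] = set()
    for lineno, line in rows[1:]:
        parts = line.split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{lineno}: expected 3 tab-separated columns")
        pid, name, pstr = parts[0].strip(), parts[1].strip(), parts[2].strip()
        if pid in seen:
            raise FormatError(f"{path}:{lineno}: duplicate pathway_id {pid!r}")
        seen.add(pid)
        try:
            p = float(pstr)
        except ValueError:
            raise FormatError(f"{path}:{lineno}: p_value {pstr!r} is not numeric") from None
        if not (0.0 <= p <= 1.0) or math.isnan(p):
            raise FormatError(f"{path}:{lineno}: p_value {p} outside [0, 1]")
        entries.append((pid, name, p))
    return PathwaySignificanceTable(entries=tuple(entries))


def parse_score_map(path: str | Path) -> dict[str, float]:
    """Read a pathway→score map from two-column TSV or a flat JSON object.

    Scores must be nonnegative and finite.  An empty file yields an empty
    mapping: every pathway then scores zero downstream.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path, encoding="utf-8") as fh:
            text = fh.read().strip()
        obj = json.loads(text) if text else {}
        if not isinstance(obj, dict):
            raise FormatError(f"{path}: JSON score map must be a flat object")
        out: dict[str, float] = {}
        for pid, val in obj.items():
            try:
                score = float(val)
            except (TypeError, ValueError):
                raise FormatError(f"{path}: score {val!r} for {pid!r} is not numeric") from None
            if score < 0 or math.isnan(score):
                raise FormatError(f"{path}: score {score} for {pid!r} is negative")
            out[pid] = score
        return out

    out = {}
    rows = list(_data_lines(path))
    # optional header row, recognised by its first cell only
    if rows and rows[0][1].split("\t")[0].strip() == "pathway_id":
        rows = rows[1:]
    for lineno, line in rows:
        parts = line.split("\t")
        if len(parts) < 2:
            raise FormatError(f"{path}:{lineno}: expected 2 tab-separated columns")
        pid, sstr = parts[0].strip(), parts[1].strip()
        try:
            score = float(sstr)
        except ValueError:
            raise FormatError(f"{path}:{lineno}: score {sstr!r} is not numeric") from None
        if score < 0 or math.isnan(score):
            raise FormatError(f"{path}:{lineno}: score {score} is negative")
        if pid in out:
            raise FormatError(f"{path}:{lineno}: duplicate pathway_id {pid!r}")
        out[pid] = score
    return out


def parse_label_set(
    path: str | Path,
    universe: Iterable[str],
    *,
    strict: bool = True,
) -> RelevanceLabelSet:
    """Read a newline-separated list of relevant pathway ids (π*).

    Ids outside ``universe`` raise in strict mode; in lenient mode they are
    dropped (callers may log a warning with the returned set sizes).
    """
    uni = frozenset(universe)
    ids: set[str] = set()
    for lineno, line in _data_lines(path):
        pid = line.strip()
        if pid not in uni:
            if strict:
                raise FormatError(f"{path}:{lineno}: pathway id {pid!r} not in universe")
            continue
        ids.add(pid)
    return RelevanceLabelSet(relevant_ids=frozenset(ids), universe=uni)


def write_result_table(result: RankedResult, path: str | Path) -> None:
    """Write a ranked result as TSV.

    A leading ``#`` comment records the discovery-rate weight; numeric
    fields are rendered with 8 significant digits so a round-trip preserves
    scores to well under 1e-6.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# discovery_rate_weight\t{result.weight:.8g}\n")
        fh.write("rank\tpathway_id\tCS\tIS\tscore\tperm_p\n")
        for rank, pid, cs, is_, score, perm_p in result.rows:
            fh.write(f"{rank}\t{pid}\t{cs:.8g}\t{is_:.8g}\t{score:.8g}\t{perm_p:.8g}\n")


def parse_result_table(path: str | Path) -> RankedResult:
    """Read back a TSV written by :func:`write_result_table`."""
    weight = math.nan
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    rows: list[tuple[int, str, float, float, float, float]] = []
    header_seen = False
    for line in lines:
        if not line.strip():
            continue
        if line.lstrip().startswith("#"):
            parts = line.lstrip("# \t").split("\t")
            if parts and parts[0] == "discovery_rate_weight" and len(parts) > 1:
                weight = float(parts[1])
            continue
        if not header_seen:
            header_seen = True
            continue
        rank, pid, cs, is_, score, perm_p = line.split("\t")
        rows.append((int(rank), pid, float(cs), float(is_), float(score), float(perm_p)))
    if math.isnan(weight):
        raise FormatError(f"{path}: missing discovery_rate_weight comment")
    return RankedResult(rows=tuple(rows), weight=weight)
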