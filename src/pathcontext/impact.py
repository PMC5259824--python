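"""Impact Scores: expression significance rescaled onto the Context-Score range.

The raw transform is IS*(π_i) = -log10(p_i), with p clamped below at a
small floor so p = 0 from upstream tools stays finite.  A min-max
normalization then maps IS* onto [min CS, max CS] so the two channels have
equal influence when linearly combined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from .context import ContextScoreVector
from .io import PathwaySignificanceTable

__all__ = ["ImpactRawVector", "ImpactScoreVector", "raw_impact", "normalize_impact"]

DEFAULT_P_FLOOR = 1e-15


@dataclass(frozen=True)
class ImpactRawVector:
    """IS*(π_i) = -log10(max(p_i, floor)) per pathway."""

    values: Mapping[str, float]
    floor_used: float


@dataclass(frozen=True)
class ImpactScoreVector:
    """IS(π_i): raw impact min-max rescaled onto the CS range."""

    values: Mapping[str, float]

    def __getitem__(self, pathway_id: str) -> float:
        return self.values[pathway_id]


def raw_impact(
    pvalues: PathwaySignificanceTable, floor: float = DEFAULT_P_FLOOR
) -> ImpactRawVector:
    """Negative log10 of the (clamped) p-values."""
    if not (0.0 < floor < 1.0):
        raise ValueError(f"floor must be in (0, 1), got {floor}")
    values = {pid: -math.log10(max(p, floor)) for pid, p in pvalues.pvalues.items()}
    return ImpactRawVector(values=values, floor_used=floor)


def normalize_impact(raw: ImpactRawVector, cs: ContextScoreVector) -> ImpactScoreVector:
    """Min-max rescale IS* onto [min CS, max CS].

    Degenerate ranges need conventions the formula itself does not supply:

    * all IS* equal — every pathway gets the midpoint of the CS range, a
      neutral value that neither dominates nor vanishes in the combined
      score;
    * all CS equal (e.g. no literature signal at all) — IS* is rescaled to
      [0, 1] instead, so the ranking still reflects the p-values.
    """
    if set(raw.values) != set(cs.values):
        raise ValueError("impact and context vectors must cover the same universe")
    is_vals = raw.values
    lo_is, hi_is = min(is_vals.values()), max(is_vals.values())
    lo_cs, hi_cs = min(cs.values.values()), max(cs.values.values())

    if hi_cs == lo_cs:
        lo_cs, hi_cs = 0.0, 1.0
    if hi_is == lo_is:
        mid = 0.5 * (lo_cs + hi_cs)
        return ImpactScoreVector(values={pid: mid for pid in is_vals})

    scale = (hi_cs - lo_cs) / (hi_is - lo_is)
    return ImpactScoreVector(
        values={pid: (v - lo_is) * scale + lo_cs for pid, v in is_vals.items()}
    )
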