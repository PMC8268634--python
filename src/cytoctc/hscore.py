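"""Semi-quantitative immunohistochemistry H-score.

The H-score summarises marker staining of a tissue section: for each staining
intensity level (1 = weak, 2 = moderate, 3 = strong) the percentage of
positively stained tumor area is recorded, and the score is

    H = sum_level level * pct_level,

ranging from 0 (no staining) to 300 (the whole tumor area at strong
intensity).  Scores are categorised as negative (H < 10), weak
(10 <= H < 100) or strong (H >= 100).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

__all__ = ["HScoreResult", "compute_hscore", "score_table", "LEVELS"]

LEVELS = (1, 2, 3)

_NEGATIVE_MAX = 10.0  # H < 10 -> negative
_STRONG_MIN = 100.0  # H >= 100 -> strong


@dataclass(frozen=True)
class HScoreResult:
    h_score: float
    category: str  # negative | weak | strong


def compute_hscore(pct_by_intensity: Mapping[int, float]) -> HScoreResult:
    """H-score of one tissue section.

    Parameters
    ----------
    pct_by_intensity
        Map from intensity level (1, 2 or 3) to the percentage of tumor area
        stained at that level, in [0, 100].  Levels may be omitted (0%); an
        empty map is a fully negative section.

    Raises
    ------
    ValueError
        On unknown levels, negative percentages, or a total above 100%.
    """
    for level in pct_by_intensity:
        if level not in LEVELS:
            raise ValueError(f"unknown intensity level {level!r}; expected one of {LEVELS}")
    pcts = {lvl: float(pct_by_intensity.get(lvl, 0.0)) for lvl in LEVELS}
    for lvl, pct in pcts.items():
        if pct < 0:
            raise ValueError(f"percentage for level {lvl} is negative ({pct})")
    total = sum(pcts.values())
    if total > 100.0 + 1e-9:
        raise ValueError(f"percentages sum to {total}, exceeding 100%")
    h = sum(lvl * pct for lvl, pct in pcts.items())
    if h < _NEGATIVE_MAX:
        category = "negative"
    elif h < _STRONG_MIN:
        category = "weak"
    else:
        category = "strong"
    return HScoreResult(h_score=h, category=category)


def score_table(tissue: pd.DataFrame) -> pd.DataFrame:
    """Score a batch of annotated sections.

    Expects columns ``sample_id``, ``marker``, ``pct_level1``, ``pct_level2``,
    ``pct_level3``; returns the same identifiers plus ``h_score`` and
    ``category``.
    """
    out = []
    for _, row in tissue.iterrows():
        res = compute_hscore(
            {1: row["pct_level1"], 2: row["pct_level2"], 3: row["pct_level3"]}
        )
        out.append(
            {
                "sample_id": row["sample_id"],
                "marker": row["marker"],
                "h_score": res.h_score,
                "category": res.category,
            }
        )
    return pd.DataFrame(out)
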