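"""Floor/ceiling effects and descriptive summaries of QOL-E scores.

Scores are tabulated into ten-point incremental categories [0,10), ...,
[90,100) plus a separate cell for exactly 100, and a floor (ceiling) effect
is flagged when strictly more than 15% of non-missing scores equal 0 (100).
Quartiles use linear interpolation between order statistics; the convention
is stated here because published reports rarely do.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scoring import ALL_SCORES

FLOOR_CEILING_PCT = 15.0

DECILE_EDGES = np.arange(0, 101, 10)
DECILE_LABELS = tuple(f"[{lo},{lo + 10})" for lo in range(0, 90, 10)) + ("[90,100)", "100")


@dataclass
class DistributionSummary:
    """Descriptives and decile tabulation for one score at one visit."""

    score: str
    visit: str
    n: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    min: float
    max: float
    decile_counts: dict[str, int] = field(default_factory=dict)
    decile_pct: dict[str, float] = field(default_factory=dict)
    floor_pct: float = float("nan")
    ceiling_pct: float = float("nan")
    floor_flag: bool = False
    ceiling_flag: bool = False


def flag_floor_ceiling(floor_pct: float, ceiling_pct: float) -> tuple[bool, bool]:
    """Strict >15% rule on the non-missing denominators."""
    return (bool(floor_pct > FLOOR_CEILING_PCT),
            bool(ceiling_pct > FLOOR_CEILING_PCT))


def summarize_distribution(scores, score: str = "", visit: str = "") -> DistributionSummary:
    """Summarize one vector of 0-100 scores (missing excluded throughout)."""
    x = pd.to_numeric(pd.Series(scores), errors="coerce").dropna().to_numpy(float)
    n = x.size
    if n == 0:
        nan = float("nan")
        return DistributionSummary(score, visit, 0, nan, nan, nan, nan, nan, nan, nan)
    q1, med, q3 = np.percentile(x, [25, 50, 75])  # linear interpolation
    counts: dict[str, int] = {}
    for i, label in enumerate(DECILE_LABELS[:-1]):
        lo = DECILE_EDGES[i]
        counts[label] = int(np.sum((x >= lo) & (x < lo + 10)))
    counts["100"] = int(np.sum(x == 100.0))
    pct = {k: 100.0 * v / n for k, v in counts.items()}
    floor_pct = 100.0 * float(np.sum(x == 0.0)) / n
    ceiling_pct = pct["100"]
    floor_flag, ceiling_flag = flag_floor_ceiling(floor_pct, ceiling_pct)
    return DistributionSummary(
        score=score, visit=visit, n=n,
        mean=float(np.mean(x)), sd=float(np.std(x, ddof=1)) if n > 1 else 0.0,
        median=float(med), q1=float(q1), q3=float(q3),
        min=float(np.min(x)), max=float(np.max(x)),
        decile_counts=counts, decile_pct=pct,
        floor_pct=floor_pct, ceiling_pct=ceiling_pct,
        floor_flag=floor_flag, ceiling_flag=ceiling_flag,
    )


def summarize_panel(panel: pd.DataFrame,
                    visits: tuple[str, ...] = ("baseline", "week24")) -> pd.DataFrame:
    """One summary row per (score, visit); flags reported as 0/1."""
    rows = []
    for visit in visits:
        sub = panel[panel["visit"] == visit]
        for score in ALL_SCORES:
            if score not in sub.columns:
                continue
            s = summarize_distribution(sub[score], score=score, visit=visit)
            row = {
                "score": score, "visit": visit, "n": s.n, "mean": s.mean,
                "sd": s.sd, "median": s.median, "q1": s.q1, "q3": s.q3,
                "min": s.min, "max": s.max,
                "floor_pct": s.floor_pct, "ceiling_pct": s.ceiling_pct,
                "floor_flag": int(s.floor_flag), "ceiling_flag": int(s.ceiling_flag),
            }
            row.update({f"bin {k}": v for k, v in s.decile_counts.items()})
            rows.append(row)
    return pd.DataFrame(rows)
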