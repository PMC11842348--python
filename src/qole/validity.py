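"""Construct validity: convergent/divergent correlations and known groups.

Convergent and divergent validity are assessed with Spearman rank
correlations between QOL-E scores and external measures (EORTC QLQ-C30
scales, hemoglobin, transfusion burden, platelets), pooled across the
baseline and Week-24 visits, and compared against a prespecified hypothesis
grid of expected correlation magnitudes and signs.  Known-groups validity
compares score medians and interquartile ranges across groups defined by
the QOL-E Item 1 overall-health rating and by baseline RBC transfusion
dependence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .scoring import ALL_SCORES, qlq_eligible_mask
from .synthetic import CLINICAL_COLUMNS, QLQ_ITEMS, QLQ_SCALES

MAGNITUDES = ("weak", "moderate", "strong", "very_strong")

#: Item 1 raw coding 0..3 = poor..excellent
ITEM1_LABELS = {3: "excellent", 2: "good", 1: "acceptable", 0: "poor"}


def classify_magnitude(r: float) -> str:
    """|r|<0.3 weak; <0.7 moderate; <0.9 strong; else very strong."""
    a = abs(r)
    if a < 0.3:
        return "weak"
    if a < 0.7:
        return "moderate"
    if a < 0.9:
        return "strong"
    return "very_strong"


@dataclass(frozen=True)
class CorrelationResult:
    n: int
    r: float
    p: float

    @property
    def magnitude(self) -> str:
        return classify_magnitude(self.r) if not np.isnan(self.r) else "undefined"


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation on complete pairs.

    Ties get average ranks; the P value uses the t approximation on n-2
    degrees of freedom.  Fewer than 3 complete pairs yields a missing
    coefficient rather than an error.
    """
    x = pd.to_numeric(pd.Series(x), errors="coerce").to_numpy(float)
    y = pd.to_numeric(pd.Series(y), errors="coerce").to_numpy(float)
    ok = ~(np.isnan(x) | np.isnan(y))
    n = int(ok.sum())
    if n < 3:
        return CorrelationResult(n=n, r=float("nan"), p=float("nan"))
    r, p = stats.spearmanr(x[ok], y[ok])
    return CorrelationResult(n=n, r=float(r), p=float(p))


def pooled_spearman(df: pd.DataFrame, xcol: str, ycol: str,
                    visits: tuple[str, ...] = ("baseline", "week24")) -> CorrelationResult:
    """Spearman with baseline and Week-24 rows stacked as observations."""
    sub = df[df["visit"].isin(visits)]
    return spearman(sub[xcol], sub[ycol])


# ---------------------------------------------------------------------------
# hypothesis grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Hypothesis:
    magnitude: str  # expected band
    sign: int       # +1, -1, or 0 (no directional expectation)


def default_hypothesis_grid() -> dict[tuple[str, str], Hypothesis]:
    """Editable reconstruction of the prespecified expectations.

    QLQ-C30 functioning scales and global health are expected to correlate
    moderately and positively with all QOL-E scores except sexual
    well-being (weak); major symptom scales moderately and negatively;
    minor symptom scales and all clinical outcomes weakly.
    """
    functioning = ("qlq_global_health", "qlq_physical_functioning",
                   "qlq_role_functioning", "qlq_emotional_functioning",
                   "qlq_cognitive_functioning", "qlq_social_functioning")
    major_symptoms = ("qlq_fatigue", "qlq_pain", "qlq_dyspnea",
                      "qlq_insomnia", "qlq_appetite_loss")
    minor_symptoms = ("qlq_nausea_vomiting", "qlq_constipation",
                      "qlq_diarrhea", "qlq_financial_difficulties")
    grid: dict[tuple[str, str], Hypothesis] = {}
    for score in ALL_SCORES:
        weak_score = score == "SEX"
        for m in functioning:
            grid[(score, m)] = Hypothesis("weak" if weak_score else "moderate", +1)
        for m in major_symptoms:
            grid[(score, m)] = Hypothesis("weak" if weak_score else "moderate", -1)
        for m in minor_symptoms:
            grid[(score, m)] = Hypothesis("weak", -1)
        for m in QLQ_ITEMS:  # global health / QoL ratings
            grid[(score, m)] = Hypothesis("weak" if weak_score else "moderate", +1)
        grid[(score, "hb_g_dl")] = Hypothesis("weak", +1)
        grid[(score, "rbc_units_8wk")] = Hypothesis("weak", -1)
        grid[(score, "platelet_count_e9_l")] = Hypothesis("weak", 0)
        grid[(score, "platelet_units_8wk")] = Hypothesis("weak", -1)
    return grid


def load_hypothesis_grid(path) -> dict[tuple[str, str], Hypothesis]:
    """Read a grid from YAML: list of {score, measure, magnitude, sign}."""
    with open(path) as fh:
        entries = yaml.safe_load(fh)
    return {(e["score"], e["measure"]): Hypothesis(e["magnitude"], int(e.get("sign", 0)))
            for e in entries}


def evaluate_hypothesis_grid(
    results: Mapping[tuple[str, str], CorrelationResult],
    grid: Mapping[tuple[str, str], Hypothesis],
) -> dict[tuple[str, str], str]:
    """Verdict per pair: as_hypothesized / stronger / weaker / wrong_sign.

    A wrong-sign correlation that is not significant (P > 0.05) is reported
    as ``indeterminate``: with no evidence of a non-zero correlation its
    direction carries no information.
    """
    verdicts: dict[tuple[str, str], str] = {}
    for pair, res in results.items():
        if pair not in grid:
            raise KeyError(f"no prespecified hypothesis for pair {pair!r}")
        hyp = grid[pair]
        if np.isnan(res.r):
            verdicts[pair] = "indeterminate"
            continue
        if hyp.sign != 0 and res.r * hyp.sign < 0:
            verdicts[pair] = "indeterminate" if res.p > 0.05 else "wrong_sign"
            continue
        obs, exp = MAGNITUDES.index(res.magnitude), MAGNITUDES.index(hyp.magnitude)
        verdicts[pair] = ("as_hypothesized" if obs == exp
                          else "stronger" if obs > exp else "weaker")
    return verdicts


def convergent_validity_table(records: pd.DataFrame, panel: pd.DataFrame,
                              ) -> pd.DataFrame:
    """Spearman grid of QOL-E scores vs QLQ-C30 scales and clinical outcomes.

    Observations pool baseline and Week-24 rows (up to two per patient);
    RevMDS-like rows are excluded from QLQ-C30 measures.
    """
    merged = records.merge(panel[["patient_id", "visit"] + list(ALL_SCORES)],
                           on=["patient_id", "visit"], how="inner")
    merged = merged[merged["visit"].isin(("baseline", "week24"))]
    qlq_ok = merged[qlq_eligible_mask(merged)]
    rows = []
    for measure in list(QLQ_SCALES) + list(QLQ_ITEMS) + list(CLINICAL_COLUMNS):
        src = qlq_ok if measure.startswith("qlq_") else merged
        for score in ALL_SCORES:
            res = spearman(src[measure], src[score])
            rows.append({"measure": measure, "score": score,
                         "n": res.n, "r": res.r, "p": res.p,
                         "magnitude": res.magnitude})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# known groups
# ---------------------------------------------------------------------------

def iqr_overlap(q1a: float, q3a: float, q1b: float, q3b: float) -> bool:
    """Closed-interval intersection; a shared endpoint counts as overlap."""
    return (q1a <= q3b) and (q1b <= q3a)


def known_groups(records: pd.DataFrame, panel: pd.DataFrame,
                 grouping: str) -> pd.DataFrame:
    """Median (Q1, Q3) of each score by a baseline known group, pooled visits.

    ``grouping`` is ``"item1_response"`` (ordered excellent..poor) or
    ``"transfusion_dependency"`` (independent, dependent; >=1 RBC unit in
    the prior 8 weeks at baseline = dependent, missing units = excluded).
    Rows carry per-group n/median/Q1/Q3 plus IQR-overlap flags against every
    other group.
    """
    base = records[records["visit"] == "baseline"].set_index("patient_id")
    if grouping == "item1_response":
        raw = base["item1"].dropna()
        group = raw.map(ITEM1_LABELS)
        order = ["excellent", "good", "acceptable", "poor"]
    elif grouping == "transfusion_dependency":
        units = pd.to_numeric(base["rbc_units_8wk"], errors="coerce").dropna()
        group = (units >= 1).map({False: "independent", True: "dependent"})
        order = ["independent", "dependent"]
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    present = [g for g in order if (group == g).any()]
    if len(present) < 2:
        raise ValueError("known-groups analysis needs at least two non-empty groups")

    pooled = panel[panel["visit"].isin(("baseline", "week24"))].copy()
    pooled["group"] = pooled["patient_id"].map(group)
    rows = []
    for score in ALL_SCORES:
        stats_by_group = {}
        for gname in present:
            vals = pooled.loc[pooled["group"] == gname, score].dropna()
            if len(vals):
                q1, med, q3 = np.percentile(vals, [25, 50, 75])
            else:
                q1 = med = q3 = float("nan")
            stats_by_group[gname] = (len(vals), med, q1, q3)
        for gname in present:
            n, med, q1, q3 = stats_by_group[gname]
            row = {"score": score, "grouping": grouping, "group": gname,
                   "n": n, "median": med, "q1": q1, "q3": q3}
            for other in present:
                if other == gname:
                    continue
                _, _, oq1, oq3 = stats_by_group[other]
                row[f"overlap_{other}"] = (
                    iqr_overlap(q1, q3, oq1, oq3)
                    if not (np.isnan(q1) or np.isnan(oq1)) else np.nan)
            rows.append(row)
    return pd.DataFrame(rows)
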