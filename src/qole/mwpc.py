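"""Responsiveness and meaningful within-patient change (MWPC) thresholds.

Responder thresholds for the QOL-E are estimated anchor-first: patients are
grouped by their level of change on external anchors that themselves track
perceived health (a change-score Spearman correlation above 0.3 in absolute
value on every domain and summary score, sexual well-being excepted,
qualifies an anchor), mean/median score changes in the >=1-level
improvement and worsening groups are read off, and distribution-based
quantities - the standard error of measurement SEM = SD_baseline *
sqrt(1 - ICC) and half the baseline SD - bound the result from below.

Two parts of the published procedure are judgment calls that this module
codifies so they are deterministic and testable:

* eCDF separation.  "Clear and consistent" separation of the change-score
  eCDFs between a side group and the no-change group is declared when the
  side group's curve lies strictly on the correct side at >=80% of the
  pooled grid points AND the between-group median difference is at least
  the score's minimum possible change.

* Threshold selection.  With D = max(SEM, 0.5*SD), the improvement
  threshold is floor(k* x mpc) for the smallest positive integer k* with
  k* x mpc >= D - 0.5; the half-point tolerance absorbs one-decimal
  rounding of the printed inputs.  The worsening threshold is its negative.
  For the three summary scores (whose minimum possible steps are <0.1
  points and carry no information) a single common threshold is used: the
  floor of the smallest primary-anchor mean improvement among them,
  checked against each score's D.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .scoring import (ALL_SCORES, DOMAINS, SUMMARIES, ScoringSchema,
                      minimum_possible_change, qlq_eligible_mask)
from .validity import CorrelationResult, spearman

#: group-size floor for anchor categories; smaller groups merge inward
MIN_GROUP_N = 10

#: scores exempt from the anchor-eligibility rule and from triangulation
#: (inadequate responsiveness of sexual well-being)
EXEMPT_SCORES = frozenset({"SEX"})


# ---------------------------------------------------------------------------
# change scores and anchors
# ---------------------------------------------------------------------------

def change_from_baseline(panel: pd.DataFrame,
                         scores: Sequence[str] = ALL_SCORES) -> pd.DataFrame:
    """Per-patient Week 24 minus baseline change table.

    A change is missing when either visit's score is missing.  Summary
    changes are differences of the summary scores themselves, not summaries
    of domain changes (the two differ when a domain is missing at one
    visit).
    """
    sub = panel[panel["visit"].isin(("baseline", "week24"))]
    out = {}
    for score in scores:
        wide = sub.pivot_table(index="patient_id", columns="visit", values=score,
                               aggfunc="first", dropna=False)
        for col in ("baseline", "week24"):
            if col not in wide.columns:
                wide[col] = np.nan
        out[score] = wide["week24"] - wide["baseline"]
    changes = pd.DataFrame(out)
    meta = sub.drop_duplicates("patient_id").set_index("patient_id")
    if "trial" in meta.columns:
        changes.insert(0, "trial", meta["trial"].reindex(changes.index))
    return changes


@dataclass(frozen=True)
class AnchorSpec:
    """How one candidate anchor turns into ordered change categories.

    ``kind`` is one of:

    - ``ordinal_change``: category = follow-up level minus baseline level
      (oriented so positive = improvement);
    - ``absolute_followup``: the follow-up rating itself measures change
      (QOL-E Item 2); category = rating minus the no-change midpoint;
    - ``numeric_cutpoints``: continuous change dichotomized at
      ``improvement_cut`` / ``worsening_cut``.
    """

    name: str
    column: str
    kind: str
    qlq_based: bool = False
    no_change_value: float = 0.0
    improvement_cut: float | None = None
    worsening_cut: float | None = None

    def categorize(self, records: pd.DataFrame) -> pd.Series:
        base = records[records["visit"] == "baseline"].set_index("patient_id")
        w24 = records[records["visit"] == "week24"].set_index("patient_id")
        if self.kind == "ordinal_change":
            b = pd.to_numeric(base[self.column], errors="coerce")
            f = pd.to_numeric(w24[self.column], errors="coerce")
            cat = (f - b.reindex(f.index))
        elif self.kind == "absolute_followup":
            f = pd.to_numeric(w24[self.column], errors="coerce")
            cat = f - self.no_change_value
        elif self.kind == "numeric_cutpoints":
            b = pd.to_numeric(base[self.column], errors="coerce")
            f = pd.to_numeric(w24[self.column], errors="coerce")
            diff = f - b.reindex(f.index)
            cat = pd.Series(np.nan, index=diff.index)
            cat[diff.notna()] = 0.0
            if self.improvement_cut is not None:
                if self.improvement_cut >= self.no_change_value:
                    cat[diff >= self.improvement_cut] = 1.0
                else:
                    cat[diff <= self.improvement_cut] = 1.0
            if self.worsening_cut is not None:
                if self.worsening_cut <= self.no_change_value:
                    cat[diff <= self.worsening_cut] = -1.0
                else:
                    cat[diff >= self.worsening_cut] = -1.0
            # for anchors where a *decrease* is the improvement (RBC units)
            # the cut signs above already encode the orientation
        else:
            raise ValueError(f"unknown anchor kind {self.kind!r}")
        cat.name = self.name
        return cat

    def change_measure(self, records: pd.DataFrame) -> pd.Series:
        """Continuous/ordinal change value used for responsiveness correlations."""
        base = records[records["visit"] == "baseline"].set_index("patient_id")
        w24 = records[records["visit"] == "week24"].set_index("patient_id")
        if self.kind == "absolute_followup":
            return pd.to_numeric(w24[self.column], errors="coerce").rename(self.name)
        b = pd.to_numeric(base[self.column], errors="coerce")
        f = pd.to_numeric(w24[self.column], errors="coerce")
        return (f - b.reindex(f.index)).rename(self.name)


def default_anchor_specs() -> tuple[AnchorSpec, ...]:
    """The six candidate anchors of the validation analysis.

    Hb and RBC-unit cut points are configuration placeholders (the
    trial-programme values are not public): Hb change of +/-1.5 g/dL and a
    change of 2 RBC units in the prior-8-week count, oriented so fewer
    units = improvement.
    """
    return (
        AnchorSpec("item1", "item1", "ordinal_change"),
        AnchorSpec("item2", "item2", "absolute_followup", no_change_value=2.0),
        AnchorSpec("qlq_item29", "qlq_item29", "ordinal_change", qlq_based=True),
        AnchorSpec("qlq_item30", "qlq_item30", "ordinal_change", qlq_based=True),
        AnchorSpec("hb", "hb_g_dl", "numeric_cutpoints",
                   improvement_cut=1.5, worsening_cut=-1.5),
        AnchorSpec("rbc_units", "rbc_units_8wk", "numeric_cutpoints",
                   improvement_cut=-2.0, worsening_cut=2.0),
    )


def responsiveness_table(records: pd.DataFrame, changes: pd.DataFrame,
                         specs: Sequence[AnchorSpec] = (),
                         scores: Sequence[str] = ALL_SCORES) -> pd.DataFrame:
    """Spearman of score changes vs anchor changes (anchor x score grid)."""
    specs = specs or default_anchor_specs()
    qlq_ok = set(records.loc[qlq_eligible_mask(records), "patient_id"])
    rows = []
    for spec in specs:
        measure = spec.change_measure(records)
        idx = changes.index.intersection(measure.index)
        if spec.qlq_based:
            idx = idx.intersection(pd.Index(sorted(qlq_ok)))
        for score in scores:
            res = spearman(changes.loc[idx, score], measure.reindex(idx))
            rows.append({"anchor": spec.name, "score": score,
                         "n": res.n, "r": res.r, "p": res.p})
    return pd.DataFrame(rows)


def select_anchors(table: pd.DataFrame, threshold: float = 0.3,
                   exempt: frozenset[str] = EXEMPT_SCORES) -> list[str]:
    """Anchors whose |r| exceeds the threshold on every non-exempt score."""
    if table.empty:
        raise ValueError("empty candidate anchor table")
    eligible = []
    for anchor, grp in table.groupby("anchor", sort=False):
        rel = grp[~grp["score"].isin(exempt)]
        if len(rel) and (rel["r"].abs() > threshold).all():
            eligible.append(anchor)
    return eligible


# ---------------------------------------------------------------------------
# anchor groups
# ---------------------------------------------------------------------------

@dataclass
class AnchorGroupTable:
    """Per-category change descriptives after small-group collapsing."""

    groups: pd.DataFrame  # columns: side, label, categories, n, mean, median
    collapse_log: list[str] = field(default_factory=list)
    flagged_sides: list[str] = field(default_factory=list)


def _collapse_side(cats: list[float], counts: Mapping[float, int]) -> tuple[list[list[float]], list[str]]:
    """Merge categories with n <= MIN_GROUP_N toward no change, outermost first."""
    log: list[str] = []
    groups = [[c] for c in sorted(cats, key=abs, reverse=True)]
    while len(groups) > 1:
        sizes = [sum(counts[c] for c in g) for g in groups]
        merged = False
        for i, size in enumerate(sizes):
            if size <= MIN_GROUP_N:
                j = i + 1 if i + 1 < len(groups) else i - 1
                log.append(f"merged {groups[i]} (n={size}) into {groups[j]}")
                groups[j] = groups[i] + groups[j]
                del groups[i]
                merged = True
                break
        if not merged:
            break
    return groups[::-1], log  # inner-to-outer order


def _label(side: str, cats: list[float]) -> str:
    inner = min(abs(c) for c in cats)
    sign = "+" if side == "improvement" else "-"
    prefix = ">=" if len(cats) > 1 or inner < max(abs(c) for c in cats) else ""
    mag = int(inner) if float(inner).is_integer() else inner
    return f"{prefix}{sign}{mag}" if len(cats) == 1 else f">={sign}{mag}"


def build_anchor_groups(changes: pd.Series, categories: pd.Series) -> AnchorGroupTable:
    """Group change scores by anchor category with the n<=10 collapsing rule.

    Collapsing proceeds from the outermost category inward, never across
    the no-change boundary; a side whose total cannot exceed the floor is
    retained whole and flagged rather than absorbed into no change.
    """
    idx = changes.index.intersection(categories.index)
    df = pd.DataFrame({"change": changes.reindex(idx),
                       "cat": categories.reindex(idx)}).dropna()
    counts = df["cat"].value_counts().to_dict()
    rows = []
    log: list[str] = []
    flagged: list[str] = []
    for side, sign in (("worsening", -1), ("improvement", +1)):
        cats = [c for c in counts if sign * c > 0]
        if not cats:
            continue
        groups, side_log = _collapse_side(cats, counts)
        log.extend(side_log)
        if len(groups) == 1 and sum(counts[c] for c in groups[0]) <= MIN_GROUP_N:
            flagged.append(side)
        for g in groups:
            vals = df.loc[df["cat"].isin(g), "change"]
            rows.append({"side": side, "label": _label(side, g),
                         "categories": sorted(g), "n": len(vals),
                         "mean": vals.mean(), "median": vals.median()})
    if 0.0 in counts:
        vals = df.loc[df["cat"] == 0.0, "change"]
        rows.append({"side": "no_change", "label": "0", "categories": [0.0],
                     "n": len(vals), "mean": vals.mean(), "median": vals.median()})
    table = pd.DataFrame(rows)
    if len(table) == 1:
        log.append("all patients fall in a single category")
    return AnchorGroupTable(groups=table, collapse_log=log, flagged_sides=flagged)


def side_estimates(changes: pd.Series, categories: pd.Series,
                   side: str) -> dict[str, float]:
    """n/mean/median change for the pooled >=1-level improvement or worsening group."""
    sign = +1 if side == "improvement" else -1
    idx = changes.index.intersection(categories.index)
    df = pd.DataFrame({"change": changes.reindex(idx),
                       "cat": categories.reindex(idx)}).dropna()
    vals = df.loc[sign * df["cat"] > 0, "change"]
    return {"n": int(len(vals)),
            "mean": float(vals.mean()) if len(vals) else float("nan"),
            "median": float(vals.median()) if len(vals) else float("nan")}


# ---------------------------------------------------------------------------
# eCDF separation
# ---------------------------------------------------------------------------

def ecdf_separation(side_changes, no_change_changes, side: str,
                    mpc: float, dominance: float = 0.8) -> dict:
    """Codified "clear and consistent" eCDF separation check.

    Returns ``separated`` (True/False, or None when either group has fewer
    than 3 observations), the fraction of pooled grid points at which the
    side group's eCDF lies strictly on the correct side, and the
    between-group median difference.
    """
    a = pd.to_numeric(pd.Series(side_changes), errors="coerce").dropna().to_numpy(float)
    b = pd.to_numeric(pd.Series(no_change_changes), errors="coerce").dropna().to_numpy(float)
    if a.size < 3 or b.size < 3:
        return {"separated": None, "dominance_fraction": float("nan"),
                "median_difference": float("nan")}
    grid = np.unique(np.concatenate([a, b]))
    fa = np.searchsorted(np.sort(a), grid, side="right") / a.size
    fb = np.searchsorted(np.sort(b), grid, side="right") / b.size
    # improvement: side group stochastically larger, its eCDF lies below
    strict = (fa < fb) if side == "improvement" else (fa > fb)
    frac = float(strict.mean())
    med_diff = float(np.median(a) - np.median(b))
    directed = med_diff if side == "improvement" else -med_diff
    separated = bool(frac >= dominance and directed >= mpc)
    return {"separated": separated, "dominance_fraction": frac,
            "median_difference": med_diff}


# ---------------------------------------------------------------------------
# distribution-based quantities
# ---------------------------------------------------------------------------

def sem(sd_baseline: float, icc: float) -> float:
    """Standard error of measurement, SD * sqrt(1 - ICC)."""
    if sd_baseline < 0:
        raise ValueError("sd must be >= 0")
    if not 0 <= icc <= 1:
        raise ValueError(f"icc must lie in [0, 1], got {icc}")
    return sd_baseline * math.sqrt(1.0 - icc)


def half_sd(sd_baseline: float) -> float:
    """Half the baseline SD (an effect size of 0.5)."""
    if sd_baseline < 0:
        raise ValueError("sd must be >= 0")
    return sd_baseline / 2.0


# ---------------------------------------------------------------------------
# triangulation
# ---------------------------------------------------------------------------

@dataclass
class TriangulationInputs:
    """Everything the triangulation needs for one score."""

    score: str
    sem: float
    half_sd: float
    #: minimum possible change; None for summary scores (steps < 0.1 point)
    mpc: float | None
    #: anchor -> side -> {"n", "mean", "median"}
    anchor_estimates: Mapping[str, Mapping[str, Mapping[str, float]]] = field(
        default_factory=dict)
    #: side -> bool, outcome of the eCDF separation check
    ecdf_separated: Mapping[str, bool] = field(
        default_factory=lambda: {"improvement": True, "worsening": True})


@dataclass
class MWPCResult:
    score: str
    improvement_threshold: int
    worsening_threshold: int
    anchor_range: tuple[float, float | None]
    consistent: bool
    rationale: str


#: rounding slack (points) absorbing the one-decimal rounding of inputs
ROUNDING_TOLERANCE = 0.5


def _eligible_estimates(inputs: TriangulationInputs, side: str) -> list[float]:
    if not inputs.ecdf_separated.get(side, False):
        return []
    vals: list[float] = []
    for est in inputs.anchor_estimates.values():
        e = est.get(side, {})
        for key in ("mean", "median"):
            v = e.get(key)
            if v is not None and not math.isnan(v):
                vals.append(abs(v))
    return vals


def triangulate_domain(inputs: TriangulationInputs) -> MWPCResult:
    """Domain rule: smallest mpc multiple clearing max(SEM, 0.5 SD).

    The threshold must be an achievable state change, so it is a multiple
    of the domain's minimum possible change, floored to an integer for
    reporting; a half-point tolerance below D = max(SEM, 0.5 SD) absorbs
    the one-decimal rounding of the printed inputs.
    """
    if inputs.mpc is None or not inputs.mpc > 0:
        raise ValueError(f"{inputs.score}: minimum possible change required")
    d = max(inputs.sem, inputs.half_sd)
    k = max(1, math.ceil((d - ROUNDING_TOLERANCE) / inputs.mpc))
    improvement = math.floor(k * inputs.mpc + 1e-9)
    imp_est = _eligible_estimates(inputs, "improvement")
    wors_est = _eligible_estimates(inputs, "worsening")
    if not (imp_est or wors_est) and not inputs.anchor_estimates:
        raise ValueError(f"{inputs.score}: no anchor estimates and no "
                         "distribution inputs to triangulate from")
    all_est = imp_est + wors_est
    hi = max(all_est) if all_est else None
    consistent = (hi is None and improvement >= d - ROUNDING_TOLERANCE - 1) or \
        (hi is not None and (d - 1) <= improvement <= hi + 1)
    mult = ("the minimum possible change" if k == 1
            else f"{k} times the minimum possible change")
    rationale = (f"equivalent to {mult} (rounded down); "
                 f">=SEM ({inputs.sem:.1f}) and >=0.5*SD ({inputs.half_sd:.1f}) "
                 f"within the {ROUNDING_TOLERANCE}-point rounding tolerance")
    return MWPCResult(score=inputs.score, improvement_threshold=improvement,
                      worsening_threshold=-improvement,
                      anchor_range=(d, hi), consistent=bool(consistent),
                      rationale=rationale)


def triangulate_summaries(inputs_by_score: Mapping[str, TriangulationInputs],
                          primary_anchor: str = "item1") -> dict[str, MWPCResult]:
    """Summary rule: one common threshold across GEN/ALL/TOI.

    The common value is the floor of the smallest primary-anchor mean
    improvement among the three scores, and must clear every score's
    max(SEM, 0.5 SD) within the rounding tolerance.
    """
    means = {}
    for score, inp in inputs_by_score.items():
        est = inp.anchor_estimates.get(primary_anchor, {}).get("improvement", {})
        m = est.get("mean")
        if m is None or math.isnan(m):
            raise ValueError(f"{score}: primary anchor improvement mean required")
        means[score] = m
    common = math.floor(min(means.values()))
    out: dict[str, MWPCResult] = {}
    for score, inp in inputs_by_score.items():
        d = max(inp.sem, inp.half_sd)
        meets = common >= d - ROUNDING_TOLERANCE
        est = _eligible_estimates(inp, "improvement") + _eligible_estimates(inp, "worsening")
        hi = max(est) if est else None
        rationale = ("single threshold across the summary scores; "
                     f"floor of the smallest primary-anchor mean improvement "
                     f"({min(means.values()):.1f}); "
                     + (">=SEM and >=0.5*SD" if meets
                        else "below the distribution-based bound (flagged)"))
        out[score] = MWPCResult(score=score, improvement_threshold=common,
                                worsening_threshold=-common,
                                anchor_range=(d, hi),
                                consistent=bool(meets), rationale=rationale)
    return out


def triangulate_mwpc(inputs: Mapping[str, TriangulationInputs],
                     primary_anchor: str = "item1") -> dict[str, MWPCResult]:
    """Triangulate every supplied score; summaries share a common threshold."""
    results: dict[str, MWPCResult] = {}
    for score, inp in inputs.items():
        if score in DOMAINS:
            results[score] = triangulate_domain(inp)
    summary_inputs = {s: inputs[s] for s in SUMMARIES if s in inputs}
    if summary_inputs:
        results.update(triangulate_summaries(summary_inputs, primary_anchor))
    return results


# ---------------------------------------------------------------------------
# end-to-end
# ---------------------------------------------------------------------------

def distribution_inputs(panel: pd.DataFrame, icc_table: pd.DataFrame,
                        ) -> pd.DataFrame:
    """Baseline SD (MEDALIST-like subset), SEM, and 0.5 SD per score."""
    base = panel[(panel["visit"] == "baseline")
                 & (panel["trial"] == "T1_medalist_like")]
    rows = []
    icc_by_score = icc_table.set_index("score")["icc"]
    for score in ALL_SCORES:
        sd = float(base[score].dropna().std(ddof=1))
        icc = float(icc_by_score.get(score, float("nan")))
        icc_clipped = min(max(icc, 0.0), 1.0) if not math.isnan(icc) else float("nan")
        rows.append({"score": score, "sd_baseline": sd, "icc": icc,
                     "sem": sem(sd, icc_clipped) if not math.isnan(icc) else float("nan"),
                     "half_sd": half_sd(sd)})
    return pd.DataFrame(rows)


def run_mwpc(records: pd.DataFrame, panel: pd.DataFrame, schema: ScoringSchema,
             icc_table: pd.DataFrame,
             specs: Sequence[AnchorSpec] = ()) -> dict:
    """Full responsiveness-to-threshold pipeline on a scored cohort.

    Returns a dict with the responsiveness correlation table, the selected
    anchors, per-anchor group tables, eCDF separation outcomes, the
    distribution-based inputs, and the triangulated thresholds.
    """
    specs = specs or default_anchor_specs()
    changes = change_from_baseline(panel)
    resp = responsiveness_table(records, changes, specs)
    selected = select_anchors(resp)
    dist = distribution_inputs(panel, icc_table).set_index("score")
    categories = {s.name: s.categorize(records) for s in specs if s.name in selected}
    qlq_ok = pd.Index(sorted(set(records.loc[qlq_eligible_mask(records), "patient_id"])))
    spec_by_name = {s.name: s for s in specs}

    group_tables: dict[tuple[str, str], AnchorGroupTable] = {}
    separation: dict[str, dict[str, dict]] = {}
    tri_inputs: dict[str, TriangulationInputs] = {}
    target_scores = [s for s in ALL_SCORES if s not in EXEMPT_SCORES]
    for score in target_scores:
        mpc = None
        if score in DOMAINS:
            mpc = minimum_possible_change(schema, score)
        estimates: dict[str, dict[str, dict[str, float]]] = {}
        sep_by_side = {"improvement": [], "worsening": []}
        separation[score] = {}
        for name in selected:
            cats = categories[name]
            if spec_by_name[name].qlq_based:
                cats = cats.reindex(cats.index.intersection(qlq_ok))
            ch = changes[score]
            group_tables[(name, score)] = build_anchor_groups(ch, cats)
            estimates[name] = {
                side: side_estimates(ch, cats, side)
                for side in ("improvement", "worsening")
            }
            idx = ch.index.intersection(cats.index)
            df = pd.DataFrame({"change": ch.reindex(idx), "cat": cats.reindex(idx)}).dropna()
            separation[score][name] = {}
            for side, sign in (("improvement", +1), ("worsening", -1)):
                res = ecdf_separation(
                    df.loc[sign * df["cat"] > 0, "change"],
                    df.loc[df["cat"] == 0, "change"],
                    side, mpc if mpc is not None else 0.0)
                separation[score][name][side] = res
                if res["separated"] is not None:
                    sep_by_side[side].append(res["separated"])
        row = dist.loc[score]
        tri_inputs[score] = TriangulationInputs(
            score=score, sem=float(row["sem"]), half_sd=float(row["half_sd"]),
            mpc=mpc, anchor_estimates=estimates,
            ecdf_separated={side: bool(flags) and all(flags)
                            for side, flags in sep_by_side.items()},
        )
    thresholds = triangulate_mwpc(tri_inputs)
    return {
        "responsiveness": resp,
        "selected_anchors": selected,
        "anchor_groups": group_tables,
        "ecdf_separation": separation,
        "distribution_inputs": dist.reset_index(),
        "triangulation_inputs": tri_inputs,
        "thresholds": thresholds,
    }


def ecdf_coordinates(changes: pd.Series, categories: pd.Series) -> pd.DataFrame:
    """Tidy (group, x, F) eCDF coordinates for plotting or export."""
    idx = changes.index.intersection(categories.index)
    df = pd.DataFrame({"change": changes.reindex(idx),
                       "cat": categories.reindex(idx)}).dropna()
    rows = []
    for label, sel in (("improvement", df["cat"] > 0),
                       ("no_change", df["cat"] == 0),
                       ("worsening", df["cat"] < 0)):
        vals = np.sort(df.loc[sel, "change"].to_numpy(float))
        if vals.size == 0:
            continue
        grid = np.unique(vals)
        f = np.searchsorted(vals, grid, side="right") / vals.size
        for x, y in zip(grid, f):
            rows.append({"group": label, "x": float(x), "F": float(y)})
    return pd.DataFrame(rows)


def plot_ecdf(coords: pd.DataFrame, path, title: str = "") -> None:
    """Optional PNG dump of eCDF curves (one line per anchor group)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, grp in coords.groupby("group"):
        ax.step(grp["x"], grp["F"], where="post", label=label)
    ax.set_xlabel("change from baseline (points)")
    ax.set_ylabel("eCDF")
    ax.legend()
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
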