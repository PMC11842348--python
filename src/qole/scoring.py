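"""QOL-E instrument structure and 0-100 score computation.

The QOL-E is a 29-item questionnaire for patients with myelodysplastic
neoplasms (MDS).  Items 1 and 2 ask about general well-being and are kept
outside the scored domains; the remaining 27 items form six domains:

====== ================================ ==============
code   domain                           total raw range
====== ================================ ==============
FIS    physical well-being              8
FUN    functional well-being            9
SOC    social/family well-being         4
SEX    sexual well-being                12
FAT    fatigue                          21
MDSS   MDS-specific disturbances        42
====== ================================ ==============

Each domain score is the oriented raw sum rescaled linearly to 0-100, with
0 the worst and 100 the best outcome.  Three summary scores are means of
domains: GEN (all domains except MDSS), ALL (mean of GEN and MDSS), and the
treatment outcome index TOI (mean of FIS, FUN, MDSS).

The exact item-level response scales live in the instrument's scoring
manual, which is distributed separately from the validation literature; the
default schema here is a reconstruction constrained to the published domain
raw ranges (so that the minimum possible change of each standardized score
is exact) and is fully swappable via YAML/JSON configuration.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

DOMAINS: tuple[str, ...] = ("FIS", "FUN", "SOC", "SEX", "FAT", "MDSS")
SUMMARIES: tuple[str, ...] = ("GEN", "ALL", "TOI")
ALL_SCORES: tuple[str, ...] = DOMAINS + SUMMARIES
GENERAL = "GENERAL"

#: Trials of the pooled validation cohort (MEDALIST-, DARB-MDS-, EQoL-MDS-,
#: and RevMDS-like designs).
TRIALS: tuple[str, ...] = (
    "T1_medalist_like",
    "T2_darb_like",
    "T3_eqol_like",
    "T4_rev_like",
)
VISITS: tuple[str, ...] = ("screening", "baseline", "week24")

ID_COLUMNS = ("patient_id", "trial", "visit")

DEFAULT_SUMMARY_COMPOSITION: dict[str, tuple[str, ...]] = {
    "GEN": ("FIS", "FUN", "SOC", "SEX", "FAT"),
    "ALL": ("GEN", "MDSS"),
    "TOI": ("FIS", "FUN", "MDSS"),
}

#: Domains that may be dropped from a summary mean when missing.  Sexual
#: well-being is frequently unanswered, and the instrument allows GEN (and
#: hence ALL) to be computed without it.
OPTIONAL_SUMMARY_CONSTITUENTS = frozenset({"SEX"})


class SchemaError(ValueError):
    """The scoring schema is structurally invalid or an item is unknown."""


class ResponseError(ValueError):
    """An item response lies outside the item's raw range."""


@dataclass(frozen=True)
class Item:
    """One questionnaire item: identity, domain, raw range, orientation."""

    item_id: str
    domain: str
    raw_min: int
    raw_max: int
    reverse: bool = False

    @property
    def raw_range(self) -> int:
        return self.raw_max - self.raw_min

    def oriented(self, raw: float) -> float:
        """Map a raw response to 0..raw_range with higher = better."""
        if self.reverse:
            return self.raw_max - raw
        return raw - self.raw_min


@dataclass(frozen=True)
class ScoringSchema:
    """Item->domain mapping, raw ranges, reversals, and summary composition.

    ``min_answered_fraction`` is the half-rule default: a domain is scored
    only when at least this fraction of its items is answered, in which case
    the oriented raw sum is prorated from the answered items.
    """

    items: tuple[Item, ...]
    summary_composition: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_SUMMARY_COMPOSITION)
    )
    min_answered_fraction: float = 0.5

    def __post_init__(self) -> None:
        if len(self.items) != 29:
            raise SchemaError(f"schema must have exactly 29 items, got {len(self.items)}")
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise SchemaError("duplicate item ids in schema")
        general = [it for it in self.items if it.domain == GENERAL]
        scored = [it for it in self.items if it.domain != GENERAL]
        if len(general) != 2 or len(scored) != 27:
            raise SchemaError(
                f"schema must have 2 general-well-being items and 27 domain items, "
                f"got {len(general)}/{len(scored)}"
            )
        for it in self.items:
            if it.domain != GENERAL and it.domain not in DOMAINS:
                raise SchemaError(f"unknown domain {it.domain!r} for item {it.item_id}")
            if it.raw_max <= it.raw_min:
                raise SchemaError(f"item {it.item_id}: raw_max must exceed raw_min")
        if not 0 < self.min_answered_fraction <= 1:
            raise SchemaError("min_answered_fraction must lie in (0, 1]")

    # -- lookups ---------------------------------------------------------
    def item(self, item_id: str) -> Item:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise SchemaError(f"unknown item id {item_id!r}")

    def domain_items(self, domain: str) -> tuple[Item, ...]:
        return tuple(it for it in self.items if it.domain == domain)

    def domain_raw_range(self, domain: str) -> int:
        items = self.domain_items(domain)
        if not items:
            raise SchemaError(f"no items for domain {domain!r}")
        return sum(it.raw_range for it in items)

    @property
    def scored_item_ids(self) -> tuple[str, ...]:
        return tuple(it.item_id for it in self.items if it.domain != GENERAL)

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(it.item_id for it in self.items)

    def summary_domains(self, summary: str) -> tuple[str, ...]:
        """Constituents of a summary expanded down to domain level."""
        out: list[str] = []
        for c in self.summary_composition[summary]:
            if c in SUMMARIES:
                out.extend(self.summary_domains(c))
            else:
                out.append(c)
        # preserve order, drop duplicates
        seen: list[str] = []
        for d in out:
            if d not in seen:
                seen.append(d)
        return tuple(seen)

    # -- (de)serialization ----------------------------------------------
    def to_dict(self) -> dict:
        return {
            "items": [
                {
                    "item_id": it.item_id,
                    "domain": it.domain,
                    "raw_min": it.raw_min,
                    "raw_max": it.raw_max,
                    "reverse": it.reverse,
                }
                for it in self.items
            ],
            "summary_composition": {k: list(v) for k, v in self.summary_composition.items()},
            "min_answered_fraction": self.min_answered_fraction,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScoringSchema":
        items = tuple(
            Item(
                item_id=str(x["item_id"]),
                domain=str(x["domain"]),
                raw_min=int(x["raw_min"]),
                raw_max=int(x["raw_max"]),
                reverse=bool(x.get("reverse", False)),
            )
            for x in d["items"]
        )
        comp = {k: tuple(v) for k, v in d.get(
            "summary_composition", DEFAULT_SUMMARY_COMPOSITION).items()}
        return cls(items=items, summary_composition=comp,
                   min_answered_fraction=float(d.get("min_answered_fraction", 0.5)))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScoringSchema":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_schema() -> ScoringSchema:
    """Default reconstruction of the QOL-E v2/v3 structure.

    Per-domain item counts and raw ranges are chosen so every domain's total
    raw range matches the published instrument (FIS 8, FUN 9, SOC 4, SEX 12,
    FAT 21, MDSS 42).  Symptom-burden domains (FAT, MDSS) and the physical
    limitation items are raw-coded with higher = worse and carry a reversal
    flag; ability/satisfaction domains are coded higher = better.
    """
    items: list[Item] = [
        # general well-being; item1: 0=poor .. 3=excellent, item2: follow-up
        # change rating, 0=much worse .. 4=much better
        Item("item1", GENERAL, 0, 3),
        Item("item2", GENERAL, 0, 4),
        # physical well-being: limitation frequency, higher raw = worse
        Item("item3", "FIS", 0, 2, reverse=True),
        Item("item4", "FIS", 0, 2, reverse=True),
        Item("item6", "FIS", 0, 2, reverse=True),
        Item("item14", "FIS", 0, 2, reverse=True),
        # functional well-being
        Item("item5", "FUN", 0, 3),
        Item("item8", "FUN", 0, 3),
        Item("item9", "FUN", 0, 3),
        # social/family well-being
        Item("item7", "SOC", 0, 2),
        Item("item10", "SOC", 0, 2),
        # sexual well-being
        Item("item13a", "SEX", 0, 3),
        Item("item13b", "SEX", 0, 3),
        Item("item13c", "SEX", 0, 3),
        Item("item13d", "SEX", 0, 3),
        # fatigue: symptom frequency, higher raw = worse
        Item("item11a", "FAT", 0, 3, reverse=True),
        Item("item11b", "FAT", 0, 3, reverse=True),
        Item("item11c", "FAT", 0, 3, reverse=True),
        Item("item11d", "FAT", 0, 3, reverse=True),
        Item("item11e", "FAT", 0, 3, reverse=True),
        Item("item11f", "FAT", 0, 3, reverse=True),
        Item("item12", "FAT", 0, 3, reverse=True),
        # MDS-specific disturbances, higher raw = worse
        Item("item15a", "MDSS", 0, 6, reverse=True),
        Item("item15b", "MDSS", 0, 6, reverse=True),
        Item("item15c", "MDSS", 0, 6, reverse=True),
        Item("item15d", "MDSS", 0, 6, reverse=True),
        Item("item15e", "MDSS", 0, 6, reverse=True),
        Item("item15f", "MDSS", 0, 6, reverse=True),
        Item("item15g", "MDSS", 0, 6, reverse=True),
    ]
    return ScoringSchema(items=tuple(items))


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def score_domains(responses: Mapping[str, float | None],
                  schema: ScoringSchema) -> dict[str, float]:
    """Standardized 0-100 domain scores for one patient-visit.

    ``responses`` maps item_id -> raw response (``None``/NaN = missing).
    Unknown item ids raise :class:`SchemaError`; out-of-range responses
    raise :class:`ResponseError`.  A domain with fewer than
    ``min_answered_fraction`` of its items answered is NaN; otherwise the
    oriented sum of answered items is prorated to the full domain range.
    """
    for item_id, raw in responses.items():
        if raw is None or (isinstance(raw, float) and math.isnan(raw)):
            continue
        it = schema.item(item_id)  # raises SchemaError if unknown
        if not (it.raw_min <= raw <= it.raw_max):
            raise ResponseError(
                f"response {raw!r} for item {item_id!r} outside "
                f"[{it.raw_min}, {it.raw_max}]"
            )
    scores: dict[str, float] = {}
    for domain in DOMAINS:
        items = schema.domain_items(domain)
        oriented: list[float] = []
        answered_range = 0
        for it in items:
            raw = responses.get(it.item_id)
            if raw is None or (isinstance(raw, float) and math.isnan(raw)):
                continue
            oriented.append(it.oriented(raw))
            answered_range += it.raw_range
        if len(oriented) / len(items) < schema.min_answered_fraction or not oriented:
            scores[domain] = float("nan")
        else:
            scores[domain] = 100.0 * sum(oriented) / answered_range
    return scores


def score_summaries(domains: Mapping[str, float],
                    schema: ScoringSchema) -> dict[str, float]:
    """GEN/ALL/TOI summary scores from the six domain scores.

    Missing constituents propagate to a missing summary, except that SEX
    may be dropped from any summary mean that includes it.
    """
    resolved: dict[str, float] = {d: float(domains.get(d, float("nan"))) for d in DOMAINS}

    out: dict[str, float] = {}
    # compute in dependency order: GEN before ALL (which references it)
    for summary in ("GEN", "ALL", "TOI"):
        parts = schema.summary_composition[summary]
        vals: list[float] = []
        missing = False
        for p in parts:
            v = out[p] if p in SUMMARIES else resolved[p]
            if math.isnan(v):
                if p in OPTIONAL_SUMMARY_CONSTITUENTS:
                    continue
                missing = True
                break
            vals.append(v)
        out[summary] = float("nan") if (missing or not vals) else sum(vals) / len(vals)
    return {s: out[s] for s in SUMMARIES}


def minimum_possible_change(schema: ScoringSchema, domain: str) -> float:
    """Smallest nonzero step of a standardized domain score, 100 / raw range.

    Reported rounded to one decimal, matching how the thresholds literature
    tabulates it.  The general-well-being pseudo-domain has no score.
    """
    if domain == GENERAL:
        raise SchemaError("general well-being items do not form a scored domain")
    if domain not in DOMAINS:
        raise SchemaError(f"unknown domain {domain!r}")
    return round(100.0 / schema.domain_raw_range(domain), 1)


# ---------------------------------------------------------------------------
# dataframe-level scoring
# ---------------------------------------------------------------------------

def score_dataframe(df: pd.DataFrame, schema: ScoringSchema) -> pd.DataFrame:
    """Score a wide cohort table (one row per patient-visit) into a panel.

    Input columns: ``patient_id``, ``trial``, ``visit`` plus one column per
    item id (missing = NaN).  Returns the score panel with the same id
    columns plus the nine score columns FIS..TOI.
    """
    panel = df.loc[:, [c for c in ID_COLUMNS if c in df.columns]].copy()
    oriented: dict[str, pd.Series] = {}
    for it in schema.items:
        if it.domain == GENERAL:
            continue
        if it.item_id in df.columns:
            raw = pd.to_numeric(df[it.item_id], errors="coerce")
            bad = raw.notna() & ((raw < it.raw_min) | (raw > it.raw_max))
            if bad.any():
                i = bad[bad].index[0]
                raise ResponseError(
                    f"response {raw.loc[i]!r} for item {it.item_id!r} outside "
                    f"[{it.raw_min}, {it.raw_max}] (row {i})"
                )
            oriented[it.item_id] = it.oriented(raw)
        else:
            oriented[it.item_id] = pd.Series(np.nan, index=df.index)
    for domain in DOMAINS:
        items = schema.domain_items(domain)
        vals = pd.concat([oriented[it.item_id] for it in items], axis=1)
        ranges = np.array([it.raw_range for it in items], dtype=float)
        answered = vals.notna()
        answered_range = (answered * ranges).sum(axis=1)
        frac = answered.sum(axis=1) / len(items)
        score = 100.0 * vals.sum(axis=1) / answered_range.replace(0, np.nan)
        score[frac < schema.min_answered_fraction] = np.nan
        panel[domain] = score
    # summaries, vectorized with the SEX-optional rule
    required = {s: [d for d in schema.summary_domains(s)
                    if d not in OPTIONAL_SUMMARY_CONSTITUENTS]
                for s in SUMMARIES}
    gen_req = panel[list(required["GEN"])]
    gen_ok = gen_req.notna().all(axis=1)
    sex = panel["SEX"] if "SEX" in schema.summary_domains("GEN") else pd.Series(np.nan, index=panel.index)
    gen = (gen_req.sum(axis=1) + sex.fillna(0.0)) / (len(required["GEN"]) + sex.notna())
    panel["GEN"] = gen.where(gen_ok)
    panel["ALL"] = (panel["GEN"] + panel["MDSS"]) / 2.0
    toi_parts = panel[list(schema.summary_domains("TOI"))]
    panel["TOI"] = toi_parts.mean(axis=1).where(toi_parts.notna().all(axis=1))
    return panel


def filter_analysis_population(
    panel: pd.DataFrame,
) -> tuple[pd.DataFrame, list[dict]]:
    """Keep patients with at least one non-missing baseline domain score.

    Returns the filtered panel (all visits for retained patients) and an
    exclusion log of ``{"patient_id", "reason"}`` entries.
    """
    if panel.empty:
        logger.warning("filter_analysis_population: empty input panel")
        return panel.copy(), []
    log: list[dict] = []
    baseline = panel[panel["visit"] == "baseline"]
    has_baseline_score = baseline.groupby("patient_id")[list(DOMAINS)].apply(
        lambda g: g.notna().any().any()
    )
    keep: set[str] = set(has_baseline_score.index[has_baseline_score])
    for pid in pd.unique(panel["patient_id"]):
        if pid in keep:
            continue
        reason = ("no baseline visit" if pid not in set(baseline["patient_id"])
                  else "all baseline domain scores missing")
        log.append({"patient_id": pid, "reason": reason})
    return panel[panel["patient_id"].isin(keep)].copy(), log


def qlq_eligible_mask(df: pd.DataFrame) -> pd.Series:
    """True for rows usable in QLQ-C30-dependent analyses.

    The RevMDS-like trial did not administer the QLQ-C30 and is excluded
    from any analysis involving it.
    """
    return df["trial"] != "T4_rev_like"
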