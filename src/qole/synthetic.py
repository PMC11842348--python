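"""Seeded synthetic multi-trial cohorts with the structure the validation assumes.

The pooled validation cohort this generator emulates combines four trials
(227/34/158/39 patients) that all administered the QOL-E at baseline and
Week 24; only the MEDALIST-like trial adds a screening visit 14-35 days
before baseline, and the RevMDS-like trial did not administer the EORTC
QLQ-C30.

Generative model
----------------
* One latent HRQoL trait per domain, sharing a general factor (loading 0.6;
  sexual well-being loads weakly at 0.2) so inter-domain correlations land
  in the moderate band.
* Occasion latents mix the stable trait with fresh occasion noise at a rate
  calibrated so that the simulated test-retest correlation of the resulting
  0-100 domain scores approximates the configured ``occasion_reliability``
  (the ordinal readout attenuates latent correlations; per-domain
  calibration multipliers correct for this).
* Item responses are graded (cumulative-threshold) readouts of the occasion
  latent plus a patient-persistent item residual; thresholds per domain are
  set from target category probabilities, hand-tuned to the published
  floor/ceiling pattern (heavy floor for SOC, ceilings for FUN/SOC/SEX).
* Week-24 change is a latent shift (trial-specific small drift) that also
  drives the anchor items (QOL-E Items 1-2, QLQ-C30 Items 29-30) and,
  weakly, the clinical outcomes, so change-score correlations land in the
  0.3-0.5 band for the two good anchors and below 0.3 for the clinical ones.
* Clinical outcomes: baseline Hb ~ Normal(9.5, 1.9) g/dL, transfusion
  dependence with probability 0.683 (>=1 RBC unit in the prior 8 weeks),
  platelet counts from a three-component mixture.

All randomness flows from one root seed through named substreams so each
component is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import DOMAINS, TRIALS, ScoringSchema, default_schema

# QLQ-C30 scale columns emitted by the generator (15 scales + Items 29/30).
QLQ_SCALES: tuple[str, ...] = (
    "qlq_global_health",
    "qlq_physical_functioning",
    "qlq_role_functioning",
    "qlq_emotional_functioning",
    "qlq_cognitive_functioning",
    "qlq_social_functioning",
    "qlq_fatigue",
    "qlq_nausea_vomiting",
    "qlq_pain",
    "qlq_dyspnea",
    "qlq_insomnia",
    "qlq_appetite_loss",
    "qlq_constipation",
    "qlq_diarrhea",
    "qlq_financial_difficulties",
)
QLQ_ITEMS: tuple[str, ...] = ("qlq_item29", "qlq_item30")
CLINICAL_COLUMNS: tuple[str, ...] = (
    "hb_g_dl", "rbc_units_8wk", "platelet_count_e9_l", "platelet_units_8wk",
)

#: scale -> (driving domain latent or "general", sign).  Symptom scales are
#: coded 0-100 with higher = more symptoms, hence the negative signs.
_QLQ_DRIVERS: dict[str, tuple[str, float]] = {
    "qlq_global_health": ("general", +0.75),
    "qlq_physical_functioning": ("FIS", +0.75),
    "qlq_role_functioning": ("FUN", +0.72),
    "qlq_emotional_functioning": ("general", +0.62),
    "qlq_cognitive_functioning": ("general", +0.55),
    "qlq_social_functioning": ("SOC", +0.70),
    "qlq_fatigue": ("FAT", -0.78),
    "qlq_nausea_vomiting": ("general", -0.35),
    "qlq_pain": ("general", -0.55),
    "qlq_dyspnea": ("FIS", -0.55),
    "qlq_insomnia": ("FAT", -0.45),
    "qlq_appetite_loss": ("FAT", -0.45),
    "qlq_constipation": ("general", -0.30),
    "qlq_diarrhea": ("general", -0.18),
    "qlq_financial_difficulties": ("SOC", -0.38),
}


@dataclass(frozen=True)
class AnchorModel:
    """Ordinal-threshold readouts of overall health / latent change."""

    #: loading of the overall-health latent on QOL-E Item 1 (state anchor)
    item1_loading: float = 0.93
    #: marginal category probabilities for Item 1, worst (poor) to best
    #: (excellent); roughly the published known-group sizes
    item1_probs: tuple[float, ...] = (0.20, 0.49, 0.29, 0.02)
    #: Item 2 rates recent change directly; readout of the latent shift
    item2_loading: float = 0.45
    item2_probs: tuple[float, ...] = (0.08, 0.22, 0.40, 0.22, 0.08)
    item29_loading: float = 0.93
    item29_probs: tuple[float, ...] = (0.02, 0.08, 0.20, 0.30, 0.25, 0.12, 0.03)
    item30_loading: float = 0.60
    item30_probs: tuple[float, ...] = (0.02, 0.08, 0.20, 0.30, 0.25, 0.12, 0.03)


@dataclass(frozen=True)
class ChangeModel:
    """Latent Week-24 shift and its propagation to domains and anchors."""

    sd: float = 1.0
    #: trial-specific mean drift of the latent shift
    trial_drift: Mapping[str, float] = field(default_factory=lambda: {
        "T1_medalist_like": 0.05,
        "T2_darb_like": 0.30,
        "T3_eqol_like": 0.00,
        "T4_rev_like": 0.25,
    })
    #: loading of the shared shift onto each domain's latent change
    domain_loading: Mapping[str, float] = field(default_factory=lambda: {
        "FIS": 0.72, "FUN": 0.72, "SOC": 0.68, "SEX": 0.15,
        "FAT": 0.72, "MDSS": 0.72,
    })
    #: SD of the domain-specific change component
    domain_noise_sd: float = 0.35


@dataclass(frozen=True)
class ClinicalModel:
    hb_mean: float = 9.5
    hb_sd: float = 1.9
    #: coupling of the latent shift to Hb change (g/dL per latent SD)
    hb_change_loading: float = 0.55
    hb_change_noise_sd: float = 1.05
    transfusion_dependence_p: float = 0.683
    rbc_units_mean: float = 2.2
    #: log-rate coupling of RBC units at Week 24 to the latent shift
    rbc_change_loading: float = -0.15
    #: platelet mixture: P(<100), P(100-400), P(>400) x10^9/L
    platelet_mixture: tuple[float, float, float] = (0.38, 0.51, 0.11)


@dataclass(frozen=True)
class Missingness:
    """Per-block missing-completely-at-random probabilities."""

    item: float = 0.03
    sex_item: float = 0.15
    qlq: float = 0.06
    clinical: float = 0.08
    week24_visit: float = 0.12
    screening_item1: float = 0.05


@dataclass(frozen=True)
class CohortConfig:
    """Everything :func:`generate_cohort` needs; defaults are the study conditions."""

    per_trial_n: Mapping[str, int] = field(default_factory=lambda: {
        "T1_medalist_like": 227,
        "T2_darb_like": 34,
        "T3_eqol_like": 158,
        "T4_rev_like": 39,
    })
    #: target test-retest reliability of each domain score
    occasion_reliability: Mapping[str, float] = field(default_factory=lambda: {
        "FIS": 0.66, "FUN": 0.57, "SOC": 0.77, "SEX": 0.81,
        "FAT": 0.72, "MDSS": 0.71,
    })
    #: affine map (intercept, slope) from the latent occasion stability to
    #: the simulated domain-score ICC, fitted once against large-n
    #: simulations of the default model; the generator inverts it so the
    #: realized ICC matches occasion_reliability.  The nonzero intercept
    #: reflects the patient-persistent item residuals, the slope < 1 the
    #: ordinal-readout attenuation.
    reliability_calibration: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "FIS": (0.159, 0.787), "FUN": (0.135, 0.829), "SOC": (0.148, 0.775),
            "SEX": (-0.010, 0.949), "FAT": (0.117, 0.855), "MDSS": (0.127, 0.860),
        })
    #: general-factor loading per domain latent
    general_loading: Mapping[str, float] = field(default_factory=lambda: {
        "FIS": 0.6, "FUN": 0.6, "SOC": 0.6, "SEX": 0.2, "FAT": 0.6, "MDSS": 0.6,
    })
    #: item discrimination (loading of the occasion latent on each item)
    item_loading: float = 0.85
    #: oriented per-item category probabilities (worst..best); tuned so the
    #: pooled baseline means span ~47.5 (SOC) to ~74 (FAT), SOC has a heavy
    #: floor and FUN/SOC/SEX show >15% ceilings
    level_probs: Mapping[str, tuple[float, ...]] = field(default_factory=lambda: {
        "FIS": (0.21, 0.47, 0.32),
        "FUN": (0.17, 0.20, 0.25, 0.38),
        "SOC": (0.36, 0.32, 0.32),
        "SEX": (0.24, 0.12, 0.14, 0.50),
        "FAT": (0.05, 0.15, 0.38, 0.42),
        "MDSS": (0.04, 0.07, 0.12, 0.17, 0.22, 0.21, 0.17),
    })
    change_model: ChangeModel = field(default_factory=ChangeModel)
    anchor_model: AnchorModel = field(default_factory=AnchorModel)
    clinical_model: ClinicalModel = field(default_factory=ClinicalModel)
    missingness: Missingness = field(default_factory=Missingness)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.per_trial_n.values()):
            raise ValueError("per_trial_n values must be >= 0")
        if all(n == 0 for n in self.per_trial_n.values()):
            raise ValueError("at least one trial must have n > 0")
        if not isinstance(self.seed, (int, np.integer)) or isinstance(self.seed, bool):
            raise TypeError(f"seed must be an integer, got {type(self.seed).__name__}")
        for d, r in self.occasion_reliability.items():
            if not 0 <= r <= 1:
                raise ValueError(f"occasion_reliability[{d}] must lie in [0,1]")
        for probs in self.level_probs.values():
            if abs(sum(probs) - 1.0) > 1e-9 or any(p < 0 for p in probs):
                raise ValueError("level_probs must be non-negative and sum to 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in list(d.items()):
            if isinstance(v, Mapping):
                d[k] = dict(v)
        return d


_STREAMS = ("latent", "items", "anchors", "qlq", "clinical", "missingness")


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    """Named, independent substreams derived from one root seed."""
    return {
        name: np.random.default_rng(np.random.SeedSequence([int(seed), i]))
        for i, name in enumerate(_STREAMS)
    }


def _thresholds(probs: tuple[float, ...]) -> np.ndarray:
    """Standard-normal cut points realizing the marginal category probs."""
    cum = np.cumsum(probs)[:-1]
    return stats.norm.ppf(np.clip(cum, 1e-12, 1 - 1e-12))


def _grade(latent: np.ndarray, cuts: np.ndarray) -> np.ndarray:
    """Ordinal level = number of cut points below the latent value."""
    return (latent[..., None] > cuts).sum(axis=-1)


def generate_cohort(config: CohortConfig | None = None,
                    schema: ScoringSchema | None = None) -> pd.DataFrame:
    """Simulate the pooled four-trial cohort.

    Returns a wide table, one row per patient-visit: id columns, the 29 item
    responses (raw coding), QLQ-C30 scale scores and Items 29/30, and the
    four clinical outcomes.  Screening rows exist only for the
    MEDALIST-like trial; QLQ-C30 columns are missing for the RevMDS-like
    trial.
    """
    config = config or CohortConfig()
    schema = schema or default_schema()
    rng = _rngs(config.seed)
    cm, am, cl, miss = (config.change_model, config.anchor_model,
                        config.clinical_model, config.missingness)

    frames: list[pd.DataFrame] = []
    for t_idx, trial in enumerate(TRIALS):
        n = int(config.per_trial_n.get(trial, 0))
        if n == 0:
            continue
        has_screening = trial == "T1_medalist_like"
        has_qlq = trial != "T4_rev_like"
        visits = (["screening"] if has_screening else []) + ["baseline", "week24"]

        # ---- latent structure -----------------------------------------
        g = rng["latent"].normal(size=n)
        theta: dict[str, np.ndarray] = {}
        for d in DOMAINS:
            lam = config.general_loading[d]
            theta[d] = lam * g + np.sqrt(1 - lam ** 2) * rng["latent"].normal(size=n)
        delta_shared = (cm.trial_drift.get(trial, 0.0)
                        + cm.sd * rng["latent"].normal(size=n))
        delta: dict[str, np.ndarray] = {
            d: (cm.domain_loading[d] * delta_shared
                + cm.domain_noise_sd * rng["latent"].normal(size=n))
            for d in DOMAINS
        }
        occ: dict[tuple[str, str], np.ndarray] = {}
        for d in DOMAINS:
            a0, b0 = config.reliability_calibration[d]
            rho = float(np.clip((config.occasion_reliability[d] - a0) / b0, 0.0, 1.0))
            sr, sn = np.sqrt(rho), np.sqrt(1 - rho)
            for visit in visits:
                trait = theta[d] + (delta[d] if visit == "week24" else 0.0)
                occ[(d, visit)] = sr * trait + sn * rng["latent"].normal(size=n)

        # ---- item responses -------------------------------------------
        a = config.item_loading
        b = np.sqrt(1 - a ** 2)
        resp: dict[tuple[str, str], np.ndarray] = {}
        for d in DOMAINS:
            cuts = _thresholds(tuple(config.level_probs[d]))
            for it in schema.domain_items(d):
                resid = rng["items"].normal(size=n)  # persistent per patient-item
                for visit in visits:
                    x = a * occ[(d, visit)] + b * resid
                    lev = _grade(x, cuts)
                    raw = (it.raw_max - lev) if it.reverse else (it.raw_min + lev)
                    resp[(it.item_id, visit)] = raw.astype(float)

        # ---- anchors ---------------------------------------------------
        nonsex = [d for d in DOMAINS if d != "SEX"]
        health = {v: np.mean([occ[(d, v)] for d in nonsex], axis=0) for v in visits}
        hsd = {v: np.std(health[v]) or 1.0 for v in visits}
        anchors: dict[tuple[str, str], np.ndarray] = {}
        for v in visits:
            h = health[v] / hsd[v]
            for name, loading, probs in (
                ("item1", am.item1_loading, am.item1_probs),
                ("qlq_item29", am.item29_loading, am.item29_probs),
                ("qlq_item30", am.item30_loading, am.item30_probs),
            ):
                z = loading * h + np.sqrt(1 - loading ** 2) * rng["anchors"].normal(size=n)
                lev = _grade(z, _thresholds(probs))
                anchors[(name, v)] = lev.astype(float) + (1.0 if name != "item1" else 0.0)
            # Item 2 rates change directly: noise-only at screening/baseline,
            # a readout of the standardized shift at Week 24
            drive = delta_shared / max(cm.sd, 1e-9) if v == "week24" else np.zeros(n)
            z2 = am.item2_loading * drive + np.sqrt(1 - am.item2_loading ** 2) \
                * rng["anchors"].normal(size=n)
            anchors[("item2", v)] = _grade(z2, _thresholds(am.item2_probs)).astype(float)

        # ---- QLQ-C30 scales -------------------------------------------
        qlq: dict[tuple[str, str], np.ndarray] = {}
        if has_qlq:
            for v in visits:
                h = health[v] / hsd[v]
                for scale, (driver, loading) in _QLQ_DRIVERS.items():
                    base = h if driver == "general" else occ[(driver, v)]
                    z = abs(loading) * base + np.sqrt(1 - loading ** 2) \
                        * rng["qlq"].normal(size=n)
                    score = 100.0 * stats.norm.cdf(z)
                    qlq[(scale, v)] = score if loading > 0 else 100.0 - score

        # ---- clinical outcomes ----------------------------------------
        hb_base = np.clip(rng["clinical"].normal(cl.hb_mean, cl.hb_sd, size=n), 4.0, 18.0)
        hb_w24 = hb_base + cl.hb_change_loading * delta_shared \
            + rng["clinical"].normal(0.0, cl.hb_change_noise_sd, size=n)
        tdep = rng["clinical"].random(size=n) < cl.transfusion_dependence_p
        rbc_base = np.where(tdep, 1 + rng["clinical"].poisson(cl.rbc_units_mean, size=n), 0)
        lam24 = np.exp(np.log(cl.rbc_units_mean)
                       + cl.rbc_change_loading * delta_shared)
        rbc_w24 = np.where(tdep, rng["clinical"].poisson(lam24), 0)
        cat = rng["clinical"].choice(3, size=n, p=cl.platelet_mixture)
        lo = np.array([10.0, 100.0, 400.0])[cat]
        hi = np.array([100.0, 400.0, 900.0])[cat]
        plt_base = np.exp(rng["clinical"].uniform(np.log(lo), np.log(hi)))
        plt_w24 = plt_base * np.exp(rng["clinical"].normal(0.0, 0.2, size=n))
        plt_units = {
            v: np.where(p < 100.0, rng["clinical"].poisson(0.8, size=n),
                        rng["clinical"].poisson(0.05, size=n)).astype(float)
            for v, p in (("baseline", plt_base), ("week24", plt_w24))
        }

        # ---- assemble rows --------------------------------------------
        pids = [f"{trial.split('_')[0]}-{i + 1:04d}" for i in range(n)]
        for visit in visits:
            row: dict[str, np.ndarray | list | str] = {
                "patient_id": pids, "trial": trial, "visit": visit,
            }
            row["item1"] = anchors[("item1", visit)]
            row["item2"] = anchors[("item2", visit)]
            for it in schema.items:
                if it.domain != "GENERAL":
                    row[it.item_id] = resp[(it.item_id, visit)]
            for col in QLQ_SCALES:
                row[col] = qlq[(col, visit)] if has_qlq else np.nan
            for col in ("qlq_item29", "qlq_item30"):
                row[col] = anchors[(col, visit)] if has_qlq else np.nan
            row["hb_g_dl"] = np.round(hb_w24 if visit == "week24" else hb_base, 1)
            row["rbc_units_8wk"] = (rbc_w24 if visit == "week24" else rbc_base).astype(float)
            row["platelet_count_e9_l"] = np.round(
                plt_w24 if visit == "week24" else plt_base, 0)
            row["platelet_units_8wk"] = plt_units["week24" if visit == "week24"
                                                  else "baseline"]
            frames.append(pd.DataFrame(row))

    df = pd.concat(frames, ignore_index=True)
    df = _apply_missingness(df, schema, miss, rng["missingness"])
    order = {t: i for i, t in enumerate(TRIALS)}
    vorder = {"screening": 0, "baseline": 1, "week24": 2}
    df = df.sort_values(
        ["trial", "patient_id", "visit"],
        key=lambda s: s.map(order) if s.name == "trial"
        else (s.map(vorder) if s.name == "visit" else s),
    ).reset_index(drop=True)
    return df


def _apply_missingness(df: pd.DataFrame, schema: ScoringSchema,
                       miss: Missingness, rng: np.random.Generator) -> pd.DataFrame:
    df = df.copy()
    n = len(df)
    sex_ids = {it.item_id for it in schema.domain_items("SEX")}
    pro_cols = [it.item_id for it in schema.items] + list(QLQ_ITEMS)
    # whole-PRO dropout at Week 24 (patient skipped the assessment)
    w24 = (df["visit"] == "week24").to_numpy()
    drop = w24 & (rng.random(n) < miss.week24_visit)
    for col in pro_cols + list(QLQ_SCALES):
        df.loc[drop, col] = np.nan
    for it in schema.items:
        p = miss.sex_item if it.item_id in sex_ids else miss.item
        df.loc[rng.random(n) < p, it.item_id] = np.nan
    scr = (df["visit"] == "screening").to_numpy()
    df.loc[scr & (rng.random(n) < miss.screening_item1), "item1"] = np.nan
    for col in list(QLQ_SCALES) + list(QLQ_ITEMS):
        df.loc[rng.random(n) < miss.qlq, col] = np.nan
    for col in CLINICAL_COLUMNS:
        df.loc[rng.random(n) < miss.clinical, col] = np.nan
    return df


def make_stable_flag(df: pd.DataFrame) -> pd.Series:
    """Per-patient stability flag for the test-retest subset.

    A patient is "stable" when the Item 1 overall-health rating is identical
    at screening and baseline.  Patients without both responses (all trials
    except the MEDALIST-like one lack a screening visit) get a missing flag.
    """
    item1 = df.pivot_table(index="patient_id", columns="visit", values="item1",
                           aggfunc="first", dropna=False)
    for col in ("screening", "baseline"):
        if col not in item1.columns:
            item1[col] = np.nan
    both = item1["screening"].notna() & item1["baseline"].notna()
    flag = pd.Series(np.nan, index=item1.index, dtype=object, name="stable")
    flag[both] = (item1.loc[both, "screening"] == item1.loc[both, "baseline"])
    return flag
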