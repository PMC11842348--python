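"""Reliability: test-retest ICC(A,1), Cronbach alpha, McDonald omega.

Test-retest reliability is the intraclass correlation for absolute
agreement between single scores, ICC(A,1) in the McGraw-Wong naming, from a
two-way mixed-effects ANOVA with interaction:

    ICC(A,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))

where MS_R, MS_C, MS_E are the between-subjects, between-occasions, and
residual mean squares of an n-subjects x k-occasions table.  In the QOL-E
validation design the two occasions are the screening and baseline visits
of the MEDALIST-like trial, restricted to patients whose Item 1
overall-health rating was identical at both ("stable" patients).

Internal consistency is summarized by Cronbach alpha (raw and
standardized, with leave-one-item-out values) and by McDonald omega from a
single-factor model, omega = (sum lambda)^2 / ((sum lambda)^2 + sum psi),
which drops alpha's tau-equivalence assumption.  The factor model is fit by
minimum residual: loadings minimize the squared off-diagonal discrepancy of
the item correlation matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .scoring import DOMAINS, SUMMARIES, ScoringSchema, OPTIONAL_SUMMARY_CONSTITUENTS
from .validity import spearman

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnovaDecomposition:
    n_subjects: int
    k_occasions: int
    ms_rows: float
    ms_cols: float
    ms_error: float


@dataclass
class OmegaResult:
    omega: float
    loadings: np.ndarray
    uniquenesses: np.ndarray
    converged: bool
    heywood: bool


def icc_a1(matrix) -> tuple[float, AnovaDecomposition]:
    """ICC(A,1) of an n x k subjects-by-occasions score matrix.

    Requires at least 3 subjects, 2 occasions, and no missing cells (apply
    listwise deletion upstream).  A matrix with zero total variance has no
    defined ICC and returns NaN with a warning.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("matrix must be 2-dimensional (subjects x occasions)")
    n, k = x.shape
    if n < 3 or k < 2:
        raise ValueError(f"need >=3 subjects and >=2 occasions, got {n}x{k}")
    if np.isnan(x).any():
        raise ValueError("matrix contains missing cells; listwise-delete first")
    grand = x.mean()
    if np.allclose(x, grand):
        warnings.warn("constant matrix: ICC undefined", stacklevel=2)
        dec = AnovaDecomposition(n, k, 0.0, 0.0, 0.0)
        return float("nan"), dec
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    icc = (ms_r - ms_e) / (ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e))
    return float(icc), AnovaDecomposition(n, k, float(ms_r), float(ms_c), float(ms_e))


# ---------------------------------------------------------------------------
# internal consistency
# ---------------------------------------------------------------------------

@dataclass
class AlphaResult:
    alpha_raw: float
    alpha_standardized: float
    alpha_if_deleted: dict[str, float] = field(default_factory=dict)
    n: int = 0
    dropped_items: list[str] = field(default_factory=list)


def _standardized_alpha(corr: np.ndarray) -> float:
    k = corr.shape[0]
    iu = np.triu_indices(k, 1)
    rbar = corr[iu].mean()
    return k * rbar / (1 + (k - 1) * rbar)


def cronbach_alpha(items: pd.DataFrame | np.ndarray) -> AlphaResult:
    """Raw and standardized Cronbach alpha with leave-one-out values.

    ``items`` is an n x k matrix (columns = items); rows with any missing
    value are dropped (listwise).  Zero-variance items cannot enter the
    standardized coefficient (their correlations are undefined) and are
    excluded from it with a warning.
    """
    df = pd.DataFrame(items).dropna()
    n, k = df.shape
    if k < 2:
        raise ValueError("need at least 2 items")
    x = df.to_numpy(float)
    var_items = x.var(axis=0, ddof=1)
    var_total = x.sum(axis=1).var(ddof=1)
    alpha_raw = (k / (k - 1)) * (1 - var_items.sum() / var_total) \
        if var_total > 0 else float("nan")
    keep = var_items > 0
    dropped = [str(c) for c, ok in zip(df.columns, keep) if not ok]
    if dropped:
        warnings.warn(f"zero-variance items excluded from standardized alpha: {dropped}",
                      stacklevel=2)
    cols = [c for c, ok in zip(df.columns, keep) if ok]
    alpha_std = float("nan")
    deleted: dict[str, float] = {}
    if len(cols) >= 2:
        corr = df[cols].corr().to_numpy()
        alpha_std = _standardized_alpha(corr)
        if len(cols) >= 3:
            for c in cols:
                rest = [d for d in cols if d != c]
                deleted[str(c)] = _standardized_alpha(df[rest].corr().to_numpy())
    return AlphaResult(alpha_raw=float(alpha_raw), alpha_standardized=float(alpha_std),
                       alpha_if_deleted=deleted, n=n, dropped_items=dropped)


def mcdonald_omega(items: pd.DataFrame | np.ndarray,
                   corr: np.ndarray | None = None,
                   tol: float = 1e-8, max_iter: int = 500) -> OmegaResult:
    """McDonald omega from a single-factor minimum-residual fit.

    Either raw item data (n x k, listwise-deleted) or a ready-made item
    correlation matrix can be supplied.  Needs k >= 3 for identifiability.
    Heywood cases (negative uniqueness, i.e. |loading| > 1) are clipped to a
    uniqueness of 0 and flagged.  Non-convergence yields a missing omega.
    """
    if corr is None:
        df = pd.DataFrame(items).dropna()
        if df.shape[1] < 3:
            raise ValueError("need at least 3 items for a single-factor fit")
        corr = df.corr().to_numpy()
    corr = np.asarray(corr, dtype=float)
    k = corr.shape[0]
    if k < 3:
        raise ValueError("need at least 3 items for a single-factor fit")
    iu = np.triu_indices(k, 1)

    def resid(lam: np.ndarray) -> np.ndarray:
        model = np.outer(lam, lam)
        return (corr - model)[iu]

    # first principal axis as the starting point
    evals, evecs = np.linalg.eigh(corr)
    lam0 = evecs[:, -1] * np.sqrt(max(evals[-1], 1e-6))
    if lam0.sum() < 0:
        lam0 = -lam0
    sol = optimize.least_squares(resid, lam0, xtol=tol, ftol=tol, gtol=tol,
                                 max_nfev=max_iter * k)
    converged = bool(sol.status > 0)
    if not converged:
        logger.warning("single-factor fit did not converge: %s", sol.message)
        return OmegaResult(float("nan"), sol.x, 1 - sol.x ** 2, False, False)
    lam = sol.x if sol.x.sum() >= 0 else -sol.x
    psi = 1.0 - lam ** 2
    heywood = bool((psi < 0).any())
    psi = np.clip(psi, 0.0, None)
    if heywood:
        logger.warning("Heywood case: uniqueness clipped at 0")
    s = lam.sum()
    omega = s ** 2 / (s ** 2 + psi.sum())
    return OmegaResult(float(omega), lam, psi, converged, heywood)


# ---------------------------------------------------------------------------
# panel-level helpers
# ---------------------------------------------------------------------------

def test_retest_matrix(panel: pd.DataFrame, stable: pd.Series,
                       score: str) -> np.ndarray:
    """Screening/baseline score pairs for stable MEDALIST-like patients."""
    sub = panel[(panel["trial"] == "T1_medalist_like")
                & panel["visit"].isin(("screening", "baseline"))]
    wide = sub.pivot_table(index="patient_id", columns="visit", values=score,
                           aggfunc="first", dropna=False)
    stable_ids = stable.index[stable == True]  # noqa: E712 (NaN-valued object series)
    wide = wide.reindex(wide.index.intersection(stable_ids))
    wide = wide.dropna(subset=["screening", "baseline"])
    return wide[["screening", "baseline"]].to_numpy(float)


def test_retest_table(panel: pd.DataFrame, stable: pd.Series) -> pd.DataFrame:
    """ICC(A,1) per score on the stable screening/baseline subset."""
    rows = []
    for score in DOMAINS + SUMMARIES:
        m = test_retest_matrix(panel, stable, score)
        if m.shape[0] >= 3:
            icc, dec = icc_a1(m)
            rows.append({"score": score, "n": dec.n_subjects, "icc": icc})
        else:
            rows.append({"score": score, "n": m.shape[0], "icc": float("nan")})
    return pd.DataFrame(rows)


def item_matrix(records: pd.DataFrame, schema: ScoringSchema, domain: str,
                visits: tuple[str, ...] = ("baseline",)) -> pd.DataFrame:
    """Oriented item-response matrix for one domain (rows = patient-visits)."""
    sub = records[records["visit"].isin(visits)]
    out = {}
    for it in schema.domain_items(domain):
        out[it.item_id] = it.oriented(pd.to_numeric(sub[it.item_id], errors="coerce"))
    return pd.DataFrame(out, index=sub.index)


def internal_consistency_table(records: pd.DataFrame, schema: ScoringSchema,
                               panel: pd.DataFrame | None = None) -> pd.DataFrame:
    """Alpha and omega per domain, plus omega for the three summary scores.

    Domain coefficients are computed on baseline item responses.  Summary
    omegas treat the constituent domain scores as the "items" of the
    summary composite.
    """
    rows = []
    for domain in DOMAINS:
        mat = item_matrix(records, schema, domain)
        alpha = cronbach_alpha(mat)
        # a two-item domain cannot identify a single-factor model
        omega = mcdonald_omega(mat).omega if mat.shape[1] >= 3 else float("nan")
        rows.append({"score": domain, "n": alpha.n,
                     "alpha_raw": alpha.alpha_raw,
                     "alpha_standardized": alpha.alpha_standardized,
                     "omega": omega})
    if panel is not None:
        base = panel[panel["visit"] == "baseline"]
        for summary in SUMMARIES:
            parts = [d for d in schema.summary_domains(summary)]
            mat = base[parts].dropna(
                subset=[p for p in parts if p not in OPTIONAL_SUMMARY_CONSTITUENTS])
            mat = mat.dropna()
            if mat.shape[1] >= 3 and len(mat) > mat.shape[1]:
                omega = mcdonald_omega(mat)
                rows.append({"score": summary, "n": len(mat),
                             "alpha_raw": float("nan"),
                             "alpha_standardized": float("nan"),
                             "omega": omega.omega})
    return pd.DataFrame(rows)


def alpha_if_deleted_table(records: pd.DataFrame,
                           schema: ScoringSchema) -> pd.DataFrame:
    """Standardized alpha after deleting each item, per domain."""
    rows = []
    for domain in DOMAINS:
        mat = item_matrix(records, schema, domain)
        res = cronbach_alpha(mat)
        for item_id, a in res.alpha_if_deleted.items():
            rows.append({"domain": domain, "item": item_id,
                         "alpha_standardized_if_deleted": a,
                         "alpha_standardized_full": res.alpha_standardized})
    return pd.DataFrame(rows)


def corrected_summary_score(panel: pd.DataFrame, schema: ScoringSchema,
                            summary: str, excluded_domain: str) -> pd.Series:
    """Summary score recomputed without one constituent domain."""
    parts = [d for d in schema.summary_domains(summary) if d != excluded_domain]
    if not parts:
        raise ValueError(f"{summary} without {excluded_domain} has no constituents")
    required = [p for p in parts if p not in OPTIONAL_SUMMARY_CONSTITUENTS]
    sub = panel[parts]
    ok = sub[required].notna().all(axis=1) if required else sub.notna().any(axis=1)
    return sub.mean(axis=1).where(ok)


def corrected_summary_correlations(panel: pd.DataFrame,
                                   schema: ScoringSchema) -> pd.DataFrame:
    """Spearman of each domain vs its corrected summary, pooled visits."""
    pooled = panel[panel["visit"].isin(("baseline", "week24"))]
    rows = []
    for summary in SUMMARIES:
        for domain in schema.summary_domains(summary):
            corrected = corrected_summary_score(pooled, schema, summary, domain)
            res = spearman(pooled[domain], corrected)
            rows.append({"domain": domain, "summary": summary,
                         "n": res.n, "r": res.r, "p": res.p})
    return pd.DataFrame(rows)
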