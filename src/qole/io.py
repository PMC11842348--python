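"""CSV readers/writers for cohort tables and score panels.

The cohort table is wide: one row per patient-visit with the columns
``patient_id``, ``trial``, ``visit``, one column per QOL-E item id, the
QLQ-C30 scale columns (``qlq_*``), and the clinical outcome columns.  A
long layout (one row per patient-visit-item) is also accepted for item
responses.  Missing values are empty cells.
"""

from __future__ import annotations

import pandas as pd

from .scoring import ID_COLUMNS, ResponseError, ScoringSchema, TRIALS, VISITS


def read_cohort_csv(path, schema: ScoringSchema, validate: bool = True) -> pd.DataFrame:
    """Strict wide-format reader; checks ids and item response ranges."""
    df = pd.read_csv(path)
    missing = [c for c in ID_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV lacks required columns {missing}")
    if validate:
        bad_trial = set(df["trial"].dropna()) - set(TRIALS)
        if bad_trial:
            raise ValueError(f"unknown trial labels {sorted(bad_trial)}")
        bad_visit = set(df["visit"].dropna()) - set(VISITS)
        if bad_visit:
            raise ValueError(f"unknown visit labels {sorted(bad_visit)}")
        scr = df[(df["visit"] == "screening") & (df["trial"] != "T1_medalist_like")]
        if len(scr):
            raise ValueError("screening visits are defined only for the "
                             "MEDALIST-like trial")
        for it in schema.items:
            if it.item_id not in df.columns:
                continue
            vals = pd.to_numeric(df[it.item_id], errors="coerce")
            bad = vals.notna() & ((vals < it.raw_min) | (vals > it.raw_max))
            if bad.any():
                i = bad[bad].index[0]
                raise ResponseError(
                    f"row {i}: response {vals.loc[i]!r} for item "
                    f"{it.item_id!r} outside [{it.raw_min}, {it.raw_max}]")
    return df


def read_cohort_long_csv(path, schema: ScoringSchema) -> pd.DataFrame:
    """Long layout: columns patient_id, trial, visit, item_id, response."""
    long = pd.read_csv(path)
    need = list(ID_COLUMNS) + ["item_id", "response"]
    missing = [c for c in need if c not in long.columns]
    if missing:
        raise ValueError(f"long cohort CSV lacks required columns {missing}")
    wide = long.pivot_table(index=list(ID_COLUMNS), columns="item_id",
                            values="response", aggfunc="first").reset_index()
    wide.columns.name = None
    return wide


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_panel_csv(panel: pd.DataFrame, path) -> None:
    panel.to_csv(path, index=False)


def read_panel_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ID_COLUMNS if c not in df.columns and c != "trial"]
    if missing:
        raise ValueError(f"panel CSV lacks required columns {missing}")
    return df
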