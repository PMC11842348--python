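"""Orchestration: simulate -> score -> distributional -> validity -> reliability -> MWPC.

Each stage writes its CSV outputs plus a JSON sidecar recording the stage
inputs, seed, and parameters; reruns with the same configuration and seed
produce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io
from .distributional import summarize_panel
from .mwpc import run_mwpc
from .reliability import (alpha_if_deleted_table, corrected_summary_correlations,
                          internal_consistency_table, test_retest_table)
from .scoring import ScoringSchema, default_schema, filter_analysis_population, score_dataframe
from .synthetic import CohortConfig, generate_cohort, make_stable_flag
from .validity import convergent_validity_table, known_groups

logger = logging.getLogger(__name__)

STAGES = ("simulate", "score", "distrib", "validity", "reliability", "mwpc")


@dataclass
class RunConfig:
    out_dir: Path
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    cohort_csv: Path | None = None  # input data when not simulating
    schema: ScoringSchema = field(default_factory=default_schema)
    cohort_config: CohortConfig | None = None

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("stage list must be non-empty")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")


def _write(df: pd.DataFrame, path: Path, sidecar: dict) -> None:
    df.to_csv(path, index=False, float_format="%.6g")
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, default=str))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in dependency order; return a manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "warnings": []}
    schema = config.schema
    records = panel = None
    stable = None

    def stage_done(name: str, outputs: list[str], t0: float) -> None:
        manifest["stages"][name] = {
            "outputs": outputs, "seconds": round(time.perf_counter() - t0, 3)}
        logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)

    if "simulate" in config.stages:
        t0 = time.perf_counter()
        cc = config.cohort_config or CohortConfig(seed=config.seed)
        records = generate_cohort(cc, schema)
        io.write_cohort_csv(records, out / "cohort.csv")
        (out / "cohort_config.json").write_text(
            json.dumps(cc.to_dict(), indent=2, default=str))
        stage_done("simulate", ["cohort.csv", "cohort_config.json"], t0)
    elif config.cohort_csv is not None:
        records = io.read_cohort_csv(config.cohort_csv, schema)

    needs_data = [s for s in config.stages if s != "simulate"]
    if needs_data and records is None:
        raise FileNotFoundError(
            f"stage {needs_data[0]!r} needs cohort data: run the simulate stage "
            "or supply --data with a cohort CSV")

    if records is not None and any(s in config.stages for s in STAGES[1:]):
        t0 = time.perf_counter()
        panel = score_dataframe(records, schema)
        panel, exclusions = filter_analysis_population(panel)
        records = records[records["patient_id"].isin(panel["patient_id"])]
        stable = make_stable_flag(records)
        if "score" in config.stages:
            _write(panel, out / "scores.csv",
                   {"stage": "score", "seed": config.seed,
                    "n_excluded": len(exclusions)})
            stage_done("score", ["scores.csv"], t0)

    if "distrib" in config.stages:
        t0 = time.perf_counter()
        dist = summarize_panel(panel)
        _write(dist, out / "distributional.csv", {"stage": "distrib", "seed": config.seed})
        stage_done("distrib", ["distributional.csv"], t0)

    if "validity" in config.stages:
        t0 = time.perf_counter()
        conv = convergent_validity_table(records, panel)
        kg1 = known_groups(records, panel, "item1_response")
        kg2 = known_groups(records, panel, "transfusion_dependency")
        _write(conv, out / "convergent_validity.csv", {"stage": "validity", "seed": config.seed})
        _write(pd.concat([kg1, kg2]), out / "known_groups.csv",
               {"stage": "validity", "seed": config.seed})
        stage_done("validity", ["convergent_validity.csv", "known_groups.csv"], t0)

    icc_table = None
    if "reliability" in config.stages or "mwpc" in config.stages:
        icc_table = test_retest_table(panel, stable)
    if "reliability" in config.stages:
        t0 = time.perf_counter()
        cons = internal_consistency_table(records, schema, panel)
        deleted = alpha_if_deleted_table(records, schema)
        corr = corrected_summary_correlations(panel, schema)
        _write(icc_table, out / "test_retest_icc.csv", {"stage": "reliability", "seed": config.seed})
        _write(cons, out / "internal_consistency.csv", {"stage": "reliability", "seed": config.seed})
        _write(deleted, out / "alpha_if_deleted.csv", {"stage": "reliability", "seed": config.seed})
        _write(corr, out / "corrected_summary_correlations.csv",
               {"stage": "reliability", "seed": config.seed})
        stage_done("reliability", ["test_retest_icc.csv", "internal_consistency.csv",
                                   "alpha_if_deleted.csv",
                                   "corrected_summary_correlations.csv"], t0)

    if "mwpc" in config.stages:
        t0 = time.perf_counter()
        res = run_mwpc(records, panel, schema, icc_table)
        _write(res["responsiveness"], out / "responsiveness.csv",
               {"stage": "mwpc", "seed": config.seed,
                "selected_anchors": res["selected_anchors"]})
        thr = pd.DataFrame([
            {"score": r.score, "improvement_threshold": r.improvement_threshold,
             "worsening_threshold": r.worsening_threshold,
             "range_lo": r.anchor_range[0], "range_hi": r.anchor_range[1],
             "consistent": r.consistent, "rationale": r.rationale}
            for r in res["thresholds"].values()
        ])
        _write(thr, out / "mwpc_thresholds.csv", {"stage": "mwpc", "seed": config.seed})
        _write(res["distribution_inputs"], out / "distribution_inputs.csv",
               {"stage": "mwpc", "seed": config.seed})
        stage_done("mwpc", ["responsiveness.csv", "mwpc_thresholds.csv",
                            "distribution_inputs.csv"], t0)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
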