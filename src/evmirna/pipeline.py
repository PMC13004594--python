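"""End-to-end orchestration: read -> QC -> filters -> normalize -> test -> select.

A :class:`PipelineConfig` (YAML-loadable, strictly validated) drives a run;
outputs are delimited tables plus a JSON manifest recording the config, its
hash, the seed, and the counts at every stage — wells rejected per QC rule,
assays surviving each filter, normalizers used, pairs dropped — so that a
run is auditable and exactly repeatable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import io as eio
from . import qc as eqc
from . import select as esel
from . import stats as est
from .exceptions import ConfigError
from .normalize import compute_delta_cq, select_normalizers
from .simulate import SimulationConfig, simulate_experiment

log = logging.getLogger(__name__)


class PathsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    well_table: str | None = None
    sample_sheet: str | None = None
    out_dir: str = "evmirna_out"


class NormalizationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    mode: str = "per_sample"             # or "per_group"
    override_normalizers: list[str] | None = None


class StatsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    methods: list[str] = Field(default_factory=lambda: ["skillings_mack"])
    n_draws: int = 10000
    seed: int = 0
    sd_kind: str = "se"


class SelectionConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    p_cut: float = esel.P_DISCOVERY
    fc_cut_log2: float = esel.LOG2_FC_CUTOFF
    p_sig: float = esel.P_SIGNIFICANT


class PipelineConfig(BaseModel):
    """Full run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    paths: PathsConfig = Field(default_factory=PathsConfig)
    qc: eqc.QcThresholds = Field(default_factory=eqc.QcThresholds)
    normalization: NormalizationConfig = Field(
        default_factory=NormalizationConfig)
    stats: StatsConfig = Field(default_factory=StatsConfig)
    selection: SelectionConfig = Field(default_factory=SelectionConfig)
    simulate: SimulationConfig | None = None


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(data)


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.model_dump(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute every stage and return the run manifest (also written to
    ``out_dir/manifest.json``)."""
    t0 = time.time()
    out_dir = Path(config.paths.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config": config.model_dump(mode="json"),
        "config_hash": config_hash(config),
        "stages": {},
    }

    # --- input: simulate or read --------------------------------------
    if config.simulate is not None:
        wells, sheet, truth = simulate_experiment(config.simulate)
        truth.to_csv(out_dir / "truth_manifest.csv", index=False)
        eio.write_well_table(wells, out_dir / "wells.csv")
        eio.write_sample_sheet(sheet, out_dir / "sample_sheet.csv")
        manifest["stages"]["input"] = {
            "source": "simulation", "seed": config.simulate.seed,
            "n_wells": int(len(wells)), "n_samples": int(len(sheet))}
    else:
        if not config.paths.well_table or not config.paths.sample_sheet:
            raise ConfigError("need well_table and sample_sheet paths, or a "
                              "simulate block")
        wells = eio.read_well_table(config.paths.well_table)
        sheet = eio.read_sample_sheet(config.paths.sample_sheet)
        manifest["stages"]["input"] = {
            "source": "files", "well_table": config.paths.well_table,
            "n_wells": int(len(wells)), "n_samples": int(len(sheet))}

    # --- well QC -------------------------------------------------------
    qc_res = eqc.apply_well_qc(wells, config.qc)
    manifest["stages"]["well_qc"] = qc_res.counts
    matrix = eio.pivot_to_matrix(qc_res.wells, sheet)
    eio.write_matrix(matrix, out_dir / "cq_matrix.csv")

    # --- assay filters ---------------------------------------------------
    has_mc = (sheet["condition"] == "media_control").any()
    report = eqc.assay_filter_report(matrix, sheet, config.qc)
    report.to_csv(out_dir / "qc_report.csv")
    tested = sorted(report.index[report["reason"] == "retained"])
    counts = report["reason"].value_counts().to_dict()
    manifest["stages"]["assay_filters"] = {
        "assays_total": int(len(report)),
        "media_filter_skipped": bool(not has_mc),
        "excluded_media_only": int(counts.get("media_only", 0)),
        "excluded_mc_delta": int(counts.get("mc_delta", 0)),
        "excluded_expression_rate": int(counts.get("expression_rate", 0)),
        "assays_tested": int(len(tested)),
    }

    # --- normalization ---------------------------------------------------
    normalizers = select_normalizers(
        matrix, sheet, config.qc,
        override=config.normalization.override_normalizers)
    normalizers.trace.to_csv(out_dir / "normalizer_report.csv")
    treated = sheet.loc[sheet["condition"] != "media_control", "sample_id"]
    dcq = compute_delta_cq(matrix[list(treated)], normalizers,
                           mode=config.normalization.mode, sheet=sheet)
    eio.write_matrix(dcq, out_dir / "delta_cq.csv")
    manifest["stages"]["normalization"] = {
        "n_normalizers": len(normalizers.assays),
        "normalizers": normalizers.assays[:50],
        "mode": config.normalization.mode,
    }

    # --- differential expression ----------------------------------------
    effects = est.effects_table(
        dcq.loc[tested], sheet, methods=tuple(config.stats.methods),
        n_draws=config.stats.n_draws, seed=config.stats.seed,
        sd_kind=config.stats.sd_kind)
    manifest["stages"]["diffexp"] = {
        "assays_tested": int(len(effects)),
        "assays_estimable": int(np.isfinite(
            effects["ddcq_hat"].to_numpy(float)).sum()),
        "pairs_dropped_total": int(effects["n_pairs_dropped"].sum()),
    }

    # --- selection -------------------------------------------------------
    selection = esel.rank_and_select(
        effects, p_cut=config.selection.p_cut,
        fc_cut_log2=config.selection.fc_cut_log2,
        p_sig=config.selection.p_sig)
    eio.write_results(effects, selection, out_dir / "results.csv")
    selection.to_csv(out_dir / "selection.csv", index=False)
    volcano = esel.volcano_table(effects, p_cut=config.selection.p_cut,
                                 fc_cut_log2=config.selection.fc_cut_log2)
    volcano.to_csv(out_dir / "volcano.csv", index=False)
    manifest["stages"]["selection"] = {
        "selected_p02": int(selection["selected_p02"].sum()),
        "selected_fc15": int(selection["selected_fc15"].sum()),
        "significant_p05": int(selection["significant_p05"].sum()),
        "signature": esel.signature_assays(selection),
    }

    manifest["elapsed_s"] = round(time.time() - t0, 3)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    log.info("pipeline finished in %.2fs -> %s", manifest["elapsed_s"],
             out_dir)
    return manifest
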