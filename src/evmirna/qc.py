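"""Quality filters for TaqMan-array Cq data.

Three stages, applied in this order by the pipeline:

1. **Well-level QC** — a reaction is discarded (Cq set missing) when
   Cq > 34, CqConf < 0.8 or AmpScore < 1.  All rules are strict
   inequalities, so a well at exactly the threshold is retained.
2. **Expression-rate acceptance** — an assay enters differential testing
   only if it is detected in at least 80% of samples, by default in BOTH
   the vehicle-control and agonist groups (an either-group mode exists).
3. **Media-control exclusion** — assays that represent serum/background
   rather than cell-derived cargo are removed: assays detected only in the
   cell-free media control, and assays whose media-control mean Cq is not
   at least 3.3 cycles (10-fold) above the vehicle-control mean.
"""

from __future__ import annotations

import logging
from typing import Literal, NamedTuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .exceptions import ConfigError

log = logging.getLogger(__name__)


class QcThresholds(BaseModel):
    """Thresholds for all QC stages (defaults follow the study design)."""

    model_config = ConfigDict(extra="forbid")

    cq_max: float = Field(34.0, gt=0, description="max retained Cq (cycles)")
    cq_conf_min: float = 0.8
    amp_score_min: float = 1.0
    expr_rate: float = Field(0.8, gt=0, le=1)
    expr_rule: Literal["both_groups", "either_group"] = "both_groups"
    mc_delta_min: float = 3.3
    mc_presence_rate: float = Field(0.5, gt=0, le=1)
    #: require vehicle control to be LOWER (more abundant) than media control;
    #: False compares absolute difference instead.
    mc_delta_directional: bool = True


class WellQcResult(NamedTuple):
    wells: pd.DataFrame
    counts: dict[str, int]


def apply_well_qc(wells: pd.DataFrame,
                  thresholds: QcThresholds | None = None) -> WellQcResult:
    """Set Cq missing for wells failing any well-level rule.

    Idempotent; missing inputs pass through.  Returns the filtered table and
    per-rule rejection counts (a well can fail several rules; ``rejected`` is
    the union).
    """
    thr = thresholds or QcThresholds()
    out = wells.copy()
    present = out["cq"].notna()
    fail_cq = present & (out["cq"] > thr.cq_max)
    fail_conf = present & (out["cq_conf"] < thr.cq_conf_min)
    fail_amp = present & (out["amp_score"] < thr.amp_score_min)
    rejected = fail_cq | fail_conf | fail_amp
    out.loc[rejected, "cq"] = np.nan
    counts = {
        "wells_total": int(len(out)),
        "wells_missing_input": int((~present).sum()),
        "rejected_cq_max": int(fail_cq.sum()),
        "rejected_cq_conf": int(fail_conf.sum()),
        "rejected_amp_score": int(fail_amp.sum()),
        "rejected_total": int(rejected.sum()),
    }
    log.info("well QC: %s", counts)
    return WellQcResult(out, counts)


def _group_samples(sheet: pd.DataFrame, condition: str) -> list[str]:
    return list(sheet.loc[sheet["condition"] == condition, "sample_id"])


def detection_rate(matrix: pd.DataFrame, samples: list[str]) -> pd.Series:
    """Fraction of the given samples in which each assay has a Cq."""
    if not samples:
        return pd.Series(np.nan, index=matrix.index)
    return matrix[samples].notna().mean(axis=1)


def expression_rate_filter(matrix: pd.DataFrame, sheet: pd.DataFrame,
                           thresholds: QcThresholds | None = None
                           ) -> list[str]:
    """Assays detected at >= ``expr_rate`` in both (or either) treated group.

    Returns the sorted accepted assay list.  Raises :class:`ConfigError`
    when a group has no samples.
    """
    thr = thresholds or QcThresholds()
    veh = _group_samples(sheet, "vehicle_control")
    ago = _group_samples(sheet, "agonist")
    if not veh or not ago:
        raise ConfigError("expression-rate filter needs non-empty "
                          "vehicle_control and agonist groups")
    rate_v = detection_rate(matrix, veh)
    rate_a = detection_rate(matrix, ago)
    if thr.expr_rule == "both_groups":
        ok = (rate_v >= thr.expr_rate) & (rate_a >= thr.expr_rate)
    else:
        ok = (rate_v >= thr.expr_rate) | (rate_a >= thr.expr_rate)
    return sorted(matrix.index[ok])


def media_control_exclusion(matrix: pd.DataFrame, sheet: pd.DataFrame,
                            thresholds: QcThresholds | None = None
                            ) -> list[str]:
    """Remove serum-background assays using the cell-free media control.

    An assay is *present in MC* when detected in >= ``mc_presence_rate`` of
    media-control samples.  Excluded are (a) assays present in MC but
    detected in no vehicle/agonist sample ("media-only"), and (b) assays
    present in both MC and vehicle control whose MC mean Cq is not at least
    ``mc_delta_min`` cycles above the VC mean (i.e. less than 10-fold more
    abundant in cell-conditioned media).  Assays absent from MC are retained
    unconditionally.  With no media-control samples the filter is skipped
    with a warning.
    """
    thr = thresholds or QcThresholds()
    report = assay_filter_report(matrix, sheet, thr)
    return sorted(report.index[~report["reason"].isin(
        ["media_only", "mc_delta"])])


def assay_filter_report(matrix: pd.DataFrame, sheet: pd.DataFrame,
                        thresholds: QcThresholds | None = None
                        ) -> pd.DataFrame:
    """Per-assay detection rates and a single exclusion reason.

    Reasons partition the assay set with precedence
    ``media_only > mc_delta > expression_rate > retained`` so that stage
    counts in the run manifest are conservative (sum to the assay total).
    """
    thr = thresholds or QcThresholds()
    mc = _group_samples(sheet, "media_control")
    veh = _group_samples(sheet, "vehicle_control")
    ago = _group_samples(sheet, "agonist")

    rate_mc = detection_rate(matrix, mc)
    rate_v = detection_rate(matrix, veh)
    rate_a = detection_rate(matrix, ago)
    mean_mc = matrix[mc].mean(axis=1) if mc else pd.Series(np.nan,
                                                           index=matrix.index)
    mean_vc = matrix[veh].mean(axis=1) if veh else pd.Series(
        np.nan, index=matrix.index)
    delta = mean_mc - mean_vc

    reason = pd.Series("retained", index=matrix.index, name="reason")
    if mc:
        present_mc = rate_mc >= thr.mc_presence_rate
        n_treated = matrix[veh + ago].notna().sum(axis=1)
        media_only = present_mc & (n_treated == 0)
        detected_vc = rate_v > 0
        if thr.mc_delta_directional:
            far_enough = delta >= thr.mc_delta_min
        else:
            far_enough = delta.abs() >= thr.mc_delta_min
        mc_delta = present_mc & ~media_only & detected_vc & ~far_enough
        reason[media_only] = "media_only"
        reason[mc_delta] = "mc_delta"
    else:
        log.warning("no media_control samples: media-control exclusion "
                    "filter skipped")

    if veh and ago:
        accepted = set(expression_rate_filter(matrix, sheet, thr))
        fail_expr = ~matrix.index.isin(accepted)
        reason[fail_expr & (reason == "retained")] = "expression_rate"

    return pd.DataFrame({
        "mc_detection_rate": rate_mc,
        "vc_detection_rate": rate_v,
        "agonist_detection_rate": rate_a,
        "mc_mean_cq": mean_mc,
        "vc_mean_cq": mean_vc,
        "mc_vc_delta": delta,
        "reason": reason,
    })


def tested_assays(matrix: pd.DataFrame, sheet: pd.DataFrame,
                  thresholds: QcThresholds | None = None) -> list[str]:
    """Assays surviving both the media-control and expression-rate filters."""
    report = assay_filter_report(matrix, sheet, thresholds)
    return sorted(report.index[report["reason"] == "retained"])
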