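"""Endogenous-background normalization for array qPCR.

No universal reference miRNA exists for extracellular-vesicle cargo, so the
normalizer is the mean Cq of a data-driven set of endogenous assays, pooled
across both array cards.  An assay qualifies as a normalizer when

1. it is undetected, or detected in fewer than 50% of the cell-free media
   control samples (so it is cell-derived, not serum background);
2. it is detected in 100% of vehicle-control and agonist samples (so every
   sample gets the same normalizer panel, and the mean is never computed
   over a shifting subset); and
3. if it is detected in some but <50% of media controls, its media-control
   mean Cq differs from the vehicle-control mean by more than 3.3 cycles
   (>10-fold), confirming the detections are background-level carry-over.

dCq(assay, sample) = Cq(assay, sample) - mean normalizer Cq of that sample;
ddCq = dCq(agonist) - dCq(vehicle); fold change = 2^-ddCq.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError, ConsistencyError, NoNormalizersError
from .qc import QcThresholds, _group_samples, detection_rate


@dataclass
class NormalizerSet:
    """Selected normalizer assays plus the per-sample normalizer mean.

    ``trace`` records, per candidate assay, its detection rates, the
    media-vs-vehicle Cq difference, and which criterion (if any) failed —
    every assay carries exactly one status.
    """

    assays: list[str]
    per_sample_mean: pd.Series
    trace: pd.DataFrame

    def __post_init__(self) -> None:
        self.assays = list(self.assays)


def select_normalizers(matrix: pd.DataFrame, sheet: pd.DataFrame,
                       thresholds: QcThresholds | None = None,
                       override: Sequence[str] | None = None) -> NormalizerSet:
    """Apply the three endogenous-normalizer criteria to every assay.

    ``override`` bypasses the criteria with an explicit assay list (the
    documented escape hatch when nothing qualifies); the trace is still
    computed.  Raises :class:`NoNormalizersError` when no assay qualifies
    and no override is given.
    """
    thr = thresholds or QcThresholds()
    mc = _group_samples(sheet, "media_control")
    treated = (_group_samples(sheet, "vehicle_control")
               + _group_samples(sheet, "agonist"))
    if not treated:
        raise ConfigError("normalizer selection needs vehicle_control and "
                          "agonist samples")

    rate_mc = detection_rate(matrix, mc)
    rate_treated = detection_rate(matrix, treated)
    mean_mc = (matrix[mc].mean(axis=1) if mc
               else pd.Series(np.nan, index=matrix.index))
    veh = _group_samples(sheet, "vehicle_control")
    mean_vc = matrix[veh].mean(axis=1)
    delta = (mean_mc - mean_vc).abs()

    # criterion 1: undetected or <50% detected in media control
    # (vacuously satisfied when the design has no media controls)
    c1 = rate_mc.fillna(0.0) < thr.mc_presence_rate
    # criterion 2: fully observed in every vehicle/agonist sample
    c2 = rate_treated == 1.0
    # criterion 3: sporadic MC detections must sit >3.3 cycles away from VC
    sporadic = (rate_mc.fillna(0.0) > 0) & c1
    c3 = ~sporadic | (delta > thr.mc_delta_min)

    status = pd.Series("qualified", index=matrix.index)
    status[~c3] = "fails_mc_delta"
    status[~c2] = "fails_full_observation"
    status[~c1] = "fails_mc_presence"

    trace = pd.DataFrame({
        "mc_detection_rate": rate_mc,
        "vcag_detection_rate": rate_treated,
        "mc_vc_delta": mean_mc - mean_vc,
        "qualified": status == "qualified",
        "status": status,
    })

    if override is not None:
        missing = set(override) - set(matrix.index)
        if missing:
            raise ConsistencyError(
                f"override normalizer(s) not in matrix: {sorted(missing)}")
        assays = sorted(override)
    else:
        assays = sorted(trace.index[trace["qualified"]])
        if not assays:
            raise NoNormalizersError(
                "no assay satisfied the normalizer criteria; supply an "
                "explicit override list to proceed")

    per_sample_mean = matrix.loc[assays].mean(axis=0)
    return NormalizerSet(assays, per_sample_mean, trace)


def compute_delta_cq(matrix: pd.DataFrame, normalizers: NormalizerSet,
                     mode: Literal["per_sample", "per_group"] = "per_sample",
                     sheet: pd.DataFrame | None = None) -> pd.DataFrame:
    """Subtract the normalizer mean from every Cq; missingness propagates.

    ``per_sample`` (default) subtracts each sample's own normalizer mean,
    so sample-level loading shifts cancel exactly.  ``per_group`` subtracts
    the mean of the normalizer means within a condition group (a sensitivity
    mode; requires ``sheet``).  Raises :class:`ConsistencyError` for samples
    lacking a finite normalizer mean.
    """
    means = normalizers.per_sample_mean.reindex(matrix.columns)
    if mode == "per_group":
        if sheet is None:
            raise ConfigError("per_group normalization requires the sample "
                              "sheet")
        cond = sheet.set_index("sample_id")["condition"].reindex(matrix.columns)
        group_means = means.groupby(cond).transform("mean")
        means = group_means
    lacking = sorted(matrix.columns[~np.isfinite(means.to_numpy(float))])
    if lacking:
        raise ConsistencyError(
            f"sample(s) lack a finite normalizer mean: {lacking}")
    return matrix.sub(means, axis=1)


def fold_change(ddcq):
    """Relative quantification 2^-ddCq (log2 fold change = -ddCq)."""
    return 2.0 ** (-np.asarray(ddcq, dtype=float)) if np.ndim(ddcq) else \
        float(2.0 ** (-float(ddcq)))
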