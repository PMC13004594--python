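"""Seeded synthetic TaqMan-array experiments with ground truth.

The generator emulates the statistical structure the analysis assumes: ~754
assays split over two cards, matched vehicle/agonist pairs plus media-control
replicates, assay-specific baseline Cq levels, a media-only assay subset
(serum background detectable only in cell-free media), a cell-derived subset
strongly enriched over media control, planted treatment effects, pair- and
card-level additive offsets, detection-limit censoring with logistic dropout,
and random AmpScore/CqConf failures that the QC module — not the simulator —
must remove.

Underlying Cq:  mu = baseline(assay) + card_offset*[card B]
                     + pair_offset(pair) + planted_ddcq*[agonist]
                     + media shift (class-dependent, media controls only)
    observed Cq = mu + residual, missing when above ``cq_censor`` or via a
    logistic dropout in the underlying Cq.

One shared RNG stream is consumed in a fixed, documented order (baselines,
class assignment, background media shifts, pair offsets, residual matrix,
dropout draws, QC-failure draws, quality metrics), so a fixed seed gives
bit-identical output.
"""

from __future__ import annotations

import warnings
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.special import expit

from .exceptions import ConfigError, ConsistencyError


class SimulationConfig(BaseModel):
    """Design and noise parameters of one synthetic experiment.

    Defaults mirror the study design: 754 assays over an A+B card pair,
    6 matched vehicle/agonist pairs, 6 media-control replicates, a Cq
    detection ceiling of 34 cycles.
    """

    model_config = ConfigDict(extra="forbid")

    n_assays: int = Field(754, ge=1)
    card_split: float = Field(0.5, ge=0, le=1)
    n_pairs: int = Field(6, ge=2)
    n_media: int = Field(6, ge=0)
    baseline_cq_mean: float = 28.0
    baseline_cq_sd: float = Field(3.0, ge=0)
    frac_media_only: float = Field(0.05, ge=0, le=1)
    frac_cell_derived: float = Field(0.55, ge=0, le=1)
    #: explicit planted effects: assay name -> ddCq (cycles)
    effect_assays: dict[str, float] = Field(default_factory=dict)
    #: alternative placement: plant ``effect_sizes`` on the cell-derived
    #: assays with baselines nearest the overall median baseline
    effect_sizes: list[float] = Field(default_factory=list)
    effect_placement: Literal["named", "median_baseline"] = "named"
    pair_sd: float = Field(0.5, ge=0)
    card_offset: float = 0.5
    resid_sd: float = Field(0.3, ge=0)
    cq_censor: float = 34.0
    #: slope of the logistic extra-dropout curve in the underlying Cq,
    #: centred at ``cq_censor``; 0 disables the mechanism
    dropout_slope: float = Field(1.0, ge=0)
    qc_fail_rate: float = Field(0.02, ge=0, le=1)
    #: media-control Cq shift of cell-derived assays (cycles; pushes most
    #: above the detection ceiling)
    mc_shift_cell: float = 6.0
    #: SD of the media-control shift of background assays
    mc_shift_background_sd: float = 1.0
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        if self.frac_media_only + self.frac_cell_derived > 1:
            raise ValueError("frac_media_only + frac_cell_derived must be <= 1")
        if self.effect_placement == "median_baseline" and self.effect_assays:
            raise ValueError("use either effect_assays (named) or "
                             "effect_sizes (median_baseline), not both")
        return self


def assay_names(n: int) -> list[str]:
    return [f"sim-miR-{i:04d}" for i in range(n)]


def _build_sheet(cfg: SimulationConfig) -> pd.DataFrame:
    rows = []
    for i in range(cfg.n_media):
        rows.append(("MC%02d" % (i + 1), "other", "media_control",
                     pd.NA, pd.NA))
    for i in range(cfg.n_pairs):
        pid = "P%02d" % (i + 1)
        rows.append(("VEH%02d" % (i + 1), "other", "vehicle_control",
                     pid, pd.NA))
        rows.append(("AGO%02d" % (i + 1), "other", "agonist", pid, pd.NA))
    return pd.DataFrame(rows, columns=["sample_id", "receptor", "condition",
                                       "pair_id", "run_batch"])


def simulate_experiment(cfg: SimulationConfig
                        ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate one experiment: (well table, sample sheet, truth manifest).

    The truth manifest holds, per assay, the planted ddCq (0 for nulls),
    the media-only and cell-derived class flags, and an expected
    normalizer-eligibility flag computed from the noise-free underlying Cq
    (the three normalizer criteria applied to mu with censoring only).
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_assays
    names = assay_names(n)
    sheet = _build_sheet(cfg)
    samples = list(sheet["sample_id"])
    cond = sheet.set_index("sample_id")["condition"]
    n_s = len(samples)

    # 1. assay baselines
    baseline = cfg.baseline_cq_mean + cfg.baseline_cq_sd * rng.standard_normal(n)
    # 2. class assignment
    n_mo = round(cfg.frac_media_only * n)
    n_cd = round(cfg.frac_cell_derived * n)
    perm = rng.permutation(n)
    media_only = np.zeros(n, bool)
    cell_derived = np.zeros(n, bool)
    media_only[perm[:n_mo]] = True
    cell_derived[perm[n_mo:n_mo + n_cd]] = True

    # planted effects
    planted = np.zeros(n)
    if cfg.effect_placement == "named":
        unknown = set(cfg.effect_assays) - set(names)
        if unknown:
            raise ConfigError(f"effect_assays reference unknown assay(s): "
                              f"{sorted(unknown)}")
        for name, e in cfg.effect_assays.items():
            i = names.index(name)
            planted[i] = e
            if media_only[i]:        # effects must act on detectable cargo
                media_only[i] = False
                cell_derived[i] = True
            elif not cell_derived[i]:
                cell_derived[i] = True
    else:
        cd_idx = np.flatnonzero(cell_derived)
        if len(cfg.effect_sizes) > cd_idx.size:
            raise ConfigError("more effect_sizes than cell-derived assays")
        med = np.median(baseline)
        chosen = cd_idx[np.argsort(np.abs(baseline[cd_idx] - med),
                                   kind="stable")[:len(cfg.effect_sizes)]]
        chosen = np.sort(chosen)
        planted[chosen] = cfg.effect_sizes

    # 3. background media shifts (drawn for all assays, used where relevant)
    bg_shift = cfg.mc_shift_background_sd * rng.standard_normal(n)
    # 4. pair offsets
    pair_offset = cfg.pair_sd * rng.standard_normal(cfg.n_pairs)
    # 5-7. well-level noise
    resid = cfg.resid_sd * rng.standard_normal((n, n_s))
    drop_u = rng.random((n, n_s))
    qc_u = rng.random((n, n_s))
    qc_which = rng.random((n, n_s))
    amp_pass = rng.uniform(1.0, 2.0, (n, n_s))
    conf_pass = rng.uniform(0.85, 1.0, (n, n_s))
    amp_fail = rng.uniform(0.1, 0.9, (n, n_s))
    conf_fail = rng.uniform(0.1, 0.79, (n, n_s))

    n_card_a = round(cfg.card_split * n)
    card = np.where(np.arange(n) < n_card_a, "A", "B")
    card_add = np.where(card == "B", cfg.card_offset, 0.0)

    pair_of = sheet.set_index("sample_id")["pair_id"]
    pair_index = {f"P{i+1:02d}": i for i in range(cfg.n_pairs)}

    mu = np.empty((n, n_s))
    for j, s in enumerate(samples):
        col = baseline + card_add
        if cond[s] == "media_control":
            shift = np.where(media_only, 0.0,
                             np.where(cell_derived, cfg.mc_shift_cell,
                                      bg_shift))
            col = col + shift
        else:
            col = col + pair_offset[pair_index[pair_of[s]]]
            col = col + np.where(media_only, np.inf, 0.0)
            if cond[s] == "agonist":
                col = col + planted
        mu[:, j] = col

    cq = mu + resid
    missing = cq > cfg.cq_censor
    if cfg.dropout_slope > 0:
        p_drop = expit(cfg.dropout_slope * (cq - cfg.cq_censor))
        missing |= drop_u < p_drop
    missing |= ~np.isfinite(cq)

    qc_fail = qc_u < cfg.qc_fail_rate
    amp = np.where(qc_fail & (qc_which < 0.5), amp_fail, amp_pass)
    conf = np.where(qc_fail & (qc_which >= 0.5), conf_fail, conf_pass)
    amp = np.where(missing, 0.0, amp)
    conf = np.where(missing, 0.0, conf)
    cq_obs = np.where(missing, np.nan, cq)

    wells = pd.DataFrame({
        "sample_id": np.tile(samples, n),
        "assay_id": np.repeat(names, n_s),
        "card": np.repeat(card, n_s),
        "cq": cq_obs.ravel(),
        "amp_score": np.round(amp.ravel(), 4),
        "cq_conf": np.round(conf.ravel(), 4),
    })

    truth = _truth_manifest(cfg, names, mu, sheet, planted, media_only,
                            cell_derived)
    return wells, sheet, truth


def _truth_manifest(cfg: SimulationConfig, names: list[str], mu: np.ndarray,
                    sheet: pd.DataFrame, planted: np.ndarray,
                    media_only: np.ndarray, cell_derived: np.ndarray
                    ) -> pd.DataFrame:
    cond = sheet["condition"].to_numpy()
    mc_cols = cond == "media_control"
    vc_cols = cond == "vehicle_control"
    treated = (cond == "vehicle_control") | (cond == "agonist")
    det = mu <= cfg.cq_censor
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-censored rows
        rate_mc = (det[:, mc_cols].mean(axis=1) if mc_cols.any()
                   else np.zeros(len(names)))
        rate_tr = det[:, treated].mean(axis=1)
        mc_mean = np.where(det[:, mc_cols], mu[:, mc_cols], np.nan)
        vc_mean = np.where(det[:, vc_cols], mu[:, vc_cols], np.nan)
        mc_mean = np.nanmean(np.where(mc_mean == np.inf, np.nan, mc_mean),
                             axis=1) if mc_cols.any() else np.full(len(names),
                                                                   np.nan)
        vc_mean = np.nanmean(vc_mean, axis=1)
    c1 = rate_mc < 0.5
    c2 = rate_tr == 1.0
    sporadic = (rate_mc > 0) & c1
    delta = np.abs(mc_mean - vc_mean)
    c3 = ~sporadic | (delta > 3.3)
    eligible = c1 & c2 & c3
    return pd.DataFrame({
        "assay_id": names,
        "planted_ddcq": planted,
        "media_only": media_only,
        "cell_derived": cell_derived,
        "normalizer_eligible": eligible,
    })


def simulate_null_paired(n_assays: int, n_pairs: int = 6,
                         one_sided_missing_rate: float = 0.3,
                         seed: int | np.random.Generator | None = None
                         ) -> np.ndarray:
    """Pure-null paired dCq draws for test calibration.

    Returns an (n_assays, n_pairs, 2) array of standard-normal
    vehicle/agonist values where, independently per pair, one randomly
    chosen side is set missing with probability
    ``one_sided_missing_rate`` — the missingness regime under which the
    incomplete-block test must stay close to its nominal level.
    """
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_assays, n_pairs, 2))
    drop = rng.random((n_assays, n_pairs)) < one_sided_missing_rate
    side = rng.integers(0, 2, (n_assays, n_pairs))
    i, j = np.nonzero(drop)
    x[i, j, side[i, j]] = np.nan
    return x


def evaluate_recovery(selected: list[str] | pd.Series,
                      truth: pd.DataFrame,
                      candidates: list[str] | None = None) -> dict[str, float]:
    """Confusion-matrix metrics of a selection against planted effects.

    Positives are assays with planted ddCq != 0.  ``candidates`` restricts
    the universe (e.g. to assays that survived filtering); default is every
    assay in the truth manifest.  Raises :class:`ConsistencyError` when the
    selection contains assays outside the universe.
    """
    universe = list(truth["assay_id"]) if candidates is None else list(candidates)
    uni = set(universe)
    sel = set(selected)
    if not sel <= uni:
        raise ConsistencyError(
            f"selected assay(s) outside the candidate set: "
            f"{sorted(sel - uni)[:10]}")
    truth_map = truth.set_index("assay_id")["planted_ddcq"]
    missing = uni - set(truth_map.index)
    if missing:
        raise ConsistencyError(
            f"candidate assay(s) absent from truth: {sorted(missing)[:10]}")
    pos = {a for a in universe if truth_map[a] != 0}
    neg = uni - pos
    tp = len(sel & pos)
    fp = len(sel & neg)
    fn = len(pos - sel)
    tn = len(neg - sel)
    return {
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        "sensitivity": tp / len(pos) if pos else np.nan,
        "specificity": tn / len(neg) if neg else np.nan,
        "fdp": fp / len(sel) if sel else 0.0,
    }
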