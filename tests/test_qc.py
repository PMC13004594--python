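"""Well-level QC rules, expression-rate acceptance, media-control exclusion."""

import numpy as np
import pandas as pd
import pytest

from evmirna import (ConfigError, QcThresholds, SimulationConfig,
                     apply_well_qc, expression_rate_filter,
                     media_control_exclusion, pivot_to_matrix,
                     simulate_experiment)


def _well(cq, conf=0.95, amp=1.5):
    return pd.DataFrame({"sample_id": ["S1"], "assay_id": ["m1"],
                         "card": ["A"], "cq": [cq], "amp_score": [amp],
                         "cq_conf": [conf]})


def _sheet(n_mc=2, n_pairs=0, n_veh=0, n_ago=0):
    """Sheet with either paired (n_pairs) or unpaired-looking groups."""
    rows = [(f"MC{i}", "other", "media_control", None) for i in range(n_mc)]
    for i in range(max(n_pairs, n_veh, n_ago)):
        if i < (n_pairs or n_veh):
            rows.append((f"V{i}", "other", "vehicle_control", f"P{i}"))
        if i < (n_pairs or n_ago):
            rows.append((f"A{i}", "other", "agonist", f"P{i}"))
    return pd.DataFrame(rows, columns=["sample_id", "receptor", "condition",
                                       "pair_id"])


class TestWellQc:
    @pytest.mark.parametrize("cq,conf,amp,kept", [
        (35.0, 0.95, 1.2, False),   # Cq above the 34-cycle ceiling
        (34.0, 0.95, 1.2, True),    # boundary: rule is strictly >34
        (28.0, 0.80, 1.0, True),    # boundaries: rules strictly <0.8, <1
        (28.0, 0.79, 1.2, False),
        (28.0, 0.95, 0.99, False),
    ])
    def test_rule_boundaries(self, cq, conf, amp, kept):
        out = apply_well_qc(_well(cq, conf, amp)).wells
        assert out.loc[0, "cq"] == cq if kept else np.isnan(out.loc[0, "cq"])

    def test_missing_input_passes_through(self):
        res = apply_well_qc(_well(np.nan, 0.0, 0.0))
        assert np.isnan(res.wells.loc[0, "cq"])
        assert res.counts["rejected_total"] == 0
        assert res.counts["wells_missing_input"] == 1

    def test_idempotent(self, toy_wells):
        once = apply_well_qc(toy_wells).wells
        twice = apply_well_qc(once).wells
        pd.testing.assert_frame_equal(once, twice)

    def test_per_rule_counts(self, toy_wells):
        counts = apply_well_qc(toy_wells).counts
        assert counts["rejected_cq_max"] == 1
        assert counts["rejected_amp_score"] == 1
        assert counts["rejected_cq_conf"] == 0
        assert counts["rejected_total"] == 2


def _detection_matrix(det, sheet, cq=28.0):
    """Matrix from a detection-pattern dict assay -> {sample: cq or None}."""
    m = pd.DataFrame(np.nan, index=sorted(det),
                     columns=list(sheet["sample_id"]))
    for assay, cells in det.items():
        for s, v in cells.items():
            m.loc[assay, s] = v
    return m


class TestExpressionRate:
    def setup_method(self):
        self.sheet = _sheet(n_mc=0, n_pairs=6)
        self.veh = [f"V{i}" for i in range(6)]
        self.ago = [f"A{i}" for i in range(6)]

    def _matrix(self, n_veh_det, n_ago_det):
        cells = {s: 28.0 for s in self.veh[:n_veh_det]}
        cells.update({s: 28.0 for s in self.ago[:n_ago_det]})
        return _detection_matrix({"m1": cells}, self.sheet)

    def test_five_of_six_accepted_both_groups(self):
        m = self._matrix(6, 5)       # 0.833 >= 0.8 in both
        assert expression_rate_filter(m, self.sheet) == ["m1"]

    def test_four_of_six_rejected_both_accepted_either(self):
        m = self._matrix(6, 4)       # agonist 0.667 < 0.8
        assert expression_rate_filter(m, self.sheet) == []
        thr = QcThresholds(expr_rule="either_group")
        assert expression_rate_filter(m, self.sheet, thr) == ["m1"]

    def test_fully_detected_identity(self):
        m = self._matrix(6, 6)
        assert expression_rate_filter(m, self.sheet) == ["m1"]

    def test_empty_group_raises(self):
        sheet = self.sheet[self.sheet.condition != "agonist"]
        with pytest.raises(ConfigError):
            expression_rate_filter(self._matrix(6, 6), sheet)

    def test_tightening_rate_shrinks_set(self):
        rng = np.random.default_rng(7)
        sheet = self.sheet
        m = pd.DataFrame(
            np.where(rng.random((40, len(sheet))) < 0.85, 28.0, np.nan),
            index=[f"a{i:02d}" for i in range(40)],
            columns=list(sheet["sample_id"]))
        prev = None
        for rate in (0.5, 0.8, 0.9, 1.0):
            acc = set(expression_rate_filter(
                m, sheet, QcThresholds(expr_rate=rate)))
            if prev is not None:
                assert acc <= prev
            prev = acc


class TestMediaControlExclusion:
    def setup_method(self):
        self.sheet = _sheet(n_mc=6, n_pairs=6)
        self.mc = [f"MC{i}" for i in range(6)]
        self.veh = [f"V{i}" for i in range(6)]
        self.ago = [f"A{i}" for i in range(6)]

    def _matrix(self, mc_cq=None, vc_cq=None, ago_cq=None):
        cells = {}
        if mc_cq is not None:
            cells.update({s: mc_cq for s in self.mc})
        if vc_cq is not None:
            cells.update({s: vc_cq for s in self.veh})
        if ago_cq is not None:
            cells.update({s: ago_cq for s in self.ago})
        return _detection_matrix({"m1": cells}, self.sheet)

    def test_ten_fold_enriched_retained(self):
        m = self._matrix(mc_cq=30.0, vc_cq=26.0, ago_cq=26.0)   # diff 4.0
        assert media_control_exclusion(m, self.sheet) == ["m1"]

    def test_less_than_ten_fold_excluded(self):
        m = self._matrix(mc_cq=27.0, vc_cq=26.0, ago_cq=26.0)   # diff 1.0
        assert media_control_exclusion(m, self.sheet) == []

    def test_media_only_excluded(self):
        m = self._matrix(mc_cq=28.0)
        assert media_control_exclusion(m, self.sheet) == []

    def test_absent_from_mc_retained_unconditionally(self):
        m = self._matrix(vc_cq=26.0, ago_cq=26.0)
        assert media_control_exclusion(m, self.sheet) == ["m1"]

    def test_no_media_controls_skips_filter(self):
        sheet = _sheet(n_mc=0, n_pairs=6)
        m = _detection_matrix({"m1": {f"V{i}": 26.0 for i in range(6)}},
                              sheet)
        assert media_control_exclusion(m, sheet) == ["m1"]

    def test_noise_free_simulation_recovers_media_only_truth(self):
        cfg = SimulationConfig(
            n_assays=60, frac_media_only=0.2, frac_cell_derived=0.8,
            baseline_cq_sd=1.0, pair_sd=0.0, resid_sd=0.0,
            dropout_slope=0.0, qc_fail_rate=0.0, seed=11)
        wells, sheet, truth = simulate_experiment(cfg)
        matrix = pivot_to_matrix(wells, sheet)
        retained = set(media_control_exclusion(matrix, sheet))
        media_only = set(truth.loc[truth.media_only, "assay_id"])
        assert retained == set(truth["assay_id"]) - media_only
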