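"""Matched-pairs estimator, Skillings-Mack test, alternative tests.

Independent oracles: a pair-fixed-effects least-squares regression (numpy),
scipy's Friedman statistic on complete designs, closed-form chi-square
tails, and exact sign-flip enumeration for two-treatment designs.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from evmirna import (DisconnectedDesignError, alternative_tests,
                     matched_pairs_effect, paired_design, sign_flip_p,
                     skillings_mack, skillings_mack_mc)
from evmirna.stats import effects_table, sensitivity_grid


def _regression_oracle(vehicle, agonist):
    """Treatment coefficient of y ~ pair fixed effects + treatment."""
    v, a = np.asarray(vehicle), np.asarray(agonist)
    ok = np.isfinite(v) & np.isfinite(a)
    v, a = v[ok], a[ok]
    n = v.size
    y = np.concatenate([v, a])
    pair = np.tile(np.eye(n), (2, 1))
    treat = np.concatenate([np.zeros(n), np.ones(n)])[:, None]
    X = np.hstack([pair, treat])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta[-1]


class TestMatchedPairs:
    def test_constant_case(self):
        v = pd.Series(np.arange(6, dtype=float))
        eff = matched_pairs_effect(v, v - 1.0)
        assert eff.ddcq_hat == -1.0 and eff.log2_fc == 1.0
        assert eff.n_pairs_used == 6

    def test_incomplete_pair_dropped(self):
        v = pd.Series([1.0, 1.0, 1.0, 1.0])
        a = pd.Series([0.0, 0.5, -0.5, np.nan])
        eff = matched_pairs_effect(v, a)
        assert eff.ddcq_hat == pytest.approx(-1.0)
        assert eff.n_pairs_used == 3 and eff.n_pairs_dropped == 1

    def test_fewer_than_two_pairs_not_estimable(self):
        eff = matched_pairs_effect(pd.Series([1.0, np.nan]),
                                   pd.Series([0.0, 2.0]))
        assert np.isnan(eff.ddcq_hat) and eff.n_pairs_used == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_pair_fixed_effects_regression(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(0, 1, 6)
        a = v + rng.normal(-0.8, 0.5, 6)
        if seed % 2:
            a[rng.integers(0, 6)] = np.nan
        eff = matched_pairs_effect(v, a)
        assert eff.ddcq_hat == pytest.approx(_regression_oracle(v, a))


class TestSkillingsMack:
    def test_six_concordant_blocks_closed_form(self):
        d = paired_design(np.arange(6) + 1.0, np.arange(6) + 0.5)
        res = skillings_mack(d)
        assert res.statistic == pytest.approx(6.0)
        assert res.df == 1
        assert res.p_value == pytest.approx(sps.chi2.sf(6.0, 1), abs=1e-12)
        assert round(res.p_value, 4) == 0.0143

    def test_five_concordant_blocks_closed_form(self):
        d = paired_design(np.arange(5) + 1.0, np.arange(5) + 0.5)
        res = skillings_mack(d)
        assert res.statistic == pytest.approx(5.0)
        assert round(res.p_value, 4) == 0.0253

    def test_balanced_directions_give_zero(self):
        v = np.ones(6)
        a = np.array([0.5, 0.5, 0.5, 1.5, 1.5, 1.5])
        res = skillings_mack(paired_design(v, a))
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("n", range(2, 9))
    def test_two_treatment_equals_direction_count_formula(self, n):
        rng = np.random.default_rng(n)
        for _ in range(10):
            v, a = rng.normal(size=(2, n))
            s = np.sign(a - v).sum()
            res = skillings_mack(paired_design(v, a))
            assert res.statistic == pytest.approx(s * s / n)

    @pytest.mark.parametrize("t,seed", [(3, 0), (4, 1), (5, 2)])
    def test_complete_design_equals_friedman(self, t, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(8, t))
        res = skillings_mack(x)
        stat, p = sps.friedmanchisquare(*x.T)
        assert res.statistic == pytest.approx(stat)
        assert res.df == t - 1
        assert res.p_value == pytest.approx(p)

    def test_incomplete_blocks_dropped(self):
        v = np.array([1.0, 1, 1, 1, 1, np.nan])
        a = np.array([0.0, 0, 0, 0, 0, 0.5])
        res = skillings_mack(paired_design(v, a))
        assert res.n_blocks_used == 5
        assert res.statistic == pytest.approx(5.0)

    def test_no_usable_blocks_gives_missing_p(self):
        v = np.array([1.0, np.nan])
        a = np.array([np.nan, 1.0])
        res = skillings_mack(paired_design(v, a))
        assert np.isnan(res.p_value) and res.n_blocks_used == 0

    def test_disconnected_design_raises(self):
        x = np.array([[1.0, 2.0, np.nan, np.nan],
                      [2.0, 1.0, np.nan, np.nan],
                      [np.nan, np.nan, 1.0, 2.0],
                      [np.nan, np.nan, 2.0, 1.0]])
        with pytest.raises(DisconnectedDesignError, match=r"\[0, 1\]"):
            skillings_mack(x)

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(6, 3))
        x[rng.integers(0, 6), rng.integers(0, 3)] = np.nan
        base = skillings_mack(x).statistic
        trans = skillings_mack(np.exp(x) + x ** 3 / 3).statistic
        assert base == pytest.approx(trans)

    def test_statistic_nonnegative_and_p_monotone(self):
        rng = np.random.default_rng(0)
        stats, ps = [], []
        for _ in range(50):
            res = skillings_mack(rng.normal(size=(6, 2)))
            assert res.statistic >= 0
            stats.append(res.statistic)
            ps.append(res.p_value)
        order = np.argsort(stats)
        assert (np.diff(np.array(ps)[order]) <= 1e-12).all()


class TestSkillingsMackMC:
    def test_zero_statistic_gives_p_one(self):
        v = np.ones(6)
        a = np.array([0.5, 0.5, 0.5, 1.5, 1.5, 1.5])
        assert skillings_mack_mc(paired_design(v, a), 1000, seed=0) == 1.0

    def test_concordant_pairs_match_exact_signflip_null(self):
        d = paired_design(np.arange(6) + 1.0, np.arange(6) + 0.5)
        p = skillings_mack_mc(d, n_draws=20000, seed=5)
        # exact within-block permutation null: 2 * (1/2)^6
        assert p == pytest.approx(2 / 64, abs=0.006)

    def test_reproducible_for_fixed_seed(self):
        rng = np.random.default_rng(9)
        d = paired_design(rng.normal(size=6), rng.normal(size=6))
        assert skillings_mack_mc(d, 2000, seed=3) == \
            skillings_mack_mc(d, 2000, seed=3)


class TestAlternativeTests:
    def test_constant_zero_differences_null(self):
        v = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        p = alternative_tests(v, v, methods=("perm_signflip", "signed_rank"))
        assert p["perm_signflip"] == 1.0
        assert p["signed_rank"] == 1.0

    def test_six_concordant_pairs_exact_signflip(self):
        v = pd.Series(np.arange(6, dtype=float))
        p = alternative_tests(v, v - 1.0, methods=("perm_signflip",))
        assert p["perm_signflip"] == pytest.approx(2 / 64)

    def test_exact_enumeration_matches_brute_force(self):
        rng = np.random.default_rng(2)
        d = rng.normal(-0.5, 1, 7)
        obs = abs(d.mean())
        count = sum(abs(np.dot(s, d) / 7) >= obs - 1e-12
                    for s in itertools.product([1, -1], repeat=7))
        assert sign_flip_p(d) == pytest.approx(count / 2 ** 7)

    def test_insufficient_n_yields_nan_without_breaking_others(self):
        v = pd.Series([1.0, np.nan, np.nan])
        a = pd.Series([0.0, 2.0, 1.0])
        p = alternative_tests(v, a, n_draws=1000, seed=0)
        assert np.isnan(p["perm_signflip"])      # only one complete pair
        assert np.isfinite(p["mann_whitney"])

    def test_unknown_method_raises(self):
        with pytest.raises(ValueError, match="unknown test method"):
            alternative_tests(pd.Series([1.0, 2.0]), pd.Series([1.0, 2.0]),
                              methods=("bogus",))


class TestEffectsTable:
    def _dcq_and_sheet(self):
        rows = [(f"V{i}", "other", "vehicle_control", f"P{i}")
                for i in range(6)]
        rows += [(f"A{i}", "other", "agonist", f"P{i}") for i in range(6)]
        sheet = pd.DataFrame(rows, columns=["sample_id", "receptor",
                                            "condition", "pair_id"])
        rng = np.random.default_rng(4)
        veh = rng.normal(size=(3, 6))
        ago = veh + rng.normal(0, 0.2, size=(3, 6))   # paired: shared pair level
        dcq = pd.DataFrame(np.hstack([veh, ago]),
                           index=["m1", "m2", "m3"],
                           columns=[f"V{i}" for i in range(6)]
                           + [f"A{i}" for i in range(6)])
        dcq.loc["m1", [f"A{i}" for i in range(6)]] -= 1.0
        return dcq, sheet

    def test_columns_and_sign_convention(self):
        dcq, sheet = self._dcq_and_sheet()
        eff = effects_table(dcq, sheet)
        assert (eff["log2_fc"] == -eff["ddcq_hat"]).all()
        m1 = eff.set_index("assay_id").loc["m1"]
        assert m1["log2_fc"] > 0                 # down-shifted Cq = up-regulated
        assert m1["sd_log2_fc"] == pytest.approx(
            m1["sd_pairs"] / np.sqrt(m1["n_pairs"]))

    def test_sensitivity_grid_shape(self):
        dcq, sheet = self._dcq_and_sheet()
        grid = sensitivity_grid(dcq, sheet, n_draws=1000, seed=0)
        assert set(grid["estimator"]) == {"matched_pairs", "group_means"}
        assert len(grid) == 3 * 6                # assays x test methods
        sm = grid[(grid.assay_id == "m1") & (grid.test == "skillings_mack")]
        assert sm["p_value"].iloc[0] < 0.05
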