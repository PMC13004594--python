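"""Matched-pairs effect estimation and rank tests for incomplete blocks.

The treatment effect on each assay is the mean of per-pair dCq differences
(agonist minus vehicle), which equals the coefficient of a within-pairs
linear regression with pair fixed effects on complete pairs.  p-values come
primarily from the Skillings-Mack test, the generalization of the Friedman
rank test to incomplete block designs: blocks observing fewer than two
treatments carry no rank information and are dropped; within each remaining
block of size k_i the observations are ranked (midranks for ties) and the
treatment scores

    A_j = sum over blocks containing j of sqrt(12/(k_i+1)) * (r_ij - (k_i+1)/2)

are combined into T = A' S^- A, where S is the null covariance of A
(diagonal sum of k_i - 1, off-diagonal -1 per co-observing block) and S^-
a generalized inverse (S is singular because scores sum to zero).  T is
referred to a chi-square with df = rank(S); for connected designs df = t-1.
On complete two-treatment data T reduces to the Friedman statistic
(S_plus - S_minus)^2 / n_blocks.

A within-block permutation Monte-Carlo p and a panel of alternative tests
(sign-flip permutation, Wilcoxon signed-rank, Welch's t, Mann-Whitney,
unpaired permutation) support the sensitivity grid of estimator x test
combinations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import pinvh
from scipy.stats import rankdata

from .exceptions import DisconnectedDesignError

ALL_TEST_METHODS = ("skillings_mack", "perm_signflip", "signed_rank",
                    "welch_t", "mann_whitney", "unpaired_perm")

_EPS = 1e-12


# ---------------------------------------------------------------------------
# matched-pairs estimator

@dataclass
class PairedEffect:
    """Matched-pairs ddCq estimate for one assay."""

    ddcq_hat: float
    sd_pairs: float      # SD of the per-pair ddCq values
    se: float            # sd_pairs / sqrt(n_pairs_used)
    n_pairs_used: int
    n_pairs_dropped: int
    per_pair: pd.Series = field(repr=False)

    @property
    def log2_fc(self) -> float:
        return -self.ddcq_hat


def matched_pairs_effect(vehicle: pd.Series | np.ndarray,
                         agonist: pd.Series | np.ndarray) -> PairedEffect:
    """Mean per-pair dCq difference (agonist - vehicle).

    Inputs are aligned by pair (same index/order); pairs with a missing side
    are dropped and counted.  With fewer than two complete pairs the effect
    is reported as NaN rather than raising.
    """
    v = pd.Series(vehicle, dtype=float)
    a = pd.Series(agonist, dtype=float)
    a = a.reindex(v.index) if isinstance(agonist, pd.Series) else a
    diff = a.to_numpy(float) - v.to_numpy(float)
    idx = v.index
    complete = np.isfinite(diff)
    per_pair = pd.Series(diff[complete], index=idx[complete], name="ddcq")
    n = int(complete.sum())
    dropped = int(len(diff) - n)
    if n < 2:
        return PairedEffect(np.nan, np.nan, np.nan, n, dropped, per_pair)
    sd = float(np.std(per_pair, ddof=1))
    return PairedEffect(float(per_pair.mean()), sd, sd / np.sqrt(n), n,
                        dropped, per_pair)


# ---------------------------------------------------------------------------
# Skillings-Mack

@dataclass
class SMResult:
    statistic: float
    df: int
    p_value: float
    n_blocks_used: int


def _sm_scores(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Treatment scores A and their null covariance from a blocks x t array."""
    obs = np.isfinite(values)
    k = obs.sum(axis=1)
    usable = k >= 2
    values, obs, k = values[usable], obs[usable], k[usable]
    t = values.shape[1]
    A = np.zeros(t)
    cov = np.zeros((t, t))
    for row, o, ki in zip(values, obs, k):
        r = rankdata(row[o])          # midranks for ties
        c = np.sqrt(12.0 / (ki + 1)) * (r - (ki + 1) / 2.0)
        idx = np.flatnonzero(o)
        A[idx] += c
        cov[np.ix_(idx, idx)] -= 1.0
        cov[idx, idx] += ki
    return A, cov, int(usable.sum())


def _check_connected(values: np.ndarray) -> None:
    obs = np.isfinite(values)
    obs = obs[obs.sum(axis=1) >= 2]
    t = values.shape[1]
    seen = [j for j in range(t) if obs[:, j].any()] if len(obs) else []
    if not seen:
        return
    parent = list(range(t))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for row in obs:
        idx = np.flatnonzero(row)
        for j in idx[1:]:
            parent[find(j)] = find(idx[0])
    comps: dict[int, list[int]] = {}
    for j in seen:
        comps.setdefault(find(j), []).append(j)
    if len(comps) > 1:
        raise DisconnectedDesignError(
            "design is disconnected; treatment components: "
            + ", ".join(str(sorted(c)) for c in comps.values()))


def skillings_mack(values: np.ndarray | pd.DataFrame) -> SMResult:
    """Skillings-Mack chi-square test on a blocks x treatments array.

    Unobserved cells are NaN.  Blocks observing <2 treatments are dropped;
    with no usable block the p-value is reported missing.  Raises
    :class:`DisconnectedDesignError` when the observed design splits into
    treatment groups that never co-occur in a block.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] < 2:
        raise ValueError("need a 2-D blocks x treatments array with t >= 2")
    _check_connected(values)
    A, cov, n_used = _sm_scores(values)
    if n_used == 0:
        return SMResult(np.nan, 0, np.nan, 0)
    eigvals = np.linalg.eigvalsh(cov)
    scale = eigvals[-1] if eigvals[-1] > 0 else 1.0
    df = int((eigvals > 1e-8 * scale).sum())
    if df == 0:
        return SMResult(0.0, 0, np.nan, n_used)
    stat = float(A @ pinvh(cov) @ A)
    stat = max(stat, 0.0)
    return SMResult(stat, df, float(sps.chi2.sf(stat, df)), n_used)


def skillings_mack_mc(values: np.ndarray | pd.DataFrame, n_draws: int = 10000,
                      seed: int | np.random.Generator | None = None
                      ) -> float:
    """Monte-Carlo Skillings-Mack p by permuting treatments within blocks.

    Small-sample refinement of the chi-square approximation; uses the
    add-one correction p = (1 + #{T* >= T_obs}) / (1 + n_draws).
    """
    if n_draws < 1000:
        raise ValueError("n_draws must be >= 1000")
    values = np.asarray(values, dtype=float)
    _check_connected(values)
    obs_res = skillings_mack(values)
    if not np.isfinite(obs_res.statistic):
        return np.nan
    rng = np.random.default_rng(seed)
    obs_mask = np.isfinite(values)
    usable = obs_mask.sum(axis=1) >= 2
    work = values[usable].copy()
    mask = obs_mask[usable]
    hits = 0
    for _ in range(n_draws):
        perm = work.copy()
        for i in range(perm.shape[0]):
            idx = np.flatnonzero(mask[i])
            perm[i, idx] = perm[i, rng.permutation(idx)]
        A, cov, _ = _sm_scores(perm)
        stat = float(A @ pinvh(cov) @ A)
        if stat >= obs_res.statistic - _EPS:
            hits += 1
    return (1 + hits) / (1 + n_draws)


def paired_design(vehicle: np.ndarray | pd.Series,
                  agonist: np.ndarray | pd.Series) -> np.ndarray:
    """Stack aligned vehicle/agonist dCq into a blocks x 2 design array."""
    return np.column_stack([np.asarray(vehicle, float),
                            np.asarray(agonist, float)])


# ---------------------------------------------------------------------------
# alternative tests

def sign_flip_p(diffs: np.ndarray, n_draws: int = 10000,
                seed: int | np.random.Generator | None = None,
                exact_max: int = 12) -> float:
    """Two-sided sign-flip permutation p for paired differences.

    Exact enumeration of all 2^n sign patterns when n <= ``exact_max``
    (worst case 4096 evaluations); seeded Monte-Carlo with the add-one
    correction otherwise.  Statistic: |mean difference|.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[np.isfinite(d)]
    n = d.size
    if n < 1:
        return np.nan
    obs = abs(d.mean())
    if n <= exact_max:
        signs = np.array(list(itertools.product([1.0, -1.0], repeat=n)))
        stats = np.abs(signs @ d) / n
        return float((stats >= obs - _EPS).mean())
    rng = np.random.default_rng(seed)
    signs = rng.choice([1.0, -1.0], size=(n_draws, n))
    stats = np.abs(signs @ d) / n
    return float((1 + (stats >= obs - _EPS).sum()) / (1 + n_draws))


def unpaired_perm_p(x: np.ndarray, y: np.ndarray, n_draws: int = 10000,
                    seed: int | np.random.Generator | None = None) -> float:
    """Two-sided label-permutation p for a difference of group means."""
    x = np.asarray(x, float)[np.isfinite(x)]
    y = np.asarray(y, float)[np.isfinite(y)]
    if x.size < 2 or y.size < 2:
        return np.nan
    rng = np.random.default_rng(seed)
    res = sps.permutation_test(
        (x, y), lambda a, b, axis=-1: np.mean(a, axis=axis) - np.mean(b, axis=axis),
        permutation_type="independent", alternative="two-sided",
        n_resamples=n_draws, vectorized=True, rng=rng)
    return float(res.pvalue)


def alternative_tests(vehicle: pd.Series | np.ndarray,
                      agonist: pd.Series | np.ndarray,
                      methods: tuple[str, ...] = ALL_TEST_METHODS,
                      n_draws: int = 10000,
                      seed: int | np.random.Generator | None = None
                      ) -> dict[str, float]:
    """p-values for the requested methods on one assay's dCq data.

    ``vehicle`` and ``agonist`` are aligned by pair; unpaired tests use all
    observed values from each side.  A method with insufficient data yields
    NaN without affecting the others.
    """
    rng = np.random.default_rng(seed)
    v = np.asarray(vehicle, dtype=float)
    a = np.asarray(agonist, dtype=float)
    d = a - v
    d_complete = d[np.isfinite(d)]
    v_obs, a_obs = v[np.isfinite(v)], a[np.isfinite(a)]
    out: dict[str, float] = {}
    for m in methods:
        p = np.nan
        try:
            if m == "skillings_mack":
                if np.isfinite(d).sum() >= 2:
                    p = skillings_mack(paired_design(v, a)).p_value
            elif m == "perm_signflip":
                if d_complete.size >= 2:
                    p = sign_flip_p(d_complete, n_draws=n_draws, seed=rng)
            elif m == "signed_rank":
                if d_complete.size >= 2:
                    if np.allclose(d_complete, 0):
                        p = 1.0
                    else:
                        p = float(sps.wilcoxon(
                            d_complete, alternative="two-sided").pvalue)
            elif m == "welch_t":
                if v_obs.size >= 2 and a_obs.size >= 2:
                    p = float(sps.ttest_ind(a_obs, v_obs,
                                            equal_var=False).pvalue)
            elif m == "mann_whitney":
                if v_obs.size >= 1 and a_obs.size >= 1:
                    p = float(sps.mannwhitneyu(
                        a_obs, v_obs, alternative="two-sided").pvalue)
            elif m == "unpaired_perm":
                p = unpaired_perm_p(a_obs, v_obs, n_draws=n_draws, seed=rng)
            else:
                raise ValueError(f"unknown test method: {m}")
        except ValueError as err:
            if "unknown test method" in str(err):
                raise
            p = np.nan
        out[m] = p
    return out


# ---------------------------------------------------------------------------
# per-assay effects table

def paired_observations(dcq: pd.DataFrame, sheet: pd.DataFrame
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Vehicle and agonist dCq matrices aligned on pair ids (assays x pairs)."""
    veh = sheet[sheet["condition"] == "vehicle_control"]
    ago = sheet[sheet["condition"] == "agonist"]
    pair_ids = sorted(veh["pair_id"])
    v_map = veh.set_index("pair_id")["sample_id"]
    a_map = ago.set_index("pair_id")["sample_id"]
    v = dcq[[v_map[p] for p in pair_ids]].set_axis(pair_ids, axis=1)
    a = dcq[[a_map[p] for p in pair_ids]].set_axis(pair_ids, axis=1)
    return v, a


def effects_table(dcq: pd.DataFrame, sheet: pd.DataFrame,
                  methods: tuple[str, ...] = ("skillings_mack",),
                  n_draws: int = 10000,
                  seed: int | None = None,
                  sd_kind: str = "se") -> pd.DataFrame:
    """Per-assay ddCq estimates and p-values on a dCq matrix.

    ``sd_kind`` selects what the ``sd_log2_fc`` column reports: the standard
    error of the estimate ("se", default) or the per-pair SD ("sd_pairs");
    both are always present as explicit columns.
    """
    v_all, a_all = paired_observations(dcq, sheet)
    rng = np.random.default_rng(seed)
    rows = []
    for assay in dcq.index:
        eff = matched_pairs_effect(v_all.loc[assay], a_all.loc[assay])
        pvals = alternative_tests(v_all.loc[assay], a_all.loc[assay],
                                  methods=methods, n_draws=n_draws, seed=rng)
        row = {
            "assay_id": assay,
            "ddcq_hat": eff.ddcq_hat,
            "log2_fc": eff.log2_fc,
            "sd_pairs": eff.sd_pairs,
            "se_log2_fc": eff.se,
            "sd_log2_fc": eff.se if sd_kind == "se" else eff.sd_pairs,
            "n_pairs": eff.n_pairs_used,
            "n_pairs_dropped": eff.n_pairs_dropped,
        }
        row.update({f"p_{m}": p for m, p in pvals.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def sensitivity_grid(dcq: pd.DataFrame, sheet: pd.DataFrame,
                     n_draws: int = 10000, seed: int | None = None
                     ) -> pd.DataFrame:
    """Estimator x test grid per assay: paired and unpaired effect estimates
    crossed with the full test panel (long format)."""
    v_all, a_all = paired_observations(dcq, sheet)
    rng = np.random.default_rng(seed)
    rows = []
    for assay in dcq.index:
        v = v_all.loc[assay].to_numpy(float)
        a = a_all.loc[assay].to_numpy(float)
        eff_paired = matched_pairs_effect(v_all.loc[assay], a_all.loc[assay])
        eff_unpaired = (np.nanmean(a) - np.nanmean(v)
                        if np.isfinite(a).any() and np.isfinite(v).any()
                        else np.nan)
        pvals = alternative_tests(v_all.loc[assay], a_all.loc[assay],
                                  n_draws=n_draws, seed=rng)
        for test, p in pvals.items():
            paired_test = test in ("skillings_mack", "perm_signflip",
                                   "signed_rank")
            est_name = "matched_pairs" if paired_test else "group_means"
            est = eff_paired.ddcq_hat if paired_test else eff_unpaired
            rows.append({"assay_id": assay, "estimator": est_name,
                         "test": test, "ddcq_hat": est, "p_value": p})
    return pd.DataFrame(rows)
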