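# Methods

## Problem and model

TaqMan low-density array cards measure ~754 miRNA assays per sample as
quantification cycles (Cq); one cycle ≈ a 2-fold difference in template.
The experiments profiled here compare extracellular-vesicle (EV) miRNA
cargo between cells stimulated with a GPCR agonist and paired
vehicle-treated cells, with cell-free media controls processed in parallel.
Three features dominate the statistics: (i) missingness is mostly a
detection limit — reactions beyond ~34 cycles report no usable Cq — plus
instrument quality failures; (ii) the culture medium itself contributes
serum-derived miRNAs that must not be mistaken for EV cargo; and (iii)
samples are processed in matched vehicle/agonist pairs, so pair-level
technical variation is large, shared, and removable by within-pair
contrasts.

The analysis chain is:

1. **Well-level QC.** A reaction is set missing when Cq > 34, CqConf < 0.8
   or AmpScore < 1 (all strict, so boundary values are retained).
2. **Expression-rate acceptance.** An assay is tested only if detected in
   ≥ 80% of samples in both the vehicle and agonist groups.  The
   either-group variant is available (`expr_rule="either_group"`); "both"
   is the default because it is the stricter, analysis-operative reading.
3. **Media-control exclusion.** Assays present in media control (detected
   in ≥ 50% of MC replicates) are removed if they appear in no treated
   sample (media-only), or if the MC mean Cq is not at least 3.3 cycles
   (10-fold) above the vehicle-control mean.  The rule is directional by
   default — the point is to keep assays *more* abundant in
   cell-conditioned media — with an absolute-difference mode for
   sensitivity checks.  Group means use detected wells only; censored
   wells have no Cq to average.
4. **Normalization.** No universal EV reference miRNA exists, so the
   normalizer is the per-sample mean Cq of a data-driven endogenous panel
   pooled across both cards.  An assay qualifies when it is (1) detected
   in < 50% of media controls, (2) detected in 100% of vehicle/agonist
   samples, and (3) — if sporadically detected in MC — separated from the
   vehicle mean by > 3.3 cycles (two-sided, per "different from").  ΔCq =
   Cq − normalizer mean *of the same sample*: per-sample rather than
   per-group, because a per-group mean would cancel out of every
   within-pair contrast and make ΔΔCq independent of the pairing the
   estimator relies on.  A per-group mode exists for sensitivity analysis.
   If nothing qualifies the pipeline raises rather than silently falling
   back; an explicit override list is the documented escape hatch.
5. **Effect estimation.** ΔΔCq per assay is the mean of per-pair
   differences ΔCq(agonist) − ΔCq(vehicle) over complete pairs — equal to
   the treatment coefficient of a within-pairs regression with pair fixed
   effects (verified against a least-squares oracle in the tests).
   log2 fold change = −ΔΔCq; fold change = 2^−ΔΔCq.  Pairs missing one
   side are dropped and counted; fewer than two complete pairs makes the
   effect "not estimable" (reported, not raised).
6. **Testing.** The primary p-value is the Skillings–Mack statistic, the
   generalization of the Friedman rank test to incomplete blocks: blocks
   (pairs) observing < 2 treatments are dropped, observations are ranked
   within blocks (midranks for ties), the centered scaled rank scores are
   summed per treatment, and T = AᵀΣ⁻A is referred to χ² with
   df = rank(Σ).  Σ is singular by construction (scores sum to zero), so a
   generalized inverse is used and the rank is computed with a relative
   eigenvalue tolerance of 1e-8.  On complete two-treatment data T
   reduces to (S₊ − S₋)²/n — six concordant pairs give T = 6.0
   (p = 0.0143), five give 5.0 (p = 0.0253).  The covariance is not
   tie-corrected; the within-block permutation Monte-Carlo p (add-one
   corrected, seeded) is the remedy when ties or very small block counts
   matter.  At 4–6 usable blocks the χ² tail is anti-conservative (the
   null calibration runs near 6%, not 5%, under 30% one-sided pair
   missingness); this is a documented property of the approximation, not
   a bug, and the Monte-Carlo p removes it.
7. **Sensitivity grid.** Alternative tests — exact sign-flip permutation
   on per-pair differences (full enumeration up to 12 pairs, ≤ 4096
   evaluations), Wilcoxon signed-rank, Welch's t, Mann–Whitney, and
   unpaired label permutation — crossed with the matched-pairs and
   group-means estimators, reproduce the estimator × test sensitivity
   analysis.  All p-values are two-sided.
8. **Selection.** Assays are ranked by |log2FC| (ties by ascending p, then
   assay id) and flagged by three strict thresholds: the liberal discovery
   screen p < 0.2, the effect-size rule |log2FC| ≥ 0.585 (1.5-fold; the
   log2-scale reading is the only one consistent with reported sub-1.5
   log2FC discoveries), and conventional p < 0.05.  The signature is the
   intersection of the first two.  Heatmap inputs are row-wise
   z-transformed (population SD; zero-SD rows map to zero) and ordered by
   agglomerative clustering on Euclidean distances with average linkage
   (the distance is prescribed; the linkage is a configurable choice).

### The "SD of log2(FC)" column

Reported per-assay dispersions of 0.07–0.27 at 5–6 pairs are consistent
with a standard error rather than a per-pair SD, so `sd_log2_fc` reports
the standard error by default; both `sd_pairs` and `se_log2_fc` are always
emitted explicitly and the choice is a config switch (`sd_kind`).

## Synthetic data generator

`simulate_experiment` draws, in a fixed documented order from one seeded
RNG stream: assay baselines, class assignment, background media shifts,
pair offsets, the residual matrix, dropout uniforms, and quality-metric
draws — so one seed gives bit-identical output within this implementation.

Underlying Cq = baseline + card-B offset + pair offset + planted ΔΔCq
(agonist wells) + class-dependent media shift (MC wells) + residual.
Assays fall into three classes: *media-only* (serum background detectable
only in MC; treated wells undetected by construction), *cell-derived*
(MC shifted +6 cycles, usually beyond the ceiling), and *background*
(similar levels in MC and treated samples, shift ~ N(0, 1) — these are
exactly what the 3.3-cycle rule should remove).  Missingness arises from
hard censoring at 34 cycles plus a logistic dropout in the underlying Cq
centred at the ceiling (slope 1/cycle by default), because real detection
failure is gradual, not a step.  QC failures are *realized as* low
AmpScore/CqConf values at the configured rate and left in the table, so
the QC module — not the simulator — removes them.

Defaults and why: baseline Cq ~ N(28, 3) spans strongly expressed to
near-ceiling assays on these cards; pair offset SD 0.5 and card-B offset
0.5 cycles represent batch effects of the size global-mean normalization
exists to remove; residual SD 0.3 cycles is a typical well-level
repeatability for TaqMan arrays; 6 pairs and 6 media controls mirror the
study design; QC failures at 2% of wells.  Planted effects can be named
per assay or placed on the cell-derived assays with baselines nearest the
median (`effect_placement="median_baseline"`), reflecting that signature
miRNAs are by construction robustly detected species — effect recovery
then measures the estimator and filters rather than censoring luck.

What the generator does *not* emulate: pre-amplification bias,
card-position effects, sequence-dependent amplification efficiency,
between-run drift, or correlated missingness beyond the Cq-driven
mechanism.  Passing tests therefore demonstrate correctness of the
filters, normalization, estimator and tests under the stated missingness
model — not robustness to these unmodelled artifacts.

## Verification scenarios and problem sizes

`scripts/acceptance.py` (and the mirrored tests) recompute, per run:
threshold algebra; the closed-form Skillings–Mack values; null
calibration on 2000 pure-null assays of 6 pairs with 30% one-sided pair
missingness (one side of a pair dropped with probability 0.3 — generated
by a dedicated paired-null helper because the main generator's
missingness is Cq-driven); estimator recovery of planted ΔΔCq ∈ {−1.5,
−1.0, −0.585, 0, 0.585, 1.0} on 500 assays per level (6 pairs, residual
SD 0.3, baseline SD narrowed to 1.5 and dropout off so the detection
limit stays out of reach of the bias measurement, which is computed on
raw per-pair Cq differences where pair and card offsets cancel exactly);
the 5-assay hand-traced filter fixture; and end-to-end recovery of 8
planted effects (|ΔΔCq| ≥ 1) among 100 assays with 10 media-only assays.
These sizes keep a full run in well under a minute while leaving
Monte-Carlo error small relative to every margin tested.

## Numerical choices and degenerate inputs

- Strict inequalities exactly as stated for every threshold; the
  1.5-fold flag uses ≥ with a 1e-12 guard against representation error.
- Midranks for ties; generalized inverse via `scipy.linalg.pinvh`;
  statistic clamped at 0 against rounding.
- Disconnected incomplete designs raise, naming the components; designs
  with no usable block report a missing p rather than raising.
- p = 0 is clamped to the smallest positive float before −log10, with a
  warning.
- Missing Cq sentinels on input: empty, "Undetermined", "NA" (case
  insensitive); written back as "Undetermined".

## Known limitations

- The Skillings–Mack covariance is not tie-corrected; use
  `skillings_mack_mc` when ties are material.
- Censoring is treated as missingness, not modelled; strongly censored
  assays are (by design) excluded by the expression-rate filter rather
  than imputed.
- No multiple-testing adjustment: the p < 0.2 screen is deliberately a
  discovery cutoff, and downstream interpretation must treat it as such.
- Fold-change matrices fed to the heatmap can be per-condition or
  per-sample; the z-transform standardizes whatever it is given and the
  caller chooses the columns.
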