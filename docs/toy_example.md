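# Worked 5-assay toy example

A hand-traceable fixture (`examples/data/toy_wells.csv` and
`toy_sample_sheet.csv`): two media-control replicates (MC1, MC2) and two
matched vehicle/agonist pairs (V1/A1 = P1, V2/A2 = P2), five assays
covering one of each filter outcome.

## Well table

| assay       | card | MC1          | MC2 | V1   | A1   | V2   | A2   |
|-------------|------|--------------|-----|------|------|------|------|
| miR-alpha   | A    | 35.0         | Und | 25.0 | 24.0 | 25.2 | 24.1 |
| miR-beta    | A    | 28.0         | 28.4| Und  | Und  | Und  | Und  |
| miR-gamma   | B    | 27.1         | 26.9| 26.0 | 26.0 | 26.0 | 26.0 |
| miR-delta   | B    | Und          | Und | 29.0 | 29.1 | 29.5 | Und  |
| miR-epsilon | A    | 27.0 (amp 0.5)| Und| 26.0 | 25.0 | 26.2 | 25.3 |

All wells have AmpScore 1.5 and CqConf 0.95 except the two flagged below;
"Und" is an undetermined reaction.

## Hand trace (default thresholds)

**Well-level QC** (Cq > 34, CqConf < 0.8, AmpScore < 1): 30 wells in,
9 undetermined on input, 2 rejected —
miR-alpha/MC1 (Cq 35.0 > 34) and miR-epsilon/MC1 (AmpScore 0.5 < 1).

**Assay filters** (media-control presence = detection in ≥ 50% of MC;
media rule ≥ 3.3 cycles; expression rate ≥ 80% of both groups):

| assay       | MC rate | VC rate | AG rate | outcome |
|-------------|---------|---------|---------|---------|
| miR-alpha   | 0/2     | 2/2     | 2/2     | retained |
| miR-beta    | 2/2     | 0/2     | 0/2     | excluded: media-only |
| miR-gamma   | 2/2     | 2/2     | 2/2     | excluded: MC mean 27.0 − VC mean 26.0 = 1.0 < 3.3 |
| miR-delta   | 0/2     | 2/2     | 1/2     | excluded: agonist detection 0.5 < 0.8 |
| miR-epsilon | 0/2     | 2/2     | 2/2     | retained |

**Surviving assays: 2** (miR-alpha, miR-epsilon).

**Normalizers**: miR-alpha and miR-epsilon qualify (undetected in MC,
fully observed in all treated samples); miR-beta and miR-gamma fail the
MC-presence criterion, miR-delta fails full observation.
Per-sample normalizer means: V1 = (25.0+26.0)/2 = 25.5, A1 = 24.5,
V2 = 25.7, A2 = 24.7.

**Effects** (ΔCq = Cq − normalizer mean; ΔΔCq = agonist − vehicle):

* miR-alpha: ΔCq = (−0.5, −0.5, −0.5, −0.6) → per-pair ΔΔCq (0.0, −0.1)
  → ΔΔCq = −0.05, log2FC = +0.05.
* miR-epsilon: mirror image, ΔΔCq = +0.05, log2FC = −0.05.

Run `python examples/01_filter_trace.py` to reproduce every number above.
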