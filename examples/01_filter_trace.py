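"""Trace the 5-assay toy fixture through every filter stage.

Loads the printed fixture from examples/data/, applies well-level QC, the
media-control and expression-rate filters, selects normalizers, and prints
the per-stage counts documented in docs/toy_example.md.  The two surviving
assays carry near-zero effects (log2FC +/-0.05), i.e. no discovery.
"""

from pathlib import Path

from evmirna import (apply_well_qc, assay_filter_report, effects_table,
                     compute_delta_cq, pivot_to_matrix, read_sample_sheet,
                     read_well_table, select_normalizers)

data = Path(__file__).parent / "data"
wells = read_well_table(data / "toy_wells.csv")
sheet = read_sample_sheet(data / "toy_sample_sheet.csv")

qc = apply_well_qc(wells)
print("well QC counts:", qc.counts)

matrix = pivot_to_matrix(qc.wells, sheet)
report = assay_filter_report(matrix, sheet)
print("\nper-assay filter outcome:")
print(report[["mc_detection_rate", "vc_detection_rate",
              "agonist_detection_rate", "reason"]])

norm = select_normalizers(matrix, sheet)
print("\nnormalizers:", norm.assays)
print("per-sample normalizer mean:")
print(norm.per_sample_mean.dropna())

tested = report.index[report["reason"] == "retained"]
treated = sheet.loc[sheet["condition"] != "media_control", "sample_id"]
dcq = compute_delta_cq(matrix[list(treated)], norm)
effects = effects_table(dcq.loc[tested], sheet)
print("\neffects (ddCq_hat is agonist - vehicle on the dCq scale):")
print(effects[["assay_id", "ddcq_hat", "log2_fc", "n_pairs",
               "p_skillings_mack"]])
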