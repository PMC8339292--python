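"""Transcriptome-wide best-cutoff survival scan with FDR and ranking.

For each gene, every distinct expression value between the quartiles is
tried as a dichotomizing cutoff; the split with the smallest log-rank
p-value is kept. Benjamini-Hochberg FDR is computed across genes, then the
filter cascade (FDR <= 5%, max expression > 1000, cutoff > 100, best probe
per gene) yields the ranked biomarker list.
"""

from kmscan import (
    SimulationConfig,
    apply_filters,
    scale_normalize,
    scan_transcriptome,
    simulate_cohort,
)
from kmscan.ranking import results_table

config = SimulationConfig(
    n_datasets=2, samples_per_dataset=150, n_probes=400, n_prognostic=8,
    n_duplicates=0, n_outlier_arrays=0, n_biased_arrays=0, seed=3,
)
matrix, clinical, _, probe_map, truth = simulate_cohort(config)
normalized = scale_normalize(matrix)
survival = clinical.set_index("sample_id")[["rfs_months", "rfs_event"]]

scan = scan_transcriptome(normalized, survival, probe_map)
ranked, report = apply_filters(scan.results, probe_map)

print(f"scanned {len(scan.results)} gene-mapped probes "
      f"({len(scan.unscannable)} unscannable)")
print(f"filter cascade: {report.n_gene_mapped} mapped -> {report.n_fdr_pass} "
      f"FDR<=5% -> {report.n_maxexpr_pass} expressed -> {report.n_cutoff_pass} "
      f"cutoff>100 -> {report.n_bestprobe_pass} best probes")

table = results_table(ranked).head(10)
print(table[["rank", "gene_symbol", "probe_id", "best_cutoff", "hr",
             "p_value", "fdr_q"]].to_string(index=False))

planted = set(truth.prognostic_probe_ids)
hits = [r.probe_id for r in ranked if r.probe_id in planted]
print(f"\n{len(hits)}/{len(planted)} planted prognostic genes recovered; "
      "hazard ratios near the planted 2.5 (protective genes appear as ~0.4).")
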