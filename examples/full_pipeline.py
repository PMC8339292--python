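"""Run the complete pipeline — normalize, QC, deduplicate, build the
ER+/ERBB2- chemotherapy-treated cohort, scan, filter, rank — and print the
run manifest.
"""

import json

from kmscan import PipelineConfig, run_pipeline

config = PipelineConfig(
    subtype="er_pos_erbb2_neg",
    treatment_rule="chemo_documented",
    seed=7,
    simulation=dict(
        n_datasets=3, samples_per_dataset=120, n_probes=400, n_prognostic=8,
        treated_fraction=0.6, untreated_fraction=0.2,
        n_duplicates=4, n_outlier_arrays=3, n_biased_arrays=2,
    ),
)
manifest, ranked, report = run_pipeline(config, outdir="scratch/pipeline_demo")

print(json.dumps(manifest.counts, indent=1))
print(f"\ntop gene: {ranked[0].gene_symbol} "
      f"(HR {ranked[0].fit.hr:.2f}, p {ranked[0].fit.p_value:.2g}, "
      f"q {ranked[0].fdr_q:.2g})")
print("Counts reconcile stage by stage; rerunning with the same seed "
      "reproduces identical tables in scratch/pipeline_demo/.")
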