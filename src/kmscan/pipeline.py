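"""End-to-end orchestration: normalize -> QC exclude -> deduplicate ->
cohort -> scan -> FDR -> filter -> rank, with a reproducible run manifest.

A single YAML configuration holds every threshold of the analysis (receptor
probe cutoffs 500/4800, normalization target 1000, FDR 5%, expression and
cutoff floors 1000/100) so defaults are visible and overridable. Each stage
logs one line with its sample/gene counts, making the filter cascade
auditable, and the manifest records the counts for reconciliation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohorts import CohortSpec, assign_receptor_status, select_cohort
from .io import write_gene_list
from .matrix import ExpressionMatrix
from .preprocess import classify_qc, exclude_biased, remove_redundant, scale_normalize
from .ranking import apply_filters, results_table
from .scan import scan_transcriptome
from .simulate import SimulationConfig, simulate_cohort

logger = logging.getLogger("kmscan")

__all__ = ["PipelineConfig", "RunManifest", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """Raised when a stage fails; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    """Analysis settings; ``simulation`` drives the built-in generator."""

    subtype: str = "er_pos_erbb2_neg"
    treatment_rule: str = "chemo_documented"
    target_mean: float = 1000.0
    er_cutoff: float = 500.0
    erbb2_cutoff: float = 4800.0
    fdr_max: float = 0.05
    min_max_expression: float = 1000.0
    min_cutoff: float = 100.0
    ties: str = "efron"
    test: str = "score"
    seed: int = 0
    simulation: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class RunManifest:
    """Audit record of one pipeline run."""

    config: dict
    seed: int
    version: str
    counts: dict
    timestamp: str

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)


def run_pipeline(config, outdir=None):
    """Run the full analysis on a simulated cohort.

    ``config`` is a :class:`PipelineConfig` or a path to its YAML form.
    Returns ``(manifest, ranked_results, filter_report)``; when ``outdir``
    is given, the ranked table, gene list, filter report and manifest are
    written there. Identical config and seed reproduce identical tables.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)

    counts = {}

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise PipelineError(name, str(exc)) from exc
        return wrap

    sim_kwargs = dict(config.simulation)
    sim_kwargs.setdefault("seed", config.seed)
    sim_config = SimulationConfig(**sim_kwargs)
    matrix, clinical, qc, probe_map, truth = stage("simulate")(
        lambda: simulate_cohort(sim_config)
    )
    counts["samples_simulated"] = matrix.n_samples
    counts["probes"] = matrix.n_probes
    logger.info("simulate: %d samples, %d probes", matrix.n_samples, matrix.n_probes)

    normalized = stage("normalize")(
        lambda: scale_normalize(matrix, target_mean=config.target_mean)
    )

    statuses = stage("qc")(lambda: classify_qc(qc))
    n_biased = sum(s.label == "biased" for s in statuses)
    n_outlier = sum(s.label == "outlier" for s in statuses)
    kept = stage("qc")(lambda: exclude_biased(normalized, statuses))
    counts["qc_outliers_flagged"] = n_outlier
    counts["qc_biased_excluded"] = n_biased
    counts["samples_after_qc"] = kept.n_samples
    logger.info("qc: %d outliers flagged, %d biased excluded", n_outlier, n_biased)

    deduped, dropped = stage("deduplicate")(lambda: remove_redundant(kept))
    counts["duplicates_removed"] = len(dropped)
    counts["samples_after_dedup"] = deduped.n_samples
    logger.info("deduplicate: %d redundant arrays removed", len(dropped))

    def _cohort():
        calls = assign_receptor_status(
            deduped, er_cutoff=config.er_cutoff, erbb2_cutoff=config.erbb2_cutoff
        )
        clin = clinical[clinical["sample_id"].isin(deduped.sample_ids)]
        spec = CohortSpec(subtype=config.subtype, treatment_rule=config.treatment_rule)
        ids = select_cohort(clin, calls, spec)
        if not ids:
            raise ValueError(
                f"empty cohort for subtype={config.subtype}, "
                f"treatment_rule={config.treatment_rule}"
            )
        return ids

    cohort_ids = stage("cohort")(_cohort)
    counts["cohort_samples"] = len(cohort_ids)
    logger.info("cohort: %d samples selected", len(cohort_ids))

    cohort_matrix = deduped.select_samples(cohort_ids)
    survival = (
        clinical.set_index("sample_id")
        .loc[cohort_ids, ["rfs_months", "rfs_event"]]
    )
    scan = stage("scan")(
        lambda: scan_transcriptome(
            cohort_matrix, survival, probe_map, ties=config.ties, test=config.test
        )
    )
    counts["probes_scanned"] = len(scan.results)
    counts["probes_unscannable"] = len(scan.unscannable)
    logger.info("scan: %d probes scanned, %d unscannable",
                len(scan.results), len(scan.unscannable))

    ranked, report = stage("rank")(
        lambda: apply_filters(
            scan.results,
            probe_map,
            fdr_max=config.fdr_max,
            min_max_expression=config.min_max_expression,
            min_cutoff=config.min_cutoff,
        )
    )
    counts["genes_gene_mapped"] = report.n_gene_mapped
    counts["genes_fdr_pass"] = report.n_fdr_pass
    counts["genes_maxexpr_pass"] = report.n_maxexpr_pass
    counts["genes_cutoff_pass"] = report.n_cutoff_pass
    counts["genes_ranked"] = report.n_bestprobe_pass
    logger.info(
        "rank: cascade %d -> %d -> %d -> %d -> %d",
        report.n_gene_mapped, report.n_fdr_pass, report.n_maxexpr_pass,
        report.n_cutoff_pass, report.n_bestprobe_pass,
    )

    manifest = RunManifest(
        config=dataclasses.asdict(config),
        seed=config.seed,
        version=__version__,
        counts=counts,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        results_table(ranked).to_csv(outdir / "ranked_genes.tsv", sep="\t", index=False)
        write_gene_list([r.gene_symbol for r in ranked], outdir / "gene_list.txt")
        with open(outdir / "filter_report.json", "w") as fh:
            json.dump(dataclasses.asdict(report), fh, indent=1)
        with open(outdir / "manifest.json", "w") as fh:
            fh.write(manifest.to_json())
    return manifest, ranked, report
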