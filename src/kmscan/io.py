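"""Tab-separated readers and writers for the pipeline's tables."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .matrix import ExpressionMatrix

__all__ = [
    "read_expression",
    "read_clinical",
    "read_qc",
    "read_probe_map",
    "write_gene_list",
    "write_km_curve",
]


def read_expression(matrix_path, clinical_path=None) -> ExpressionMatrix:
    """Load a probes-by-samples TSV; dataset ids taken from the clinical table.

    Without a clinical table every sample is assigned a single dataset.
    Dataset publication order follows first appearance in the clinical table.
    """
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    if clinical_path is not None:
        clinical = read_clinical(clinical_path)
        dataset_id = clinical.set_index("sample_id")["dataset_id"]
        seen = list(dict.fromkeys(clinical["dataset_id"]))
        order = {ds: i + 1 for i, ds in enumerate(seen)}
    else:
        dataset_id = pd.Series("DS01", index=values.columns)
        order = {"DS01": 1}
    return ExpressionMatrix(values=values, dataset_id=dataset_id, dataset_order=order)


def read_clinical(path) -> pd.DataFrame:
    clinical = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "dataset_id": str})
    required = {"sample_id", "dataset_id", "rfs_months", "rfs_event"}
    missing = required - set(clinical.columns)
    if missing:
        raise ValueError(f"clinical table missing columns: {sorted(missing)}")
    return clinical


def read_qc(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample_id": str})


def read_probe_map(path) -> pd.DataFrame:
    pm = pd.read_csv(path, sep="\t", dtype={"probe_id": str})
    pm["gene_symbol"] = pm["gene_symbol"].where(pm["gene_symbol"].notna(), None)
    pm["is_best_probe"] = pm["is_best_probe"].astype(bool)
    return pm


def write_gene_list(genes, path) -> None:
    """One gene symbol per line — ready for external enrichment tools."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def write_km_curve(curve, path) -> None:
    pd.DataFrame(
        {
            "time": curve.event_times,
            "survival": curve.survival_probability,
            "at_risk": curve.at_risk,
        }
    ).to_csv(path, sep="\t", index=False)
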