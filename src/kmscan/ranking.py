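"""Filter cascade, absolute-HR ranking and gene-list overlap statistics.

Scanned probes pass through five sequential filters before ranking:

1. mapped to a gene symbol (unmapped probes never enter the scan/FDR);
2. FDR q-value at most ``fdr_max`` (default 5%);
3. maximal expression across the cohort strictly over ``min_max_expression``
   (default 1000 — the post-normalization mean intensity), i.e. the gene is
   robustly expressed in at least one sample;
4. selected cutoff strictly over ``min_cutoff`` (default 100), excluding
   dichotomizations at background-noise level;
5. only the designated best probe set per gene is retained.

Survivors are ranked by absolute hazard ratio, max(HR, 1/HR), treating
protective and risk directions symmetrically.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

__all__ = [
    "FilterReport",
    "OverlapReport",
    "apply_filters",
    "absolute_hr",
    "list_overlap",
    "results_table",
]


@dataclass(frozen=True)
class FilterReport:
    """Probe counts surviving each stage of the filter cascade."""

    n_gene_mapped: int
    n_fdr_pass: int
    n_maxexpr_pass: int
    n_cutoff_pass: int
    n_bestprobe_pass: int
    fdr_max: float
    min_max_expression: float
    min_cutoff: float

    def __post_init__(self) -> None:
        counts = (
            self.n_gene_mapped,
            self.n_fdr_pass,
            self.n_maxexpr_pass,
            self.n_cutoff_pass,
            self.n_bestprobe_pass,
        )
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise ValueError("filter-cascade counts must be non-increasing")


@dataclass(frozen=True)
class OverlapReport:
    """Overlap between two gene lists, percentages on the combined list."""

    n_a: int
    n_b: int
    n_shared: int
    n_combined: int
    pct_shared_of_combined: float
    pct_unique_to_one: float
    shared_genes: tuple


def absolute_hr(hr: float) -> float:
    """Direction-symmetric hazard ratio: max(hr, 1/hr).

    A protective HR of 0.3 and a risk HR of 3.33 carry the same
    discriminating strength; both map to ~3.33.
    """
    if not np.isfinite(hr) or hr <= 0:
        raise ValueError("hazard ratio must be positive and finite")
    return max(hr, 1.0 / hr)


def apply_filters(
    results,
    probe_map: pd.DataFrame,
    fdr_max: float = 0.05,
    min_max_expression: float = 1000.0,
    min_cutoff: float = 100.0,
):
    """Run the five-stage cascade and rank survivors by absolute HR (descending).

    ``results`` are :class:`~kmscan.scan.ScanResult` objects carrying
    ``fdr_q`` and ``max_expression``. Returns ``(ranked, FilterReport)``.
    Ties in absolute HR are ordered by ascending p-value, then probe id, for
    a deterministic output.
    """
    mapped_genes = {
        str(r.probe_id): r.gene_symbol
        for r in probe_map.itertuples(index=False)
        if isinstance(r.gene_symbol, str) and r.gene_symbol
    }
    best_probes = {
        str(r.probe_id)
        for r in probe_map.itertuples(index=False)
        if bool(r.is_best_probe)
    }

    stage1 = [r for r in results if r.probe_id in mapped_genes]
    stage2 = [r for r in stage1 if r.fdr_q is not None and r.fdr_q <= fdr_max]
    stage3 = [r for r in stage2 if r.max_expression > min_max_expression]
    stage4 = [r for r in stage3 if r.best_cutoff > min_cutoff]
    stage5 = [r for r in stage4 if r.probe_id in best_probes]

    ranked = sorted(
        stage5,
        key=lambda r: (-r.fit.absolute_hr, r.fit.p_value, r.probe_id),
    )
    report = FilterReport(
        n_gene_mapped=len(stage1),
        n_fdr_pass=len(stage2),
        n_maxexpr_pass=len(stage3),
        n_cutoff_pass=len(stage4),
        n_bestprobe_pass=len(stage5),
        fdr_max=fdr_max,
        min_max_expression=min_max_expression,
        min_cutoff=min_cutoff,
    )
    return ranked, report


def _pct(numerator: int, denominator: int) -> float:
    """Percentage rounded half-up to one decimal (report formatting parity)."""
    if denominator == 0:
        return 0.0
    frac = Decimal(100 * numerator) / Decimal(denominator)
    return float(frac.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def list_overlap(list_a, list_b) -> OverlapReport:
    """Overlap statistics between two deduplicated gene-symbol lists."""
    a, b = set(list_a), set(list_b)
    if len(a) != len(list_a) or len(b) != len(list_b):
        raise ValueError("gene lists must be deduplicated")
    shared = a & b
    combined = a | b
    return OverlapReport(
        n_a=len(a),
        n_b=len(b),
        n_shared=len(shared),
        n_combined=len(combined),
        pct_shared_of_combined=_pct(len(shared), len(combined)),
        pct_unique_to_one=_pct(len(combined) - len(shared), len(combined)),
        shared_genes=tuple(sorted(shared)),
    )


def results_table(results) -> pd.DataFrame:
    """Flatten scan results into the ranked output table."""
    rows = []
    for rank, r in enumerate(results, start=1):
        rows.append(
            {
                "rank": rank,
                "gene_symbol": r.gene_symbol,
                "probe_id": r.probe_id,
                "best_cutoff": r.best_cutoff,
                "hr": r.fit.hr,
                "absolute_hr": r.fit.absolute_hr,
                "ci_low": r.fit.ci_low,
                "ci_high": r.fit.ci_high,
                "p_value": r.fit.p_value,
                "fdr_q": r.fdr_q,
                "n_low": r.fit.n_low,
                "n_high": r.fit.n_high,
                "n_events": r.fit.n_events,
                "max_expression": r.max_expression,
            }
        )
    return pd.DataFrame(rows)
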