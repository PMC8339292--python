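"""Array-level preprocessing: scaling normalization, QC classification and
redundant-array removal.

The pipeline consumes already-summarized (MAS5-like) intensities. Three
preprocessing steps are applied before any survival statistics:

1. *Scaling normalization* — each array is rescaled so its mean intensity
   over a reference probe set equals a common target (default 1000),
   removing multiplicative batch differences between datasets.
2. *QC classification* — five per-array quality metrics (background, raw Q,
   percent present calls, bioB/C/D spike presence, GAPDH/ACTB 3'/5' ratio)
   are screened; an array failing exactly one metric is an *outlier*
   (flagged, retained), two or more a *biased* array (excluded).
3. *Redundancy removal* — arrays with identical expression vectors (the same
   physical array submitted to several repository series) are collapsed to
   the copy from the earliest-published dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

__all__ = [
    "QC_CONTINUOUS_PARAMS",
    "QcStatus",
    "scale_normalize",
    "classify_qc",
    "remove_redundant",
    "exclude_biased",
]

#: Continuous QC metrics screened against the central 95% range.
QC_CONTINUOUS_PARAMS = ("background", "raw_q", "percent_present", "ratio_3to5")

#: Flag QC metric: bioB/C/D hybridization spike-in controls detected.
QC_FLAG_PARAM = "biob_spikes_present"


@dataclass(frozen=True)
class QcStatus:
    """Per-array QC verdict.

    ``label`` is ``pass`` (no metric failed), ``outlier`` (exactly one) or
    ``biased`` (two or more). Only biased arrays are excluded from analysis.
    """

    sample_id: str
    label: str
    failed_parameters: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        n = len(self.failed_parameters)
        expected = "pass" if n == 0 else ("outlier" if n == 1 else "biased")
        if self.label != expected:
            raise ValueError(
                f"label {self.label!r} inconsistent with {n} failed parameters"
            )


def scale_normalize(
    matrix: ExpressionMatrix,
    reference_probes=None,
    target_mean: float = 1000.0,
) -> ExpressionMatrix:
    """Rescale every array so its mean over ``reference_probes`` equals
    ``target_mean``.

    The reference set defaults to all probes in the matrix (the use case is a
    platform-overlap probe set shared by every array). The operation is a
    per-column multiplication, hence idempotent and non-negativity preserving.

    Raises
    ------
    ValueError
        If a reference probe is absent, or an array has a non-positive mean
        over the reference probes (the offending sample is named).
    """
    if reference_probes is None:
        reference_probes = matrix.probe_ids
    reference_probes = list(reference_probes)
    missing = set(reference_probes) - set(matrix.probe_ids)
    if missing:
        raise ValueError(f"reference probes not in matrix: {sorted(missing)[:5]}")
    ref = matrix.values.loc[reference_probes]
    means = ref.mean(axis=0)
    bad = means[means <= 0]
    if len(bad):
        raise ValueError(
            f"non-positive reference mean for samples: {list(bad.index)[:5]}"
        )
    factors = target_mean / means
    out = matrix.copy()
    out.values = matrix.values.mul(factors, axis=1)
    return out


def classify_qc(qc: pd.DataFrame) -> list:
    """Classify every array as pass / outlier / biased from its QC metrics.

    ``qc`` must contain one row per array with columns ``sample_id``,
    the four continuous metrics and the spike flag. A continuous metric
    fails when it is non-positive or falls strictly outside the central 95%
    range (2.5th-97.5th percentile, linear interpolation, inclusive bounds)
    of that metric across all arrays. The spike flag fails when false.

    Returns a list of :class:`QcStatus`, one per row, in input order.
    """
    required = ["sample_id", *QC_CONTINUOUS_PARAMS, QC_FLAG_PARAM]
    missing_cols = [c for c in required if c not in qc.columns]
    if missing_cols:
        raise ValueError(f"QC table missing columns: {missing_cols}")
    if len(qc) == 0:
        raise ValueError("QC table is empty")
    incomplete = qc.loc[qc[required].isna().any(axis=1), "sample_id"]
    if len(incomplete):
        raise ValueError(f"missing QC values for samples: {list(incomplete)[:5]}")

    bounds = {}
    for param in QC_CONTINUOUS_PARAMS:
        vals = qc[param].to_numpy(dtype=float)
        bounds[param] = np.percentile(vals, [2.5, 97.5])

    statuses = []
    for row in qc.itertuples(index=False):
        failed = []
        for param in QC_CONTINUOUS_PARAMS:
            v = float(getattr(row, param))
            lo, hi = bounds[param]
            if v <= 0 or v < lo or v > hi:
                failed.append(param)
        if not bool(getattr(row, QC_FLAG_PARAM)):
            failed.append(QC_FLAG_PARAM)
        n = len(failed)
        label = "pass" if n == 0 else ("outlier" if n == 1 else "biased")
        statuses.append(QcStatus(str(row.sample_id), label, tuple(failed)))
    return statuses


def _round_significant(values: np.ndarray, digits: int = 6) -> np.ndarray:
    """Round to ``digits`` significant figures (0 stays 0)."""
    a = np.asarray(values, dtype=float)
    out = np.zeros_like(a)
    nz = a != 0
    mag = np.floor(np.log10(np.abs(a[nz])))
    factor = 10.0 ** (digits - 1 - mag)
    out[nz] = np.round(a[nz] * factor) / factor
    return out


def remove_redundant(matrix: ExpressionMatrix):
    """Collapse arrays with identical expression vectors to a single copy.

    Identity is judged after rounding to 6 significant figures (guards
    against serialization noise). Among identical columns the sample from
    the dataset with the smallest publication order is kept; ties broken by
    lexicographically smallest sample id.

    Returns
    -------
    (ExpressionMatrix, list of (kept_sample_id, dropped_sample_id))
    """
    if matrix.n_samples == 0:
        return matrix.copy(), []
    order = matrix.dataset_order or {}
    rounded = _round_significant(matrix.values.to_numpy())
    groups: dict = {}
    for j, sid in enumerate(matrix.sample_ids):
        key = rounded[:, j].tobytes()
        groups.setdefault(key, []).append(sid)

    def _rank(sid: str):
        ds = matrix.dataset_id.loc[sid]
        return (order.get(ds, 0), sid)

    dropped = []
    keep_set = set()
    for members in groups.values():
        keeper = min(members, key=_rank)
        keep_set.add(keeper)
        for sid in members:
            if sid != keeper:
                dropped.append((keeper, sid))
    kept = [sid for sid in matrix.sample_ids if sid in keep_set]
    return matrix.select_samples(kept), sorted(dropped, key=lambda p: p[1])


def exclude_biased(matrix: ExpressionMatrix, statuses) -> ExpressionMatrix:
    """Drop arrays labeled ``biased``; pass and outlier arrays are retained."""
    by_id = {s.sample_id: s for s in statuses}
    uncovered = [sid for sid in matrix.sample_ids if sid not in by_id]
    if uncovered:
        raise ValueError(f"QC status missing for samples: {uncovered[:5]}")
    kept = [sid for sid in matrix.sample_ids if by_id[sid].label != "biased"]
    return matrix.select_samples(kept)
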