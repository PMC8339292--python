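"""In-memory container for probe-by-sample intensity matrices.

Intensities are MAS5-style summarized values: non-negative, on an arbitrary
multiplicative scale per array until :func:`kmscan.preprocess.scale_normalize`
pins each array's mean over a reference probe set to a common target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix"]


@dataclass
class ExpressionMatrix:
    """Probe-by-sample expression intensities with per-sample dataset labels.

    Parameters
    ----------
    values
        DataFrame with probe ids as index and sample ids as columns.
        All entries must be finite and non-negative.
    dataset_id
        Series mapping each sample id to the dataset (series/accession) it
        came from.
    dataset_order
        Publication rank per dataset id (1 = earliest). Used to decide which
        copy of a redundant array is retained.
    """

    values: pd.DataFrame
    dataset_id: pd.Series
    dataset_order: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValueError("probe ids must be unique")
        if not self.values.columns.is_unique:
            raise ValueError("sample ids must be unique")
        vals = self.values.to_numpy()
        if vals.size and (not np.isfinite(vals).all() or (vals < 0).any()):
            raise ValueError("expression intensities must be finite and non-negative")
        self.dataset_id = pd.Series(self.dataset_id)
        missing = self.values.columns.difference(self.dataset_id.index)
        if len(missing):
            raise ValueError(f"samples without dataset id: {list(missing)[:5]}")
        self.dataset_id = self.dataset_id.loc[self.values.columns]

    # -- convenience accessors -------------------------------------------------
    @property
    def probe_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    def select_samples(self, sample_ids) -> "ExpressionMatrix":
        """Return a new matrix restricted to ``sample_ids`` (order preserved)."""
        sample_ids = list(sample_ids)
        return ExpressionMatrix(
            values=self.values[sample_ids].copy(),
            dataset_id=self.dataset_id.loc[sample_ids].copy(),
            dataset_order=dict(self.dataset_order),
        )

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=self.values.copy(),
            dataset_id=self.dataset_id.copy(),
            dataset_order=dict(self.dataset_order),
        )
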