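import numpy as np
import pandas as pd
import pytest

from kmscan import ExpressionMatrix, SimulationConfig, SurvivalData, simulate_cohort


def make_matrix(values, sample_ids=None, probe_ids=None, dataset_id=None, dataset_order=None):
    """Small-matrix helper for hand-built fixtures."""
    values = np.asarray(values, dtype=float)
    n_probes, n_samples = values.shape
    probe_ids = probe_ids or [f"P{i}" for i in range(n_probes)]
    sample_ids = sample_ids or [f"S{j}" for j in range(n_samples)]
    if dataset_id is None:
        dataset_id = {s: "DS01" for s in sample_ids}
    dataset_order = dataset_order or {"DS01": 1}
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=probe_ids, columns=sample_ids),
        dataset_id=pd.Series(dataset_id),
        dataset_order=dataset_order,
    )


def random_survival(rng, n, censor_frac=0.3):
    """Survival data unrelated to anything, for null/oracle checks."""
    time = rng.exponential(50.0, size=n)
    event = (rng.uniform(size=n) > censor_frac).astype(int)
    if event.sum() == 0:
        event[0] = 1
    return SurvivalData(time=time, event=event)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact default cohort shared by read-only tests."""
    config = SimulationConfig(
        n_datasets=2,
        samples_per_dataset=60,
        n_probes=80,
        n_prognostic=5,
        n_duplicates=4,
        n_outlier_arrays=3,
        n_biased_arrays=2,
        seed=11,
    )
    return config, simulate_cohort(config)
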