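"""Synthetic multi-dataset expression + survival cohorts with planted effects.

The generator emulates the structure of a pooled microarray survival
database: several datasets (batches) with MAS5-like skewed non-negative
intensities on a shared probe set, per-dataset multiplicative scale
differences, proportional-hazards relapse-free survival with a handful of
planted prognostic genes, independent right censoring, duplicated arrays
(the same sample resubmitted under a later dataset), and designated
QC-failing arrays. Every planted feature is recorded in a
:class:`GroundTruth` so downstream stages can be tested for exact recovery.

Planted effects form a single shared prognostic program: one latent binary
risk factor multiplies the hazard by exp(|true log HR|), and every planted
gene expresses that program (up- or down-regulated, sign random per gene)
strongly enough that dichotomizing the gene at the program's quantile
(default the median) recovers the risk factor with ~2% discordance. This
matches the dichotomizing estimand of the downstream cutoff scan and keeps
each gene's marginal hazard ratio equal to the planted value — independent
per-gene hazards would attenuate all marginal estimates through the frailty
induced by the other planted genes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize

from .cohorts import ER_PROBE, ERBB2_PROBE
from .matrix import ExpressionMatrix

__all__ = ["SimulationConfig", "GroundTruth", "simulate_cohort", "simulate_survival", "write_cohort"]

# QC metric operating bands: (center, grid step). Clean arrays draw from a
# coarse 7-point grid center +/- 3 steps; designated failures sit 25 steps
# out, far beyond any empirical 95% band.
_QC_GRID = {
    "background": (55.0, 1.0),
    "raw_q": (2.2, 0.05),
    "percent_present": (45.0, 1.5),
    "ratio_3to5": (1.2, 0.05),
}
_FAIL_OFFSET_STEPS = 25


@dataclass
class SimulationConfig:
    """Conditions of a simulated cohort.

    Defaults describe the reference recovery experiment: two batches of 200
    samples, 1000 probes of which 20 carry a planted prognostic effect of
    |log HR| = log 2.5 (sign random per gene), exponential baseline with a
    60-month median relapse-free survival, ~30% of follow-up right-censored.
    """

    n_datasets: int = 2
    samples_per_dataset: int = 200
    n_probes: int = 1000
    n_prognostic: int = 20
    true_log_hr: float = math.log(2.5)
    baseline_median_survival: float = 60.0
    censoring_fraction_target: float = 0.3
    batch_scale_range: tuple = (0.7, 1.4)
    er_positive_fraction: float = 0.75
    erbb2_positive_fraction: float = 0.17
    treated_fraction: float = 0.5
    untreated_fraction: float = 0.25
    n_duplicates: int = 5
    n_outlier_arrays: int = 5
    n_biased_arrays: int = 3
    seed: int = 0
    weibull_shape: float = 1.0
    effect_quantile: float = 0.5

    def validate(self) -> None:
        if min(self.n_datasets, self.samples_per_dataset, self.n_probes) < 1:
            raise ValueError("n_datasets, samples_per_dataset and n_probes must be positive")
        if self.n_prognostic < 0 or self.n_prognostic > self.n_probes - 2:
            raise ValueError("n_prognostic must fit among the non-marker probes")
        if self.baseline_median_survival <= 0:
            raise ValueError("baseline_median_survival must be positive")
        if not 0 <= self.censoring_fraction_target < 1:
            raise ValueError("censoring_fraction_target must lie in [0, 1)")
        lo, hi = self.batch_scale_range
        if lo <= 0 or hi <= 0 or lo > hi:
            raise ValueError("batch_scale_range must be a positive (low, high) pair")
        for name in ("er_positive_fraction", "erbb2_positive_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.treated_fraction < 0 or self.untreated_fraction < 0:
            raise ValueError("treatment fractions must be non-negative")
        if self.treated_fraction + self.untreated_fraction > 1:
            raise ValueError("treated_fraction + untreated_fraction must be <= 1")
        n_total = self.n_datasets * self.samples_per_dataset
        designated = self.n_duplicates + self.n_outlier_arrays + self.n_biased_arrays
        if designated > n_total:
            raise ValueError(
                "more duplicates/QC failures than samples in the cohort budget"
            )
        if self.n_duplicates > 0 and self.n_datasets < 2:
            raise ValueError("duplicates need at least two datasets (copy gets a later one)")
        if self.weibull_shape <= 0:
            raise ValueError("weibull_shape must be positive")
        if not 0 < self.effect_quantile < 1:
            raise ValueError("effect_quantile must lie in (0, 1)")


@dataclass
class GroundTruth:
    """Everything planted into a simulated cohort, keyed for recovery tests."""

    prognostic_probe_ids: list
    true_log_hr: dict
    linear_predictor: dict
    duplicate_pairs: list
    qc_fail_labels: dict
    er_status: dict = field(default_factory=dict)
    erbb2_status: dict = field(default_factory=dict)
    risk_group: dict = field(default_factory=dict)


def _streams(seed: int) -> dict:
    """One independent RNG per generation stage, all derived from one seed."""
    names = ["expression", "receptor", "survival", "censoring", "clinical", "structure", "qc"]
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


# ---------------------------------------------------------------------------
# Survival generation
# ---------------------------------------------------------------------------

def _weibull_rate(config: SimulationConfig) -> float:
    # (lam * median)^k = ln 2
    return math.log(2.0) ** (1.0 / config.weibull_shape) / config.baseline_median_survival


def _expected_censored_fraction(c: float, lam: float, shape: float, lp: np.ndarray) -> float:
    """P(censored) under C ~ U(0, c), T Weibull-PH with linear predictors lp."""
    # Gauss-Legendre on (0, c); deterministic and exact enough for calibration
    nodes, weights = np.polynomial.legendre.leggauss(64)
    t = 0.5 * c * (nodes + 1.0)
    w = 0.5 * c * weights
    hazard_scale = np.exp(lp)[:, None]
    surv = np.exp(-((lam * t[None, :]) ** shape) * hazard_scale)
    return float(((surv @ w) / c).mean())


def _calibrate_censoring(config: SimulationConfig, lp: np.ndarray) -> float:
    """Upper bound c of the uniform censoring window hitting the target fraction."""
    target = config.censoring_fraction_target
    lam = _weibull_rate(config)
    shape = config.weibull_shape

    def f(c):
        return _expected_censored_fraction(c, lam, shape, lp) - target

    hi = config.baseline_median_survival
    while f(hi) > 0:
        hi *= 2.0
        if hi > 1e9:
            break
    lo = hi
    while f(lo) < 0:
        lo /= 2.0
        if lo < 1e-9:
            break
    return float(optimize.brentq(f, lo, hi, xtol=1e-6, rtol=1e-10))


def simulate_survival(linear_predictor, config: SimulationConfig, rng) -> tuple:
    """Draw right-censored survival under a Weibull (default exponential) PH model.

    Event times follow S(t | lp) = exp(-(lam t)^k e^lp) with the rate lam set
    so the baseline (lp = 0) median equals ``baseline_median_survival``.
    Censoring times are independent Uniform(0, c) with c calibrated by root
    finding so the expected censored fraction matches the target; a target of
    zero disables censoring entirely.

    Returns ``(time, event)`` arrays; times are strictly positive.
    """
    lp = np.asarray(linear_predictor, dtype=float)
    if not np.isfinite(lp).all():
        raise ValueError("linear predictor must be finite")
    if config.baseline_median_survival <= 0:
        raise ValueError("baseline_median_survival must be positive")
    lam = _weibull_rate(config)
    shape = config.weibull_shape
    e = rng.exponential(1.0, size=lp.size)
    t_event = (e / np.exp(lp)) ** (1.0 / shape) / lam
    if config.censoring_fraction_target <= 0:
        return t_event, np.ones(lp.size, dtype=int)
    c = _calibrate_censoring(config, lp)
    t_cens = rng.uniform(0.0, c, size=lp.size)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return time, event


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _probe_ids(config: SimulationConfig) -> list:
    n_generic = config.n_probes - 2
    return [ER_PROBE, ERBB2_PROBE] + [f"PB{i:05d}_at" for i in range(n_generic)]


def _probe_map(config: SimulationConfig, probe_ids, planted, rng) -> pd.DataFrame:
    """Probe-to-gene map: mostly 1:1 best probes, some unmapped, some genes
    with a secondary (non-best) probe. Planted probes always map to their own
    gene as the best probe, as do the two receptor marker probes."""
    rows = [
        {"probe_id": ER_PROBE, "gene_symbol": "ESR1", "is_best_probe": True},
        {"probe_id": ERBB2_PROBE, "gene_symbol": "ERBB2", "is_best_probe": True},
    ]
    planted = set(planted)
    prev_gene = None
    for i, probe in enumerate(probe_ids[2:]):
        gene = f"GENE{i:05d}"
        if probe in planted:
            rows.append({"probe_id": probe, "gene_symbol": gene, "is_best_probe": True})
            prev_gene = gene
            continue
        u = rng.uniform()
        if u < 0.05:
            rows.append({"probe_id": probe, "gene_symbol": None, "is_best_probe": False})
        elif u < 0.10 and prev_gene is not None:
            rows.append({"probe_id": probe, "gene_symbol": prev_gene, "is_best_probe": False})
        else:
            rows.append({"probe_id": probe, "gene_symbol": gene, "is_best_probe": True})
            prev_gene = gene
    return pd.DataFrame(rows)


def _qc_table(config: SimulationConfig, sample_ids, outliers, biased, rng) -> pd.DataFrame:
    grid = np.arange(-3, 4)
    cols = {param: center + step * rng.choice(grid, size=len(sample_ids))
            for param, (center, step) in _QC_GRID.items()}
    qc = pd.DataFrame({"sample_id": sample_ids, **cols})
    qc["biob_spikes_present"] = True

    continuous = list(_QC_GRID)
    for k, sid in enumerate(outliers):
        param = continuous[k % len(continuous)]
        center, step = _QC_GRID[param]
        sign = 1 if k % 2 == 0 else -1
        value = center + sign * _FAIL_OFFSET_STEPS * step
        qc.loc[qc["sample_id"] == sid, param] = max(value, step)  # stay positive
    # biased arrays fail a rotating pair of parameters (one combo uses the
    # spike flag as second failure)
    combos = [
        ("background", "ratio_3to5"),
        ("raw_q", "percent_present"),
        ("background", "biob_spikes_present"),
        ("percent_present", "ratio_3to5"),
    ]
    for k, sid in enumerate(biased):
        row = qc["sample_id"] == sid
        for param in combos[k % len(combos)]:
            if param == "biob_spikes_present":
                qc.loc[row, param] = False
            else:
                center, step = _QC_GRID[param]
                qc.loc[row, param] = center + _FAIL_OFFSET_STEPS * step
    return qc


def _clinical_table(config, sample_ids, dataset_ids, time, event, er_pos, rng) -> pd.DataFrame:
    n = len(sample_ids)
    u = rng.uniform(size=n)
    treated = u < config.treated_fraction
    untreated = (~treated) & (u < config.treated_fraction + config.untreated_fraction)
    endocrine_draw = rng.uniform(size=n) < 0.5
    adjuvant_draw = rng.uniform(size=n) < 0.7

    chemo = np.where(treated, "yes", np.where(untreated, "no", "unknown"))
    endo = np.where(
        treated & er_pos & endocrine_draw, "yes", np.where(untreated, "no", np.where(treated, "no", "unknown"))
    )
    adjuvant = np.where(treated & adjuvant_draw, "yes", np.where(treated, "no", "unknown"))
    sys_untreated = np.where(untreated, "yes", np.where(treated, "no", "unknown"))
    return pd.DataFrame(
        {
            "sample_id": sample_ids,
            "dataset_id": dataset_ids,
            "rfs_months": time,
            "rfs_event": event,
            "chemotherapy": chemo,
            "endocrine_therapy": endo,
            "adjuvant_setting": adjuvant,
            "systemically_untreated": sys_untreated,
        }
    )


def simulate_cohort(config: SimulationConfig):
    """Generate a full synthetic cohort.

    Returns ``(matrix, clinical, qc, probe_map, truth)`` where ``matrix`` is
    an :class:`ExpressionMatrix` (duplicated arrays appended to the last
    dataset), ``clinical``/``qc``/``probe_map`` are DataFrames and ``truth``
    a :class:`GroundTruth`.

    Identical config (including seed) yields bitwise-identical outputs.
    """
    config.validate()
    rng = _streams(config.seed)

    dataset_names = [f"DS{i + 1:02d}" for i in range(config.n_datasets)]
    dataset_order = {name: i + 1 for i, name in enumerate(dataset_names)}
    sample_ids, dataset_ids = [], []
    for ds in dataset_names:
        for j in range(config.samples_per_dataset):
            sample_ids.append(f"{ds}_S{j + 1:04d}")
            dataset_ids.append(ds)
    n = len(sample_ids)
    probe_ids = _probe_ids(config)

    # receptor truth and marker-probe intensities
    r = rng["receptor"]
    er_pos = r.uniform(size=n) < config.er_positive_fraction
    erbb2_pos = r.uniform(size=n) < config.erbb2_positive_fraction
    # marker intensities are strongly bimodal so the planted status is
    # recoverable through the fixed intensity cutoffs (500 / 4800) after
    # per-array rescaling
    er_vals = np.where(
        er_pos,
        np.exp(r.normal(math.log(4000.0), 0.30, size=n)),
        np.exp(r.normal(math.log(80.0), 0.35, size=n)),
    )
    erbb2_vals = np.where(
        erbb2_pos,
        np.exp(r.normal(math.log(20000.0), 0.30, size=n)),
        np.exp(r.normal(math.log(1000.0), 0.35, size=n)),
    )

    # Generic probes: log-normal marginals; planted probes are robustly
    # expressed and all reflect one shared binary prognostic program (like a
    # proliferation signature), up- or down-regulated per gene. A single
    # shared risk factor keeps each gene's marginal dichotomized hazard
    # ratio equal to the planted value (independent per-gene effects would
    # attenuate every marginal estimate through the frailty the other genes
    # induce).
    e = rng["expression"]
    n_generic = config.n_probes - 2
    log_median = e.normal(math.log(400.0), 1.0, size=n_generic)
    planted_idx = e.choice(n_generic, size=config.n_prognostic, replace=False)
    log_median[planted_idx] = e.normal(math.log(1200.0), 0.3, size=config.n_prognostic)
    generic = np.exp(log_median[:, None] + 0.6 * e.standard_normal((n_generic, n)))

    planted_probes = [probe_ids[2 + i] for i in planted_idx]
    signs = np.where(e.uniform(size=config.n_prognostic) < 0.5, -1.0, 1.0)
    betas = signs * abs(config.true_log_hr)
    risk = (e.uniform(size=n) < (1.0 - config.effect_quantile)).astype(float)
    lp = abs(config.true_log_hr) * risk if config.n_prognostic > 0 else np.zeros(n)
    # shift planted genes by +/- delta around their baseline so the gene's
    # own quantile dichotomization tracks the risk factor (~2% discordance)
    delta = 2.2
    for k, i in enumerate(planted_idx):
        generic[i] *= np.exp(signs[k] * delta * (risk - 0.5))
    raw = np.vstack([er_vals[None, :], erbb2_vals[None, :], generic])

    time, event = simulate_survival(lp, config, rng["survival"])

    # per-dataset multiplicative batch scale
    s = rng["structure"]
    scales = s.uniform(config.batch_scale_range[0], config.batch_scale_range[1],
                       size=config.n_datasets)
    scale_per_sample = np.array([scales[dataset_order[d] - 1] for d in dataset_ids])
    values = raw * scale_per_sample[None, :]

    # designate duplicates and QC failures among distinct original samples
    n_designated = config.n_duplicates + config.n_outlier_arrays + config.n_biased_arrays
    if config.n_duplicates > 0:
        # duplicate originals must not come from the last dataset
        eligible = [i for i, d in enumerate(dataset_ids) if d != dataset_names[-1]]
    else:
        eligible = list(range(n))
    if n_designated > len(eligible):
        raise ValueError(
            "more duplicates/QC failures than eligible samples "
            "(duplicate originals cannot come from the last dataset)"
        )
    chosen = list(s.choice(len(eligible), size=n_designated, replace=False))
    chosen_ids = [eligible[i] for i in chosen]
    dup_src = chosen_ids[: config.n_duplicates]
    outlier_ids = [sample_ids[i] for i in chosen_ids[config.n_duplicates: config.n_duplicates + config.n_outlier_arrays]]
    biased_ids = [sample_ids[i] for i in chosen_ids[config.n_duplicates + config.n_outlier_arrays:]]

    clinical = _clinical_table(config, sample_ids, dataset_ids, time, event, er_pos, rng["clinical"])
    qc = _qc_table(config, sample_ids, outlier_ids, biased_ids, rng["qc"])

    # append duplicate columns: exact copies, assigned to the last dataset
    duplicate_pairs = []
    dup_cols, dup_sids, dup_ds = [], [], []
    for k, i in enumerate(dup_src):
        sid = f"{dataset_names[-1]}_D{k + 1:04d}"
        duplicate_pairs.append((sample_ids[i], sid))
        dup_cols.append(values[:, i])
        dup_sids.append(sid)
        dup_ds.append(dataset_names[-1])
        for table in (clinical, qc):
            row = table[table["sample_id"] == sample_ids[i]].iloc[0].copy()
            row["sample_id"] = sid
            if "dataset_id" in table.columns:
                row["dataset_id"] = dataset_names[-1]
            table.loc[len(table)] = row

    all_ids = sample_ids + dup_sids
    all_ds = dataset_ids + dup_ds
    if dup_cols:
        values = np.hstack([values, np.column_stack(dup_cols)])

    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=probe_ids, columns=all_ids),
        dataset_id=pd.Series(all_ds, index=all_ids),
        dataset_order=dataset_order,
    )
    probe_map = _probe_map(config, probe_ids, planted_probes, rng["structure"])

    truth = GroundTruth(
        prognostic_probe_ids=planted_probes,
        true_log_hr={p: float(b) for p, b in zip(planted_probes, betas)},
        linear_predictor={sid: float(v) for sid, v in zip(sample_ids, lp)},
        duplicate_pairs=duplicate_pairs,
        qc_fail_labels={**{sid: "outlier" for sid in outlier_ids},
                        **{sid: "biased" for sid in biased_ids}},
        er_status={sid: bool(v) for sid, v in zip(sample_ids, er_pos)},
        erbb2_status={sid: bool(v) for sid, v in zip(sample_ids, erbb2_pos)},
        risk_group={sid: bool(v) for sid, v in zip(sample_ids, risk)},
    )
    return matrix, clinical, qc, probe_map, truth


def write_cohort(outdir, matrix, clinical, qc, probe_map, truth) -> None:
    """Write the four tab-separated tables plus the ground-truth JSON."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix.values.to_csv(outdir / "expression.tsv", sep="\t", index_label="probe_id")
    clinical.to_csv(outdir / "clinical.tsv", sep="\t", index=False)
    qc.to_csv(outdir / "qc.tsv", sep="\t", index=False)
    probe_map.to_csv(outdir / "probe_map.tsv", sep="\t", index=False)
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(asdict(truth), fh, indent=1, default=list)
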