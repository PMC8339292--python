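"""Survival statistics: Kaplan-Meier curves, binary-covariate Cox fits,
best-cutoff scanning and transcriptome-wide FDR.

The central estimand is the hazard ratio between "high" and "low" expression
of a gene, where the dichotomizing threshold is not fixed a priori: every
distinct observed expression value between the first and third quartiles is
evaluated as a candidate cutoff, and the cutoff with the smallest score-test
(log-rank) p-value is reported. Exact p ties are broken by the strongest
absolute hazard ratio, then by the smallest cutoff.

The Cox partial likelihood for a single binary covariate is maximized by
Newton-Raphson with step-halving (Efron tie handling by default; Breslow
available). The p-value attached to a fit is, by default, the score test at
beta = 0, which for a binary covariate is the classical log-rank test; a
Wald test is available via ``test="wald"``.

Because the reported per-gene p-value is a minimum over many correlated
tests, it is anti-conservative; the Benjamini-Hochberg correction applied
across genes inherits that optimism. This mirrors the published screening
procedure and is deliberately not "corrected" here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix

__all__ = [
    "SurvivalData",
    "CoxFit",
    "ScanResult",
    "TranscriptomeScan",
    "KMCurve",
    "km_curve",
    "cox_binary",
    "scan_gene",
    "scan_transcriptome",
    "bh_fdr",
]

MAX_NEWTON_ITER = 50
NEWTON_TOL = 1e-8


@dataclass(frozen=True)
class SurvivalData:
    """Right-censored follow-up: time in months, event flag (1 = relapse)."""

    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        event = np.asarray(self.event, dtype=int)
        if time.ndim != 1 or event.shape != time.shape:
            raise ValueError("time and event must be 1-D arrays of equal length")
        if time.size == 0:
            raise ValueError("survival data is empty")
        if not np.isfinite(time).all() or (time <= 0).any():
            raise ValueError("survival times must be positive and finite")
        if not np.isin(event, (0, 1)).all():
            raise ValueError("event flags must be 0 or 1")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "event", event)

    @property
    def n(self) -> int:
        return self.time.size

    @property
    def n_events(self) -> int:
        return int(self.event.sum())


@dataclass(frozen=True)
class CoxFit:
    """Single binary covariate Cox fit (covariate 1 = high expression)."""

    log_hr: float
    hr: float
    se_beta: float
    p_value: float
    ci_low: float
    ci_high: float
    n_high: int
    n_low: int
    n_events: int
    estimable: bool = True

    @property
    def absolute_hr(self) -> float:
        return max(self.hr, 1.0 / self.hr)


@dataclass(frozen=True)
class ScanResult:
    """Best-cutoff result for one probe (one row of the ranked output)."""

    probe_id: str
    gene_symbol: Optional[str]
    best_cutoff: float
    fit: CoxFit
    max_expression: float
    fdr_q: Optional[float] = None


@dataclass(frozen=True)
class TranscriptomeScan:
    """All per-probe scan results plus the probes that could not be scanned."""

    results: list
    unscannable: list


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival curve evaluated at the observed event times."""

    event_times: np.ndarray
    survival_probability: np.ndarray
    at_risk: np.ndarray


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def km_curve(data: SurvivalData) -> KMCurve:
    """Kaplan-Meier product-limit estimate S(t) at each distinct event time.

    The curve starts at S=1 and drops only at event times; censoring between
    event times reduces the at-risk count without a drop.
    """
    kmf = KaplanMeierFitter()
    kmf.fit(data.time, event_observed=data.event)
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    event_times = ev.index.to_numpy(dtype=float)
    surv = kmf.survival_function_["KM_estimate"]
    survival = np.array([float(surv.loc[t]) for t in event_times])
    at_risk = ev["at_risk"].to_numpy(dtype=int)
    return KMCurve(event_times=event_times, survival_probability=survival, at_risk=at_risk)


# ---------------------------------------------------------------------------
# Cox partial likelihood for a binary covariate
# ---------------------------------------------------------------------------

def _sorted_structure(time: np.ndarray, event: np.ndarray):
    """Sort by time; locate distinct event times, tie counts and risk sets."""
    order = np.argsort(time, kind="stable")
    t = time[order]
    e = event[order]
    ev_mask = e == 1
    te = t[ev_mask]
    uniq, start_in_ev, dk = np.unique(te, return_index=True, return_counts=True)
    start_at_risk = np.searchsorted(t, uniq, side="left")
    nk = t.size - start_at_risk
    return order, ev_mask, start_in_ev, start_at_risk, dk, nk


def _logrank_grid(sorted_event_mask, start_in_ev, start_at_risk, dk, nk, Z):
    """Score (log-rank) statistic for each column of group matrix ``Z``.

    ``Z`` holds 0/1 group indicators for the time-sorted samples, one column
    per candidate dichotomization. Returns (p, d1_total, estimable_mask).
    The variance uses the hypergeometric (classical log-rank) form; risk sets
    of size 1 contribute zero variance.
    """
    dk = dk.astype(float)
    nkf = nk.astype(float)
    # suffix sums over time-sorted rows -> group-at-risk counts per event time
    suffix = np.cumsum(Z[::-1], axis=0)[::-1]
    n1 = suffix[start_at_risk]  # (K, C)
    Ze = Z[sorted_event_mask]
    d1 = np.add.reduceat(Ze, start_in_ev, axis=0)  # (K, C)
    frac = n1 / nkf[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.where(nk > 1, (nkf - dk) / (nkf - 1.0), 0.0)

    def _colsum(a):
        # Sum over event times with a reduction order that does not depend on
        # the number of columns, so a one-column call reproduces the grid
        # bitwise (numpy's pairwise summation blocks differently otherwise).
        return np.ascontiguousarray(a.T).sum(axis=1)

    U = _colsum(d1 - dk[:, None] * frac)
    V = _colsum(dk[:, None] * frac * (1.0 - frac) * corr[:, None])
    d1_total = _colsum(d1)
    d_total = float(dk.sum())
    estimable = (V > 0) & (d1_total > 0) & (d1_total < d_total)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(V > 0, (U * U) / np.where(V > 0, V, 1.0), np.nan)
    p = stats.chi2.sf(chi2, df=1)
    return p, d1_total, estimable


def _efron_loglik_terms(beta: float, r1, rk, d1, dk, tie_frac, tie_mask):
    """Efron partial log-likelihood, gradient and negative curvature.

    ``tie_frac``/``tie_mask`` encode l/d for l = 0..d-1 per event time
    (Breslow is the special case tie_frac = 0).
    """
    eb = math.exp(beta)
    R = (rk - r1) + r1 * eb          # risk-set weight sum, (K,)
    Rp = r1 * eb                     # d/dbeta
    D = (dk - d1) + d1 * eb          # tied-death weight sum
    Dp = d1 * eb
    phi = R[:, None] - tie_frac * D[:, None]
    phip = Rp[:, None] - tie_frac * Dp[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(tie_mask, phip / phi, 0.0)
        logphi = np.where(tie_mask, np.log(np.where(tie_mask, phi, 1.0)), 0.0)
    loglik = float((d1 * beta).sum() - logphi.sum())
    grad = float(d1.sum() - a.sum())
    neg_curv = float((a * (1.0 - a)).sum())  # -l''(beta) >= 0
    return loglik, grad, neg_curv


def _fit_binary_cox(time, event, group, ties: str = "efron"):
    """Newton-Raphson fit; returns (beta, se, converged)."""
    order, ev_mask, start_in_ev, start_at_risk, dk, nk = _sorted_structure(time, event)
    z = group[order].astype(float)
    suffix = np.cumsum(z[::-1])[::-1]
    r1 = suffix[start_at_risk]
    d1 = np.add.reduceat(z[ev_mask], start_in_ev)
    rk = nk.astype(float)
    dkf = dk.astype(float)

    dmax = int(dk.max())
    ls = np.arange(dmax, dtype=float)
    tie_mask = ls[None, :] < dkf[:, None]
    if ties == "efron":
        with np.errstate(divide="ignore"):
            tie_frac = np.where(tie_mask, ls[None, :] / dkf[:, None], 0.0)
    elif ties == "breslow":
        tie_frac = np.zeros_like(tie_mask, dtype=float)
    else:
        raise ValueError(f"unknown tie method {ties!r}")

    beta = 0.0
    loglik, grad, neg_curv = _efron_loglik_terms(beta, r1, rk, d1, dkf, tie_frac, tie_mask)
    converged = False
    for _ in range(MAX_NEWTON_ITER):
        if neg_curv <= 0:
            break
        step = grad / neg_curv
        # step-halving to guarantee ascent
        for _half in range(30):
            new_beta = beta + step
            new = _efron_loglik_terms(new_beta, r1, rk, d1, dkf, tie_frac, tie_mask)
            if np.isfinite(new[0]) and new[0] >= loglik - 1e-12:
                break
            step *= 0.5
        delta = new_beta - beta
        beta = new_beta
        loglik, grad, neg_curv = new
        if abs(beta) > 50:
            # effectively monotone likelihood: the maximizer runs away
            return beta, float("nan"), False
        if abs(delta) < NEWTON_TOL:
            converged = True
            break
    se = 1.0 / math.sqrt(neg_curv) if neg_curv > 0 else float("nan")
    return beta, se, converged and np.isfinite(se)


def _score_p(time, event, group):
    """Score-test (log-rank) p-value via the same path as the cutoff scan."""
    order, ev_mask, start_in_ev, start_at_risk, dk, nk = _sorted_structure(time, event)
    Z = group[order].astype(float)[:, None]
    p, d1_total, estimable = _logrank_grid(ev_mask, start_in_ev, start_at_risk, dk, nk, Z)
    return float(p[0]), int(d1_total[0]), bool(estimable[0])


def _non_estimable(n_high: int, n_low: int, n_events: int) -> CoxFit:
    nan = float("nan")
    return CoxFit(nan, nan, nan, nan, nan, nan, n_high, n_low, n_events, estimable=False)


def cox_binary(
    data: SurvivalData,
    group,
    ties: str = "efron",
    test: str = "score",
) -> CoxFit:
    """Cox proportional-hazards fit for one binary covariate (1 = high).

    ``beta`` maximizes the partial likelihood (Efron tie correction by
    default); the standard error comes from the observed information. The
    reported ``p_value`` is the score test at beta = 0 — the log-rank test —
    unless ``test="wald"``.

    Monotone-likelihood data (all events in one group) are returned with
    ``estimable=False`` and NaN estimates, as are non-converged fits.
    """
    group = np.asarray(group, dtype=bool)
    if group.shape != data.time.shape:
        raise ValueError("group indicator must align with survival data")
    n_high = int(group.sum())
    n_low = int((~group).sum())
    if n_high == 0 or n_low == 0:
        raise ValueError("both groups must be non-empty")
    if data.n_events == 0:
        raise ValueError("at least one event is required")
    if test not in ("score", "wald"):
        raise ValueError(f"unknown test {test!r}")

    score_p, d_high, score_ok = _score_p(data.time, data.event, group)
    if not score_ok or d_high == 0 or d_high == data.n_events:
        return _non_estimable(n_high, n_low, data.n_events)

    beta, se, converged = _fit_binary_cox(data.time, data.event, group, ties=ties)
    if not converged:
        return _non_estimable(n_high, n_low, data.n_events)
    if test == "score":
        p = score_p
    else:
        p = 2.0 * stats.norm.sf(abs(beta) / se)
    p = max(p, np.nextafter(0, 1))  # keep within (0, 1]
    zcrit = stats.norm.ppf(0.975)
    with np.errstate(over="ignore"):
        ci = (float(np.exp(beta - zcrit * se)), float(np.exp(beta + zcrit * se)))
    return CoxFit(
        log_hr=beta,
        hr=math.exp(beta),
        se_beta=se,
        p_value=p,
        ci_low=ci[0],  # huge SE can under/overflow to 0/inf; harmless in reports
        ci_high=ci[1],
        n_high=n_high,
        n_low=n_low,
        n_events=data.n_events,
    )


# ---------------------------------------------------------------------------
# Best-cutoff scan
# ---------------------------------------------------------------------------

def _candidate_cutoffs(expression: np.ndarray) -> np.ndarray:
    """Distinct observed values c with Q1 <= c < Q3 (linear-interp quartiles)."""
    q1, q3 = np.percentile(expression, [25, 75])
    uniq = np.unique(expression)
    return uniq[(uniq >= q1) & (uniq < q3)]


def scan_gene(
    expression,
    data: SurvivalData,
    ties: str = "efron",
    test: str = "score",
    probe_id: str = "",
    gene_symbol: Optional[str] = None,
) -> Optional[ScanResult]:
    """Best-cutoff survival scan for one gene.

    Every distinct observed expression value in [Q1, Q3) is a candidate
    cutoff; samples strictly above the cutoff form the high group. The
    candidate with the smallest score-test p-value is selected; exact p ties
    are broken by the largest absolute hazard ratio, then the smallest
    cutoff. The returned fit is the full Cox fit at the selected cutoff.

    Returns ``None`` when the gene is unscannable: fewer than two distinct
    interquartile values, or no candidate with an estimable fit.
    """
    expression = np.asarray(expression, dtype=float)
    if expression.shape != data.time.shape:
        raise ValueError("expression must align with survival data")
    if data.n < 8:
        raise ValueError("best-cutoff scan requires at least 8 samples")
    cutoffs = _candidate_cutoffs(expression)
    if cutoffs.size < 2:
        return None

    order, ev_mask, start_in_ev, start_at_risk, dk, nk = _sorted_structure(
        data.time, data.event
    )
    x_sorted = expression[order]
    Z = (x_sorted[:, None] > cutoffs[None, :]).astype(float)
    p, d1_total, estimable = _logrank_grid(
        ev_mask, start_in_ev, start_at_risk, dk, nk, Z
    )
    if not estimable.any():
        return None
    p_valid = np.where(estimable, p, np.inf)
    best_p = p_valid.min()
    tied = np.flatnonzero(p_valid == best_p)  # ascending cutoff order

    best = None
    best_cutoff = None
    for idx in tied:
        fit = cox_binary(data, expression > cutoffs[idx], ties=ties, test=test)
        if not fit.estimable:
            continue
        if best is None or fit.absolute_hr > best.absolute_hr:
            best = fit
            best_cutoff = float(cutoffs[idx])
        # equal |HR|: keep the earlier (smaller) cutoff
    if best is None:
        return None
    return ScanResult(
        probe_id=probe_id,
        gene_symbol=gene_symbol,
        best_cutoff=best_cutoff,
        fit=best,
        max_expression=float(expression.max()),
    )


def _median_split_result(expression, data, ties, test, probe_id, gene_symbol):
    """Fixed median-cutoff fit (used for null-calibration analyses)."""
    expression = np.asarray(expression, dtype=float)
    cutoff = float(np.median(expression))
    group = expression > cutoff
    if group.sum() == 0 or (~group).sum() == 0:
        return None
    fit = cox_binary(data, group, ties=ties, test=test)
    if not fit.estimable:
        return None
    return ScanResult(
        probe_id=probe_id,
        gene_symbol=gene_symbol,
        best_cutoff=cutoff,
        fit=fit,
        max_expression=float(expression.max()),
    )


def scan_transcriptome(
    matrix: ExpressionMatrix,
    survival: pd.DataFrame,
    probe_map: pd.DataFrame,
    ties: str = "efron",
    test: str = "score",
    cutoff_mode: str = "scan",
) -> TranscriptomeScan:
    """Run the per-gene scan over every gene-mapped probe and attach BH q-values.

    ``survival`` is a DataFrame indexed by sample id with columns
    ``rfs_months`` and ``rfs_event``; it must cover exactly the samples of
    the matrix. Probes without a gene symbol in ``probe_map`` are excluded
    before any testing, so they never enter the FDR computation. Unscannable
    probes are reported separately and excluded from the FDR vector.

    ``cutoff_mode="median"`` replaces the interquartile scan by a fixed
    median split per gene (the calibrated base test, useful for null
    analyses).
    """
    sample_ids = matrix.sample_ids
    missing = [s for s in sample_ids if s not in survival.index]
    if missing or len(survival.index) != len(sample_ids):
        raise ValueError("survival table does not match matrix samples")
    surv = survival.loc[sample_ids]
    data = SurvivalData(
        time=surv["rfs_months"].to_numpy(dtype=float),
        event=surv["rfs_event"].to_numpy(dtype=int),
    )

    gene_of = dict(
        zip(probe_map["probe_id"], probe_map["gene_symbol"])
    )
    values = matrix.values.to_numpy()
    results = []
    unscannable = []
    for i, probe in enumerate(matrix.probe_ids):
        gene = gene_of.get(probe)
        if gene is None or (isinstance(gene, float) and np.isnan(gene)) or gene == "":
            continue
        x = values[i]
        if cutoff_mode == "median":
            res = _median_split_result(x, data, ties, test, probe, gene)
        elif cutoff_mode == "scan":
            res = scan_gene(x, data, ties=ties, test=test, probe_id=probe, gene_symbol=gene)
        else:
            raise ValueError(f"unknown cutoff mode {cutoff_mode!r}")
        if res is None:
            unscannable.append(probe)
        else:
            results.append(res)

    if results:
        q = bh_fdr([r.fit.p_value for r in results])
        results = [replace(r, fdr_q=float(qi)) for r, qi in zip(results, q)]
    return TranscriptomeScan(results=results, unscannable=unscannable)


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, original order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p <= 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
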