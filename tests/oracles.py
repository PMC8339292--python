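"""Independent reference implementations used only to check the package.

Everything here is written in the most transparent way possible (plain
loops, textbook formulas, scipy scalar optimization) and never shares code
with the package internals.
"""

import numpy as np
from scipy.optimize import minimize_scalar


def efron_partial_loglik(beta, time, event, group, ties="efron"):
    """Cox partial log-likelihood for a binary covariate, written out naively.

    ``ties="breslow"`` drops the tied-death adjustment term.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    x = np.asarray(group, int)
    n = len(time)
    ll = 0.0
    for t in sorted(set(time[event == 1])):
        deaths = [i for i in range(n) if time[i] == t and event[i] == 1]
        at_risk = [i for i in range(n) if time[i] >= t]
        d = len(deaths)
        ll += beta * sum(x[i] for i in deaths)
        sum_risk = sum(np.exp(beta * x[i]) for i in at_risk)
        sum_death = sum(np.exp(beta * x[i]) for i in deaths)
        for l in range(d):
            adjust = (l / d) * sum_death if ties == "efron" else 0.0
            ll -= np.log(sum_risk - adjust)
    return ll


def grid_max_beta(time, event, group, lo=-5.0, hi=5.0, ties="efron"):
    """Maximize the written-out partial likelihood over beta in (lo, hi)."""
    res = minimize_scalar(
        lambda b: -efron_partial_loglik(b, time, event, group, ties=ties),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


def brute_force_scan(expression, data, cox_binary):
    """Exhaustive re-evaluation of the interquartile cutoff scan.

    Selection rule: smallest p, then largest absolute HR, then smallest
    cutoff; cutoffs whose fit is non-estimable are skipped. Returns
    (cutoff, fit) or None.
    """
    x = np.asarray(expression, float)
    q1, q3 = np.percentile(x, [25, 75])
    candidates = [c for c in np.unique(x) if q1 <= c < q3]
    best_key, best = None, None
    for c in candidates:
        fit = cox_binary(data, x > c)
        if not fit.estimable:
            continue
        key = (fit.p_value, -fit.absolute_hr, c)
        if best_key is None or key < best_key:
            best_key, best = key, (float(c), fit)
    return best


def step_up_bh(p_values):
    """Textbook Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running_min = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, m * p[i] / rank)
        q[i] = min(running_min, 1.0)
    return q


def product_limit(time, event):
    """Hand-evaluated Kaplan-Meier estimate at each distinct event time."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    s = 1.0
    curve = []
    for t in sorted(set(time[event == 1])):
        at_risk = int((time >= t).sum())
        deaths = int(((time == t) & (event == 1)).sum())
        s *= 1.0 - deaths / at_risk
        curve.append((t, s, at_risk))
    return curve
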