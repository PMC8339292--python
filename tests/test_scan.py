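import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test

from kmscan import (
    SimulationConfig,
    SurvivalData,
    bh_fdr,
    cox_binary,
    km_curve,
    scan_gene,
    scan_transcriptome,
    simulate_survival,
)

from conftest import make_matrix, random_survival
from oracles import brute_force_scan, grid_max_beta, product_limit, step_up_bh


def random_dataset(rng, n, with_ties=False):
    """Random survival + binary group with events in both groups."""
    while True:
        time = rng.exponential(30.0, size=n)
        if with_ties:
            time = np.ceil(time)  # force tied event times
        time = np.maximum(time, 0.5)
        event = (rng.uniform(size=n) < 0.75).astype(int)
        group = rng.uniform(size=n) < 0.5
        d_high = event[group].sum()
        if 0 < d_high < event.sum() and group.any() and (~group).any():
            return SurvivalData(time=time, event=event), group


# -- Kaplan-Meier ------------------------------------------------------------

def test_km_no_events_flat_at_one():
    curve = km_curve(SurvivalData(time=[3.0, 5.0, 8.0], event=[0, 0, 0]))
    assert curve.event_times.size == 0  # no drops: S(t) = 1 everywhere


def test_km_three_subject_closed_form():
    curve = km_curve(SurvivalData(time=[1.0, 2.0, 3.0], event=[0, 1, 1]))
    np.testing.assert_array_equal(curve.event_times, [2.0, 3.0])
    np.testing.assert_array_equal(curve.survival_probability, [0.5, 0.0])
    np.testing.assert_array_equal(curve.at_risk, [2, 1])


def test_km_invariant_under_subject_duplication():
    rng = np.random.default_rng(0)
    data = random_survival(rng, 40)
    doubled = SurvivalData(
        time=np.repeat(data.time, 2), event=np.repeat(data.event, 2)
    )
    a, b = km_curve(data), km_curve(doubled)
    np.testing.assert_array_equal(a.event_times, b.event_times)
    np.testing.assert_allclose(a.survival_probability, b.survival_probability)


def test_km_matches_hand_product_limit():
    rng = np.random.default_rng(1)
    data = random_survival(rng, 25)
    curve = km_curve(data)
    expected = product_limit(data.time, data.event)
    np.testing.assert_allclose(curve.event_times, [t for t, _, _ in expected])
    np.testing.assert_allclose(curve.survival_probability, [s for _, s, _ in expected])
    np.testing.assert_array_equal(curve.at_risk, [n for _, _, n in expected])
    assert (np.diff(curve.survival_probability) <= 0).all()


def test_km_empty_input_rejected():
    with pytest.raises(ValueError):
        SurvivalData(time=[], event=[])


# -- Cox binary fit ----------------------------------------------------------

def test_identical_groups_give_null_fit():
    time = np.array([1.0, 1.0, 2.0, 2.0, 3.0, 3.0, 4.0, 4.0])
    event = np.array([1, 1, 1, 1, 0, 0, 1, 1])
    group = np.array([0, 1, 0, 1, 0, 1, 0, 1], dtype=bool)
    fit = cox_binary(SurvivalData(time=time, event=event), group)
    assert fit.log_hr == pytest.approx(0.0, abs=1e-10)
    assert fit.hr == pytest.approx(1.0, abs=1e-10)
    assert fit.p_value == pytest.approx(1.0)


def test_eight_subject_beta_matches_grid_search():
    time = np.array([2.0, 3.5, 5.0, 6.25, 8.0, 9.5, 11.0, 13.0])
    event = np.array([1, 1, 0, 1, 1, 1, 0, 1])
    group = np.array([1, 0, 1, 1, 0, 0, 1, 0], dtype=bool)
    fit = cox_binary(SurvivalData(time=time, event=event), group)
    beta_oracle = grid_max_beta(time, event, group)
    assert fit.log_hr == pytest.approx(beta_oracle, abs=1e-4)


@pytest.mark.parametrize("with_ties", [False, True])
def test_beta_and_se_match_lifelines(with_ties):
    rng = np.random.default_rng(2)
    for _ in range(5):
        data, group = random_dataset(rng, 60, with_ties=with_ties)
        fit = cox_binary(data, group)
        df = pd.DataFrame({"t": data.time, "e": data.event, "x": group.astype(int)})
        cph = CoxPHFitter()
        cph.fit(df, duration_col="t", event_col="e")
        assert fit.log_hr == pytest.approx(cph.params_["x"], rel=1e-5, abs=1e-6)
        assert fit.se_beta == pytest.approx(cph.standard_errors_["x"], rel=1e-5)


def test_score_p_matches_lifelines_logrank():
    rng = np.random.default_rng(3)
    for _ in range(5):
        data, group = random_dataset(rng, 50, with_ties=rng.uniform() < 0.5)
        fit = cox_binary(data, group)
        lr = logrank_test(
            data.time[group], data.time[~group],
            event_observed_A=data.event[group], event_observed_B=data.event[~group],
        )
        assert fit.p_value == pytest.approx(lr.p_value, rel=1e-9)


def test_breslow_ties_matches_grid_oracle():
    rng = np.random.default_rng(4)
    data, group = random_dataset(rng, 60, with_ties=True)
    fit = cox_binary(data, group, ties="breslow")
    beta_oracle = grid_max_beta(data.time, data.event, group, ties="breslow")
    assert fit.log_hr == pytest.approx(beta_oracle, abs=1e-4)
    assert fit.log_hr != cox_binary(data, group, ties="efron").log_hr


def test_wald_test_option():
    rng = np.random.default_rng(5)
    data, group = random_dataset(rng, 60)
    fit = cox_binary(data, group, test="wald")
    from scipy import stats

    expected = 2 * stats.norm.sf(abs(fit.log_hr) / fit.se_beta)
    assert fit.p_value == pytest.approx(expected)


def test_group_swap_flips_beta_and_preserves_p():
    rng = np.random.default_rng(6)
    data, group = random_dataset(rng, 45)
    a = cox_binary(data, group)
    b = cox_binary(data, ~group)
    assert a.log_hr == pytest.approx(-b.log_hr, abs=1e-7)
    assert a.p_value == pytest.approx(b.p_value, rel=1e-12)
    assert a.n_high == b.n_low


def test_all_events_in_one_group_non_estimable():
    time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    event = np.array([1, 1, 1, 0, 0, 0])
    group = np.array([1, 1, 1, 0, 0, 0], dtype=bool)
    fit = cox_binary(SurvivalData(time=time, event=event), group)
    assert not fit.estimable
    assert math.isnan(fit.log_hr)


def test_degenerate_inputs_rejected():
    data = SurvivalData(time=[1.0, 2.0], event=[1, 1])
    with pytest.raises(ValueError):
        cox_binary(data, np.array([True, True]))
    with pytest.raises(ValueError):
        cox_binary(SurvivalData(time=[1.0, 2.0], event=[0, 0]), np.array([True, False]))


def test_large_sample_consistency_true_hr_2():
    config = SimulationConfig(censoring_fraction_target=0.2)
    rng = np.random.default_rng(7)
    group = rng.uniform(size=4000) < 0.5
    time, event = simulate_survival(math.log(2.0) * group, config, rng)
    fit = cox_binary(SurvivalData(time=time, event=event), group)
    assert 1.8 < fit.hr < 2.2


# -- best-cutoff scan --------------------------------------------------------

def test_constant_expression_unscannable():
    rng = np.random.default_rng(8)
    data = random_survival(rng, 30)
    assert scan_gene(np.full(30, 7.0), data) is None


def test_scan_equals_brute_force_rescan():
    rng = np.random.default_rng(9)
    for _ in range(10):
        n = int(rng.integers(20, 60))
        data, _ = random_dataset(rng, n, with_ties=rng.uniform() < 0.3)
        x = rng.lognormal(6, 1, size=n)
        res = scan_gene(x, data)
        oracle = brute_force_scan(x, data, cox_binary)
        assert (res is None) == (oracle is None)
        if res is not None:
            cutoff, fit = oracle
            assert res.best_cutoff == cutoff
            assert res.fit.p_value == fit.p_value
            assert res.fit.hr == fit.hr


def test_grid_p_values_bitwise_equal_scalar_path():
    """The vectorized multi-cutoff score test and the per-fit scalar path
    must agree bitwise, otherwise scan selection could diverge from
    re-evaluation."""
    from kmscan.scan import _candidate_cutoffs, _logrank_grid, _sorted_structure

    rng = np.random.default_rng(10)
    data, _ = random_dataset(rng, 80, with_ties=True)
    x = rng.lognormal(6, 1, size=80)
    cutoffs = _candidate_cutoffs(x)
    order, ev_mask, start_in_ev, start_at_risk, dk, nk = _sorted_structure(
        data.time, data.event
    )
    Z = (x[order][:, None] > cutoffs[None, :]).astype(float)
    p_grid, _, est = _logrank_grid(ev_mask, start_in_ev, start_at_risk, dk, nk, Z)
    for j, c in enumerate(cutoffs):
        if not est[j]:
            continue
        fit = cox_binary(data, x > c)
        assert fit.p_value == p_grid[j]


def test_expression_inversion_gives_reciprocal_hr():
    rng = np.random.default_rng(11)
    hits = 0
    for _ in range(5):
        data, _ = random_dataset(rng, 50)
        x = rng.lognormal(6, 1, size=50)
        res = scan_gene(x, data)
        res_inv = scan_gene(x.max() - x, data)
        assert res is not None and res_inv is not None
        assert res_inv.fit.p_value == pytest.approx(res.fit.p_value, rel=1e-9)
        assert res_inv.fit.hr == pytest.approx(1.0 / res.fit.hr, rel=1e-6)
        hits += 1
    assert hits == 5


def test_interquartile_constraint_on_selected_cutoff():
    rng = np.random.default_rng(12)
    data, _ = random_dataset(rng, 60)
    x = rng.lognormal(6, 1, size=60)
    res = scan_gene(x, data)
    q1, q3 = np.percentile(x, [25, 75])
    assert q1 <= res.best_cutoff < q3
    n = data.n
    assert min(res.fit.n_high, res.fit.n_low) >= math.ceil(0.25 * n) - 1


def test_planted_step_effect_found_near_true_cutoff():
    """A step effect at the median is located within the central 20% of the
    expression distribution in >=90% of replicates (n=400, |log HR|=log 3)."""
    config = SimulationConfig(censoring_fraction_target=0.2)
    hits = 0
    n_rep = 100
    for seed in range(n_rep):
        rng = np.random.default_rng(2000 + seed)
        x = rng.lognormal(6, 0.8, size=400)
        group = x > np.median(x)
        time, event = simulate_survival(math.log(3.0) * group, config, rng)
        res = scan_gene(x, SurvivalData(time=time, event=event))
        p40, p60 = np.percentile(x, [40, 60])
        if p40 <= res.best_cutoff <= p60:
            hits += 1
    assert hits >= 0.9 * n_rep


# -- transcriptome scan ------------------------------------------------------

def _survival_frame(data, sample_ids):
    return pd.DataFrame(
        {"rfs_months": data.time, "rfs_event": data.event}, index=sample_ids
    )


def test_single_probe_q_equals_p():
    rng = np.random.default_rng(13)
    data, _ = random_dataset(rng, 40)
    x = rng.lognormal(6, 1, size=40)
    matrix = make_matrix(x[None, :], probe_ids=["P0"])
    pm = pd.DataFrame({"probe_id": ["P0"], "gene_symbol": ["G0"], "is_best_probe": [True]})
    scan = scan_transcriptome(matrix, _survival_frame(data, matrix.sample_ids), pm)
    assert len(scan.results) == 1
    assert scan.results[0].fdr_q == scan.results[0].fit.p_value


def test_unmapped_probes_excluded_before_fdr():
    rng = np.random.default_rng(14)
    data, _ = random_dataset(rng, 40)
    x = rng.lognormal(6, 1, size=(3, 40))
    matrix = make_matrix(x, probe_ids=["P0", "P1", "P2"])
    pm = pd.DataFrame(
        {
            "probe_id": ["P0", "P1", "P2"],
            "gene_symbol": ["G0", None, None],
            "is_best_probe": [True, False, False],
        }
    )
    scan = scan_transcriptome(matrix, _survival_frame(data, matrix.sample_ids), pm)
    assert [r.probe_id for r in scan.results] == ["P0"]
    assert scan.results[0].fdr_q == scan.results[0].fit.p_value  # m=1, not 3


def test_sample_mismatch_rejected():
    rng = np.random.default_rng(15)
    data, _ = random_dataset(rng, 10)
    matrix = make_matrix(rng.lognormal(6, 1, size=(2, 10)))
    surv = _survival_frame(data, [f"X{i}" for i in range(10)])
    pm = pd.DataFrame({"probe_id": ["P0"], "gene_symbol": ["G0"], "is_best_probe": [True]})
    with pytest.raises(ValueError):
        scan_transcriptome(matrix, surv, pm)


def test_constant_probe_reported_unscannable():
    rng = np.random.default_rng(16)
    data, _ = random_dataset(rng, 30)
    vals = np.vstack([rng.lognormal(6, 1, size=30), np.full(30, 3.0)])
    matrix = make_matrix(vals, probe_ids=["P0", "P1"])
    pm = pd.DataFrame(
        {"probe_id": ["P0", "P1"], "gene_symbol": ["G0", "G1"], "is_best_probe": [True, True]}
    )
    scan = scan_transcriptome(matrix, _survival_frame(data, matrix.sample_ids), pm)
    assert scan.unscannable == ["P1"]


def test_median_mode_uses_fixed_cutoff():
    rng = np.random.default_rng(17)
    data, _ = random_dataset(rng, 40)
    x = rng.lognormal(6, 1, size=(2, 40))
    matrix = make_matrix(x, probe_ids=["P0", "P1"])
    pm = pd.DataFrame(
        {"probe_id": ["P0", "P1"], "gene_symbol": ["G0", "G1"], "is_best_probe": [True, True]}
    )
    scan = scan_transcriptome(
        matrix, _survival_frame(data, matrix.sample_ids), pm, cutoff_mode="median"
    )
    for r, row in zip(scan.results, x):
        assert r.best_cutoff == np.median(row)
        expected = cox_binary(data, row > np.median(row))
        assert r.fit.p_value == expected.p_value


# -- BH FDR ------------------------------------------------------------------

def test_bh_worked_example():
    q = bh_fdr([0.01, 0.02, 0.03, 0.04, 0.05])
    np.testing.assert_allclose(q, 0.05, rtol=0, atol=1e-12)


def test_bh_single_p_is_identity():
    assert bh_fdr([0.037])[0] == 0.037


def test_bh_equal_ps_unchanged():
    np.testing.assert_allclose(bh_fdr([0.2] * 7), 0.2, atol=1e-12)


@pytest.mark.parametrize("bad", [[0.0], [-0.1], [1.5], [float("nan")]])
def test_bh_rejects_out_of_range(bad):
    with pytest.raises(ValueError):
        bh_fdr(bad)


@settings(max_examples=50, deadline=None)
@given(
    st.lists(
        st.floats(min_value=1e-12, max_value=1.0, allow_nan=False), min_size=1, max_size=30
    )
)
def test_bh_matches_step_up_oracle_and_is_monotone(ps):
    q = bh_fdr(ps)
    np.testing.assert_allclose(q, step_up_bh(ps), rtol=1e-12)
    order = np.argsort(ps, kind="stable")
    assert (np.diff(np.asarray(q)[order]) >= -1e-15).all()
    # thresholding at alpha selects the classical step-up set
    for alpha in (0.05, 0.2):
        m = len(ps)
        sorted_p = np.sort(ps)
        k = 0
        for i, p in enumerate(sorted_p, start=1):
            if p <= alpha * i / m:
                k = i
        classical = set(np.flatnonzero(np.asarray(ps) <= (sorted_p[k - 1] if k else -1)))
        assert set(np.flatnonzero(np.asarray(q) <= alpha)) == classical
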