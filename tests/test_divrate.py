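"""Gamma/MCCR, diversification model battery, shift and cladogenesis tests."""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import norm

from museumdiv.divrate import (delta_aic_rc, fit_all_models, fit_bd,
                               fit_ddl, fit_ddx, fit_pure_birth,
                               fit_yule2rate, fit_yule3rate, gamma_stat,
                               mccr_test, ms_netdiv, rc_tail_probability,
                               rel_cladogenesis_test, shift_at_time_test,
                               yule_branching_times)
from museumdiv.phylo import BranchingTimes, TreeError, branching_times, parse_tree, as_chronogram
from museumdiv.simulate import sim_yule

COMB_BT = BranchingTimes(4, np.array([3.0, 2.0, 1.0]))


# ---------------------------------------------------------------------------
# gamma


def test_gamma_comb_direct_formula():
    """g = (1,1,1): T = 9, interior means (2+5)/2 = 3.5, so
    gamma = (3.5 - 4.5) / (9 sqrt(1/24))."""
    res = gamma_stat(COMB_BT)
    expected = (3.5 - 4.5) / (9.0 * math.sqrt(1.0 / 24.0))
    assert res.gamma == pytest.approx(expected, abs=1e-12)
    assert res.p_one_tailed == pytest.approx(norm.cdf(expected), abs=1e-12)


def test_gamma_uniform_weighted_tree_is_exactly_zero():
    """g_k = 1/k makes every k g_k = 1; gamma vanishes identically."""
    n = 12
    g = 1.0 / np.arange(2, n + 1)
    ages = np.cumsum(g[::-1])[::-1]
    res = gamma_stat(BranchingTimes(n, ages))
    assert res.gamma == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("scale", [1e-3, 7.7, 1e4])
def test_gamma_invariant_to_age_rescaling(scale):
    base = gamma_stat(COMB_BT).gamma
    scaled = gamma_stat(BranchingTimes(4, COMB_BT.ages * scale)).gamma
    assert scaled == pytest.approx(base, rel=1e-12)


def test_gamma_null_moments_on_pure_birth():
    rng = np.random.default_rng(99)
    gs = [gamma_stat(BranchingTimes(50, yule_branching_times(50, 1.0, rng))).gamma
          for _ in range(1000)]
    assert abs(np.mean(gs)) < 0.1
    assert np.var(gs) == pytest.approx(1.0, rel=0.15)


# ---------------------------------------------------------------------------
# MCCR


def test_mccr_deterministic_under_seed():
    a = mccr_test(-0.5, 20, 12, replicates=300, seed=7)
    b = mccr_test(-0.5, 20, 12, replicates=300, seed=7)
    assert a.critical_value == b.critical_value
    assert np.array_equal(a.null_gammas, b.null_gammas)
    assert a.p_value == b.p_value


def test_mccr_critical_value_decreases_with_missing_fraction():
    crits = [mccr_test(None, total, 30, replicates=2000, seed=1).critical_value
             for total in (30, 38, 47)]
    assert crits[0] > crits[1] > crits[2]
    assert crits[0] == pytest.approx(-1.645, abs=0.12)


def test_mccr_input_validation():
    with pytest.raises(TreeError):
        mccr_test(0.0, 10, 2)
    with pytest.raises(TreeError):
        mccr_test(0.0, 10, 12)


# ---------------------------------------------------------------------------
# rate-constant / rate-variable fits


def test_pure_birth_closed_form_on_comb():
    fit = fit_pure_birth(COMB_BT)
    assert fit.params["lambda"] == pytest.approx(2.0 / 9.0)
    assert fit.lnl == pytest.approx(2.0 * math.log(2.0 / 9.0) - 2.0, abs=1e-12)
    assert fit.aic == pytest.approx(-2.0 * fit.lnl + 2.0)


def test_bd_nests_pure_birth():
    for seed in range(3):
        bt = branching_times(sim_yule(40, 1.0, seed=seed))
        pb, bd = fit_pure_birth(bt), fit_bd(bt)
        assert bd.lnl >= pb.lnl - 1e-7
        assert bd.k == 2 and pb.k == 1


def test_rate_variable_models_nest_pure_birth():
    for seed in range(3):
        bt = branching_times(sim_yule(30, 1.0, seed=seed))
        pb = fit_pure_birth(bt)
        for fit in (fit_ddl(bt), fit_ddx(bt), fit_yule2rate(bt), fit_yule3rate(bt)):
            assert fit.lnl >= pb.lnl - 1e-6, fit.model
        assert fit_yule3rate(bt).lnl >= fit_yule2rate(bt).lnl - 1e-9


def test_equal_segment_rates_reduce_to_pure_birth():
    """Evaluating the two-segment Yule likelihood with both rates at the
    single-rate MLE reproduces the pure-birth likelihood exactly."""
    from museumdiv.divrate import _split_segments
    bt = branching_times(sim_yule(25, 1.0, seed=1))
    pb = fit_pure_birth(bt)
    lam = pb.params["lambda"]
    lnl = 0.0
    for seg_k, seg_g, seg_e in _split_segments(bt, [float(bt.ages[5])]):
        m = int(seg_e.sum())
        lnl += m * math.log(lam) - lam * float(np.dot(seg_k, seg_g))
    assert lnl == pytest.approx(pb.lnl, abs=1e-9)


def test_model_parameter_counts():
    bt = branching_times(sim_yule(20, 1.0, seed=0))
    ks = {f.model: f.k for f in fit_all_models(bt)}
    assert ks == {"pureBirth": 1, "bd": 2, "DDL": 2, "DDX": 2,
                  "yule2rate": 3, "yule3rate": 5}


def test_delta_aic_rc_zero_for_identical_and_sign_convention():
    bt = branching_times(sim_yule(25, 1.0, seed=4))
    fits = fit_all_models(bt)
    sel = delta_aic_rc(fits)
    best_rc = min(f.aic for f in fits if not f.rate_variable)
    best_rv = min(f.aic for f in fits if f.rate_variable)
    assert sel["delta_aic_rc"] == pytest.approx(best_rc - best_rv)
    assert sel["lr"] >= -1e-9
    with pytest.raises(ValueError):
        delta_aic_rc([f for f in fits if not f.rate_variable])


def _sim_two_rate_yule(n, lam1, lam2, shift_frac, rng):
    """Forward two-rate Yule: rate switches at a fixed fraction of the
    final crown age; returns branching times (ages)."""
    # simulate with rate 1, then warp times piecewise to effect the shift
    times = [0.0]
    t = 0.0
    for k in range(2, n + 1):
        t += rng.exponential(1.0 / k)
        times.append(t)
    present = times[-1]
    shift = shift_frac * present
    # events: crown at time 0 plus the n-3 interior splits
    ages = present - np.array(times[:-1])
    # stretch old segment by 1/lam1 and young by 1/lam2 around the shift age
    warped = np.where(ages > shift,
                      shift / lam2 + (ages - shift) / lam1,
                      ages / lam2)
    return np.sort(warped)[::-1], shift / lam2


def test_yule2rate_recovers_shift_time(rng):
    """A 4x rate increase at half the crown age is located within the
    central half of the tree depth in most replicates."""
    hits = 0
    for _ in range(50):
        ages, true_shift = _sim_two_rate_yule(80, 0.1, 0.4, 0.5, rng)
        bt = BranchingTimes(80, ages)
        fit = fit_yule2rate(bt)
        crown = bt.crown_age
        if abs(fit.params["shift"] - true_shift) < 0.25 * crown:
            hits += 1
    assert hits >= 35  # >= 70% of 50 replicates


# ---------------------------------------------------------------------------
# fixed-time shift test


def test_shift_test_constant_rate_calibration(rng):
    rejected = valid = 0
    for _ in range(500):
        ages = yule_branching_times(40, 1.0, rng)
        bt = BranchingTimes(40, ages)
        try:
            res = shift_at_time_test(bt, 0.5 * bt.crown_age)
        except TreeError:
            continue  # all events on one side of the cut: test undefined
        assert res.lr >= -1e-9
        valid += 1
        rejected += res.p_value < 0.05
    assert valid > 400
    assert 0.02 < rejected / valid < 0.09


def test_shift_test_detects_rate_drop(rng):
    """Rates 0.4 -> 0.1 forward in time: lam_before/lam_after ~ 4."""
    ratios = []
    for _ in range(50):
        ages, true_shift = _sim_two_rate_yule(80, 0.4, 0.1, 0.5, rng)
        bt = BranchingTimes(80, ages)
        res = shift_at_time_test(bt, true_shift)
        ratios.append(res.lam_before / res.lam_after)
    assert 2.5 <= np.median(ratios) <= 6.0


def test_shift_test_requires_events_on_both_sides():
    with pytest.raises(TreeError):
        shift_at_time_test(COMB_BT, 2.5)  # only the crown event older
    with pytest.raises(TreeError):
        shift_at_time_test(COMB_BT, 0.5)  # no event younger
    with pytest.raises(TreeError):
        shift_at_time_test(COMB_BT, 3.5)  # outside (0, crown)


# ---------------------------------------------------------------------------
# relative cladogenesis


def _rc_tail_by_enumeration(r, n, k):
    """Uniform over compositions of n into k positive parts."""
    total = hits = 0
    for combo in itertools.product(range(1, n - k + 2), repeat=k):
        if sum(combo) != n:
            continue
        total += 1
        hits += combo[0] >= r
    return hits / total


def test_rc_tail_probability_small_case():
    assert rc_tail_probability(4, 5, 2) == pytest.approx(0.25)


@pytest.mark.parametrize("n,k", [(5, 2), (8, 3), (10, 4), (12, 4)])
def test_rc_tail_matches_enumeration(n, k):
    for r in range(1, n - k + 2):
        assert rc_tail_probability(r, n, k) == pytest.approx(
            _rc_tail_by_enumeration(r, n, k), abs=1e-12)


def test_rel_cladogenesis_balanced_tree_not_significant():
    tree = as_chronogram(parse_tree(
        "(((A:1,B:1):2,(C:1,D:1):2):1,((E:1,F:1):2,(G:1,H:1):2):1);"))
    res = rel_cladogenesis_test(tree)
    assert not res.any_significant
    assert np.all(res.p_bonferroni >= res.p_values - 1e-15)


def test_rel_cladogenesis_flags_extreme_imbalance():
    """One of two ancient lineages leaving 23 of 24 tips is improbable
    under the equal-rates null even before correction."""
    inner = "A1:1"
    for i in range(2, 24):
        inner = f"({inner},A{i}:{i - 1}):1"
    newick = f"({inner},B:23);"
    tree = as_chronogram(parse_tree(newick))
    res = rel_cladogenesis_test(tree)
    assert res.p_values.min() < 0.01


# ---------------------------------------------------------------------------
# net diversification


def test_netdiv_exact_zero_extinction_limits():
    assert ms_netdiv(30, 27.0, 0.0).r_crown == pytest.approx(math.log(15) / 27)
    assert ms_netdiv(30, 37.0, 0.0).r_stem == pytest.approx(math.log(30) / 37)


@pytest.mark.parametrize("n,t", [(10, 5.0), (30, 27.0), (200, 60.0)])
def test_netdiv_monotone_decreasing_in_extinction(n, t):
    rates = [ms_netdiv(n, t, eps) for eps in (0.0, 0.5, 0.9)]
    crowns = [r.r_crown for r in rates]
    stems = [r.r_stem for r in rates]
    assert crowns[0] > crowns[1] > crowns[2] > 0
    assert stems[0] > stems[1] > stems[2] > 0


def test_netdiv_input_validation():
    with pytest.raises(ValueError):
        ms_netdiv(30, 27.0, 1.0)
    with pytest.raises(ValueError):
        ms_netdiv(1, 27.0, 0.0)
    with pytest.raises(ValueError):
        ms_netdiv(30, 0.0, 0.0)


# ---------------------------------------------------------------------------
# property tests

try:
    from hypothesis import given, settings, strategies as st

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        gaps=st.lists(st.floats(min_value=1e-3, max_value=10.0),
                      min_size=3, max_size=40),
        scale=st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_gamma_scale_invariance_property(gaps, scale):
        """gamma and p are invariant to rescaling time on arbitrary
        strictly-ordered branching times."""
        ages = np.cumsum(gaps[::-1])[::-1]
        n = len(ages) + 1
        a = gamma_stat(BranchingTimes(n, ages))
        b = gamma_stat(BranchingTimes(n, ages * scale))
        assert b.gamma == pytest.approx(a.gamma, rel=1e-9, abs=1e-9)
        assert a.p_one_tailed == pytest.approx(norm.cdf(a.gamma), abs=1e-12)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(min_value=2, max_value=60),
           st.floats(min_value=0.05, max_value=0.95))
    def test_netdiv_ordering_property(n, eps):
        """Crown estimates never exceed stem estimates at equal age, and
        both decrease with the extinction fraction."""
        n += 1  # >= 3
        r = ms_netdiv(n, 11.0, eps)
        r0 = ms_netdiv(n, 11.0, 0.0)
        assert r.r_crown < r.r_stem
        assert r.r_crown < r0.r_crown and r.r_stem < r0.r_stem
except ImportError:  # hypothesis is an optional test dependency
    pass
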