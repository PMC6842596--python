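"""Reweighting, dangling-intermediate free energies, bootstrap errors."""

import numpy as np
import pandas as pd
import pytest

from unwindability import junction_states as js
from unwindability import surrogate_data as sd
from unwindability import thermo_stats as ts
from unwindability.sbm_forcefield import KBT_PN_NM_296K


def test_reweight_zero_force_is_uniform():
    fw = ts.reweight(np.array([1.0, 2.0, 3.0]), 0.0)
    assert np.allclose(fw.weights, 1 / 3)
    assert fw.ess == pytest.approx(3.0)


def test_reweight_two_frames_closed_form():
    # beta f = 1 / nm -> weights proportional to {1, e^-1}
    f_pn = KBT_PN_NM_296K  # makes beta f exactly 1/nm
    fw = ts.reweight(np.array([0.0, 1.0]), f_pn)
    e = np.exp(1.0)
    assert fw.weights[0] == pytest.approx(e / (1 + e), rel=1e-12)
    assert fw.weights[1] == pytest.approx(1 / (1 + e), rel=1e-12)


def test_reweight_rejects_nonfinite():
    with pytest.raises(ValueError):
        ts.reweight(np.array([1.0, np.nan]), 1.0)


def test_reweight_exact_cancellation_by_enumeration():
    """Two states with equal unbiased weight, sampled under bias
    exp(+beta f x): enumerating the biased distribution and reweighting
    recovers 0.5/0.5 to machine precision."""
    dx, beta_f = 0.8, 2.3
    x = np.array([0.0, dx])
    p_biased = np.exp(beta_f * x)
    p_biased /= p_biased.sum()
    w = np.exp(-beta_f * x) * p_biased
    w /= w.sum()
    assert abs(w[1] - 0.5) <= 1e-12


def test_reweight_sampler_recovers_unbiased_population():
    beta_f, dx, n = 1.0, 1.0, 10_000
    x = sd.biased_two_state_sampler(dx, beta_f, n, seed=4)
    fw = ts.reweight(x, beta_f * KBT_PN_NM_296K)
    p_hi = fw.weights[x > dx / 2].sum()
    # binomial CI of the biased fraction propagated through the weights
    assert abs(p_hi - 0.5) <= 3 * 0.5 / np.sqrt(n / 4)


from helpers_unwind import series_from_states as make_series, uniform_weights


def test_dangling_dg_equal_occupancy_zero():
    states = [js.FLIP5, js.FLIP3] * 50
    tab = ts.dangling_dg(make_series(states), uniform_weights(100))
    assert tab.g("GC/CG") == pytest.approx(0.0, abs=1e-12)


def test_dangling_dg_75_25_gives_ln3():
    states = [js.FLIP5] * 75 + [js.FLIP3] * 25
    tab = ts.dangling_dg(make_series(states), uniform_weights(100))
    assert tab.g("GC/CG") == pytest.approx(np.log(3.0), rel=1e-9)


def test_dangling_dg_unobserved_intermediate_flagged():
    states = [js.FLIP5] * 10 + [js.CLOSED] * 10
    tab = ts.dangling_dg(make_series(states), uniform_weights(20))
    assert not tab.observed("GC/CG")
    assert np.isnan(tab.g("GC/CG"))
    assert tab.data.n5.iloc[0] == 10
    assert tab.data.n3.iloc[0] == 0


def test_dangling_dg_alignment_check():
    with pytest.raises(ValueError, match="aligned"):
        ts.dangling_dg(make_series([js.CLOSED] * 10), uniform_weights(5))


def test_surrogate_e2_ratio_gives_two_kbt():
    """Stationary FLIP5/FLIP3 ratio e^2 must come back as g = 2 k_BT
    within the bootstrap SE."""
    e2 = np.exp(2.0)
    pi = np.array([0.3, 0.5 * e2 / (1 + e2), 0.5 / (1 + e2), 0.2])
    model = sd.junction_model(stationary=pi, rate_scale=1.0)
    # independent oracle: stationary distribution from the generator null vector
    pi_check = model.stationary()
    assert pi_check[js.FLIP5] / pi_check[js.FLIP3] == pytest.approx(e2, rel=1e-9)
    states, _, x = sd.sample_junction_series(model, 200_000, 0.04, seed=21)
    ser = make_series(states)
    fw = uniform_weights(len(states))
    tab = ts.bootstrap_se(ser, fw, n_boot=200, block_len=50, seed=3)
    g, se = tab.data.g.iloc[0], tab.data.se.iloc[0]
    assert abs(g - 2.0) <= 3 * se
    assert se < 0.2


def test_bootstrap_se_matches_delta_method():
    """i.i.d. intermediate states, block length 1: SE approaches
    sqrt(1/n5 + 1/n3)."""
    rng = np.random.default_rng(8)
    n = 10_000
    states = np.where(rng.random(n) < 0.5, js.FLIP5, js.FLIP3).astype(np.int8)
    ser = make_series(states)
    tab = ts.bootstrap_se(ser, uniform_weights(n), n_boot=400, block_len=1, seed=5)
    n5 = int((states == js.FLIP5).sum())
    n3 = n - n5
    expected = np.sqrt(1 / n5 + 1 / n3)
    assert tab.data.se.iloc[0] == pytest.approx(expected, rel=0.15)


def test_bootstrap_se_shrinks_with_length():
    ses = []
    for n in (2_000, 8_000, 32_000):
        rng = np.random.default_rng(n)
        states = np.where(rng.random(n) < 0.5, js.FLIP5, js.FLIP3).astype(np.int8)
        tab = ts.bootstrap_se(make_series(states), uniform_weights(n),
                              n_boot=200, block_len=1, seed=2)
        ses.append(tab.data.se.iloc[0])
    assert ses[0] > ses[1] > ses[2]
    assert ses[0] / ses[2] == pytest.approx(4.0, rel=0.4)  # sqrt(16) scaling


def test_bootstrap_deterministic_for_seed():
    rng = np.random.default_rng(0)
    states = np.where(rng.random(500) < 0.6, js.FLIP5, js.FLIP3).astype(np.int8)
    a = ts.bootstrap_se(make_series(states), uniform_weights(500), n_boot=50, block_len=5, seed=9)
    b = ts.bootstrap_se(make_series(states), uniform_weights(500), n_boot=50, block_len=5, seed=9)
    assert a.data.se.iloc[0] == b.data.se.iloc[0]


def test_bootstrap_rejects_short_series():
    states = np.array([js.FLIP5] * 10, dtype=np.int8)
    with pytest.raises(ValueError, match="shorter"):
        ts.bootstrap_se(make_series(states), uniform_weights(10), n_boot=10, block_len=50)


def ev(direction, pathway, context="GC/CG"):
    return js.OpeningEvent(direction, pathway, context, 1, 0, 1)


def test_detailed_balance_mirrored_counts():
    events = [ev("opening", "via_FLIP5")] * 30 + [ev("opening", "via_FLIP3")] * 10 \
        + [ev("closing", "via_FLIP5")] * 30 + [ev("closing", "via_FLIP3")] * 10
    rep = ts.detailed_balance_report(events)
    assert rep.p.iloc[0] == pytest.approx(1.0)
    assert not rep.reject.iloc[0]


def test_detailed_balance_detects_violation():
    events = [ev("opening", "via_FLIP5")] * 100 + [ev("closing", "via_FLIP3")] * 100
    rep = ts.detailed_balance_report(events)
    assert rep.p.iloc[0] < 1e-6
    assert rep.reject.iloc[0]


def test_detailed_balance_skips_sparse_contexts():
    events = [ev("opening", "via_FLIP5")] * 5 + [ev("closing", "via_FLIP5")]
    rep = ts.detailed_balance_report(events)
    assert rep.skipped.iloc[0]


def test_all_contexts_enumeration():
    for nt in ("RNA", "DNA"):
        ctx = ts.all_contexts(nt)
        assert len(ctx) == 16 == len(set(ctx))
        for c in ctx:
            top, bottom = c.split("/")
            assert len(top) == len(bottom) == 2


def test_reweighting_consistency_two_state():
    """Sampling under force f and reweighting to zero force agrees with
    the analytic unbiased populations for any f (two-state system)."""
    dx = 1.0
    for beta_f in (0.5, 1.0, 2.0):
        x = sd.biased_two_state_sampler(dx, beta_f, 40_000, seed=int(beta_f * 10))
        fw = ts.reweight(x, beta_f * KBT_PN_NM_296K)
        p_hi = fw.weights[x > dx / 2].sum()
        assert abs(p_hi - 0.5) <= 0.02
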