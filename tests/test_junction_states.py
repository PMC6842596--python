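"""Junction-state assignment and opening/closing event extraction."""

import numpy as np
import pytest

from unwindability import helix_builder as hb
from unwindability import junction_states as js
from unwindability import surrogate_data as sd


def test_smooth_window_one_is_identity(rng):
    x = rng.standard_normal(100)
    assert np.array_equal(js.smooth(x, 1), x)


def test_smooth_constant_unchanged():
    x = np.full(50, 3.7)
    assert np.allclose(js.smooth(x, 7), x)


def test_smooth_impulse_spreads():
    x = np.zeros(9)
    x[4] = 1.0
    sm = js.smooth(x, 3)
    assert np.allclose(sm[3:6], 1 / 3)
    assert sm[0] == 0.0
    assert len(sm) == 9


def test_smooth_rejects_bad_window():
    with pytest.raises(ValueError):
        js.smooth(np.zeros(5), 0)


def test_pairing_distance_native_and_translated(rna_hexamer):
    s = rna_hexamer
    for k in range(1, 7):
        assert 2.6 <= js.pairing_distance(s.coords, s, k) <= 3.2
    # rigid +20 A separation of chain B increases every pairing distance
    X = s.coords.copy()
    mask = np.array([c == "B" for c in s.chain_id])
    X[mask] += np.array([20.0, 0.0, 0.0])
    for k in range(1, 7):
        assert js.pairing_distance(X, s, k) > js.pairing_distance(s.coords, s, k)


def test_stacking_distance_native_and_errors(dna_hexamer):
    s = dna_hexamer
    d = js.stacking_distance(s.coords, s, ("A", 1), ("A", 2))
    assert d == pytest.approx(3.38, abs=1.5)  # about one helical rise
    with pytest.raises(ValueError):
        js.stacking_distance(s.coords, s, ("A", 1), ("A", 1))
    # rotating the terminal base 90 degrees about the backbone increases it
    idx = s.base_atom_indices("A", 1)
    X = s.coords.copy()
    pivot = X[s.atom("A", 1, "C1'")]
    R = np.array([[1, 0, 0], [0, 0, -1], [0, 1, 0]], dtype=float)
    X[idx] = (X[idx] - pivot) @ R.T + pivot
    assert js.stacking_distance(X, s, ("A", 1), ("A", 2)) > d


def make_channels(structure, n_frames, bumps):
    """Native channels plus per-frame offsets; bumps maps
    (channel, pair_index) -> array of offsets."""
    nat = js.compute_channels(structure.coords[None], structure)
    ch = {k: np.repeat(v, n_frames, axis=0) for k, v in nat.items()}
    for (key, k), off in bumps.items():
        ch[key][:, k] += off
    return ch


def test_assign_states_native_is_closed(rna_hexamer):
    ch = make_channels(rna_hexamer, 10, {})
    ser = js.assign_states(ch, rna_hexamer, window=1)
    assert np.all(ser.pair_states == js.CLOSED)
    assert np.all(ser.junction == 1)
    assert np.all(ser.states == js.CLOSED)


def test_assign_states_flip5_and_flip3(rna_hexamer):
    n = 10
    big = np.full(n, 8.0)
    ch = make_channels(rna_hexamer, n, {("pairing", 0): big, ("stack5", 0): big})
    ser = js.assign_states(ch, rna_hexamer, window=1)
    assert np.all(ser.states == js.FLIP5)
    ch = make_channels(rna_hexamer, n, {("pairing", 0): big, ("stack3", 0): big})
    ser = js.assign_states(ch, rna_hexamer, window=1)
    assert np.all(ser.states == js.FLIP3)


def test_assign_states_fully_separated_is_open(rna_hexamer):
    n = 5
    bumps = {}
    for k in range(6):
        bumps[("pairing", k)] = np.full(n, 25.0)
    for k in range(5):
        bumps[("stack5", k)] = np.full(n, 25.0)
        bumps[("stack3", k)] = np.full(n, 25.0)
    ser = js.assign_states(make_channels(rna_hexamer, n, bumps), rna_hexamer, window=1)
    assert np.all(ser.pair_states[:, :5] == js.OPEN)
    assert np.all(ser.junction == 7)  # past the last pair
    assert np.all(ser.states == js.OPEN)


def test_assign_states_requires_ordered_thresholds():
    with pytest.raises(ValueError):
        js.StateThresholds(pairing_offset=1.0, stack_offset=2.0, hysteresis=1.5)


from helpers_unwind import series_from_states


@pytest.mark.parametrize(
    "seq,expected",
    [
        ([js.CLOSED, js.FLIP5, js.OPEN], [("opening", "via_FLIP5")]),
        ([js.OPEN, js.FLIP5, js.CLOSED], [("closing", "via_FLIP5")]),
        ([js.CLOSED, js.FLIP3, js.OPEN], [("opening", "via_FLIP3")]),
        ([js.CLOSED, js.FLIP5, js.CLOSED], []),  # aborted excursion
        ([js.CLOSED, js.OPEN], [("opening", "direct")]),
        (
            [js.CLOSED, js.FLIP5, js.OPEN, js.FLIP3, js.CLOSED],
            [("opening", "via_FLIP5"), ("closing", "via_FLIP3")],
        ),
    ],
)
def test_extract_events_basic(seq, expected):
    ser = series_from_states(seq)
    events = js.extract_events(ser, min_dwell=1)
    assert [(e.direction, e.pathway) for e in events] == expected
    for e in events:
        assert e.context == "GC/CG"
        assert e.start < e.end


def test_extract_events_longest_dwell_tiebreak():
    seq = [js.CLOSED, js.FLIP5, js.FLIP5, js.FLIP3, js.OPEN]
    (ev,) = js.extract_events(series_from_states(seq), min_dwell=1)
    assert ev.pathway == "via_FLIP5"
    seq = [js.CLOSED, js.FLIP5, js.FLIP3, js.OPEN]
    (ev,) = js.extract_events(series_from_states(seq), min_dwell=1)
    assert ev.pathway == "direct"  # exact tie


def test_extract_events_debounce():
    seq = [js.CLOSED] * 10 + [js.OPEN] + [js.CLOSED] * 10 + [js.OPEN] * 10
    events = js.extract_events(series_from_states(seq), min_dwell=3)
    assert len(events) == 1  # the one-frame blip is merged away


def test_surrogate_state_recovery_accuracy(rna_hexamer):
    """Channels whose state separation is >= 5 noise SD recover the
    generating state sequence almost perfectly."""
    gc = hb.build_duplex("GC", "RNA")
    nat = js.compute_channels(gc.coords[None], gc)
    model = sd.junction_model(emission_sd=0.35, x_sd=0.02)
    model.emission_means = np.array([
        [nat["pairing"][0, 0], nat["stack5"][0, 0], nat["stack3"][0, 0]],
        [nat["pairing"][0, 0] + 8, nat["stack5"][0, 0] + 8, nat["stack3"][0, 0]],
        [nat["pairing"][0, 0] + 8, nat["stack5"][0, 0], nat["stack3"][0, 0] + 8],
        [nat["pairing"][0, 0] + 8, nat["stack5"][0, 0] + 8, nat["stack3"][0, 0] + 8],
    ])
    states, ch, x = sd.sample_junction_series(model, 20_000, 0.05, seed=9)
    ch["pairing"][:, 1] = nat["pairing"][0, 1]
    ser = js.assign_states(ch, gc, window=1)
    acc = np.mean(ser.pair_states[:, 0] == states)
    assert acc >= 0.99


def test_pathway_ratio_recovery_binomial(rna_hexamer):
    """A symmetric junction chain opens through either pathway with
    probability 1/2; the recovered ratio stays inside the binomial CI."""
    model = sd.junction_model(stationary=(0.3, 0.2, 0.2, 0.3), rate_scale=2.0)
    states, _, _ = sd.sample_junction_series(model, 400_000, 0.04, seed=13)
    ser = series_from_states(states)
    events = [e for e in js.extract_events(ser, min_dwell=1) if e.pathway != "direct"]
    n5 = sum(e.pathway == "via_FLIP5" for e in events)
    n = len(events)
    assert n >= 1000
    p_hat = n5 / n
    ci = 1.96 * np.sqrt(0.25 / n)
    assert abs(p_hat - 0.5) <= ci * 1.5  # allow slight slack over the exact CI
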