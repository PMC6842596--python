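"""Integrator physics: symplectic limit, thermostat, drift, calibration."""

import numpy as np
import pytest

from unwindability import helix_builder as hb
from unwindability import langevin_engine as le
from helpers_unwind import minimal_topology


def test_end_to_end_basic_and_rotation_invariance(rna_hexamer):
    frame = np.zeros((2, 3))
    frame[1, 2] = 30.0
    assert le.end_to_end(frame, (0, 1)) == pytest.approx(3.0)
    i, j = rna_hexamer.pulling_pair
    x0 = le.end_to_end(rna_hexamer.coords, (i, j))
    assert x0 == pytest.approx(np.linalg.norm(rna_hexamer.coords[i] - rna_hexamer.coords[j]) / 10)
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=2).as_matrix()
    assert le.end_to_end(rna_hexamer.coords @ R.T, (i, j)) == pytest.approx(x0)


def test_harmonic_bond_period():
    """gamma=0, T=0 velocity-Verlet limit: period within 0.1% of
    2 pi sqrt(mu / 2k) for V = k (r - r0)^2."""
    k = 100.0
    top = minimal_topology(2, bonds=[(0, 1)], r0=[1.5], k=[k])
    X0 = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 1.6]])
    cfg = le.SimulationConfig(gamma=0.0, temperature=0.0, n_steps=80_000, save_stride=5, seed=0)
    tr = le.run(top, cfg, initial_coords=X0)
    x = tr.x_nm * 10
    peaks = np.nonzero((x[1:-1] > x[:-2]) & (x[1:-1] > x[2:]))[0] + 1
    period = np.diff(peaks).mean() * cfg.save_stride * cfg.timestep
    mu = 0.5
    expected = 2 * np.pi * np.sqrt(mu / (2 * k))
    assert period == pytest.approx(expected, rel=1e-3)


def test_nve_energy_conservation(rna_topology, rna_hexamer):
    rng = np.random.default_rng(0)
    X0 = rna_hexamer.coords + 0.05 * rng.standard_normal(rna_hexamer.coords.shape)
    cfg = le.SimulationConfig(gamma=0.0, temperature=0.0, n_steps=100_000, save_stride=200, seed=1)
    tr = le.run(rna_topology, cfg, structure=rna_hexamer, initial_coords=X0)
    E = tr.e_pot + tr.e_kin
    assert abs(E[-1] - E[0]) / abs(E[0]) <= 1e-4


def test_terminal_drift_velocity():
    """Constant force, gamma > 0, T = 0: drift velocity f/gamma per atom."""
    top = minimal_topology(2)
    X0 = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 500.0]])
    gamma, f = 0.5, 0.3
    cfg = le.SimulationConfig(gamma=gamma, temperature=0.0, n_steps=50_000,
                              save_stride=100, f_reduced=f, seed=0)
    tr = le.run(top, cfg, initial_coords=X0)
    t = np.arange(1, tr.n_frames + 1) * cfg.save_stride * cfg.timestep
    half = tr.n_frames // 2
    v = np.polyfit(t[half:], tr.x_nm[half:] * 10, 1)[0]
    assert v == pytest.approx(2 * f / gamma, rel=0.01)  # both ends drift apart


def test_harmonic_oscillator_boltzmann_variance():
    """Sampled bond-length variance matches T / (2k) within 2%."""
    k, T = 50.0, 1.3
    top = minimal_topology(2, bonds=[(0, 1)], r0=[5.0], k=[k])
    cfg = le.SimulationConfig(gamma=5.0, temperature=T, n_steps=6_000_000, save_stride=20, seed=3)
    X0 = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 5.0]])
    tr = le.run(top, cfg, initial_coords=X0)
    r = tr.x_nm * 10
    burn = len(r) // 10
    assert np.var(r[burn:]) == pytest.approx(T / (2 * k), rel=0.02)


def test_equipartition_full_duplex(rna_topology, rna_hexamer):
    cfg = le.SimulationConfig(gamma=1.0, temperature=1.0, n_steps=120_000, save_stride=20, seed=4)
    tr = le.run(rna_topology, cfg, structure=rna_hexamer)
    burn = tr.n_frames // 5
    ke = tr.e_kin[burn:].mean()
    assert ke == pytest.approx(1.5 * rna_topology.n_atoms * cfg.temperature, rel=0.02)


def test_seed_determinism(rna_topology, rna_hexamer):
    cfg = le.SimulationConfig(temperature=1.0, n_steps=5_000, save_stride=10, seed=42)
    a = le.run(rna_topology, cfg, structure=rna_hexamer)
    b = le.run(rna_topology, cfg, structure=rna_hexamer)
    assert np.array_equal(a.x_nm, b.x_nm)
    assert np.array_equal(a.e_pot, b.e_pot)


def test_channels_match_offline_computation(rna_topology, rna_hexamer):
    from unwindability import junction_states as js

    cfg = le.SimulationConfig(temperature=1.0, n_steps=2_000, save_stride=100, seed=5,
                              record_frames=True, record_channels=True)
    tr = le.run(rna_topology, cfg, structure=rna_hexamer)
    off = js.compute_channels(tr.frames, rna_hexamer)
    for key in ("pairing", "stack5", "stack3"):
        assert np.allclose(tr.channels[key], off[key], atol=1e-9)


def test_blowup_detection(rna_topology, rna_hexamer):
    cfg = le.SimulationConfig(timestep=0.3, gamma=0.0, temperature=0.0,
                              n_steps=2_000, save_stride=1, seed=0)
    rng = np.random.default_rng(0)
    X0 = rna_hexamer.coords + 0.3 * rng.standard_normal(rna_hexamer.coords.shape)
    with pytest.raises(RuntimeError, match="blow-up"):
        le.run(rna_topology, cfg, structure=rna_hexamer, initial_coords=X0)


def test_calibrate_picks_balanced_temperature(monkeypatch, rna_topology, rna_hexamer):
    """Two-state surrogate: occupancy balance follows an analytic folded
    fraction p(T); the chosen grid point brackets the coexistence T."""
    x_lo, x_hi = le.hopping_thresholds(rna_hexamer)
    t_c = 2.1

    def fake_run(topology, config, structure=None, initial_coords=None):
        rng = np.random.default_rng(config.seed + int(config.temperature * 1000))
        p_fold = 1.0 / (1.0 + np.exp((config.temperature - t_c) / 0.15))
        n = 2000
        folded = rng.random(n) < p_fold
        x = np.where(folded, x_lo - 0.3, x_hi + 0.3)
        return le.Trajectory(config=config, x_nm=x, e_pot=np.zeros(n), e_kin=np.zeros(n), n_dof=3)

    monkeypatch.setattr(le, "run", fake_run)
    grid = [1.5, 1.8, 2.1, 2.4, 2.7]
    t_best, report = le.calibrate_hopping(rna_topology, rna_hexamer, 14.0, grid, n_steps=1000)
    assert abs(t_best - t_c) <= 0.3 + 1e-9  # within one grid step
    assert report.transitions[t_best] >= 4


def test_calibrate_duplicate_grid_first_match(monkeypatch, rna_topology, rna_hexamer):
    x_lo, x_hi = le.hopping_thresholds(rna_hexamer)
    calls = []

    def fake_run(topology, config, structure=None, initial_coords=None):
        calls.append(config.temperature)
        rng = np.random.default_rng(0)
        x = np.where(rng.random(1000) < 0.5, x_lo - 0.3, x_hi + 0.3)
        return le.Trajectory(config=config, x_nm=x, e_pot=np.zeros(1000), e_kin=np.zeros(1000), n_dof=3)

    monkeypatch.setattr(le, "run", fake_run)
    t_best, _ = le.calibrate_hopping(rna_topology, rna_hexamer, 14.0, [2.0, 2.0, 2.0], n_steps=100)
    assert t_best == 2.0
    assert len(calls) == 1  # duplicates skipped deterministically


def test_calibrate_errors_when_no_hopping(monkeypatch, rna_topology, rna_hexamer):
    def fake_run(topology, config, structure=None, initial_coords=None):
        x = np.full(500, 1.0)  # always folded
        return le.Trajectory(config=config, x_nm=x, e_pot=np.zeros(500), e_kin=np.zeros(500), n_dof=3)

    monkeypatch.setattr(le, "run", fake_run)
    with pytest.raises(RuntimeError, match="widen the grid"):
        le.calibrate_hopping(rna_topology, rna_hexamer, 14.0, [1.0, 2.0], n_steps=100)


def test_transition_count_hysteresis():
    x = np.array([1.0, 1.5, 2.5, 3.5, 1.2, 2.2, 3.6, 1.1])
    assert le.transition_count(x, 1.8, 3.0) == 4  # f->u, u->f, f->u, u->f
    assert le.transition_count(np.array([1.0, 2.5, 1.0]), 1.8, 3.0) == 0  # never unfolds
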