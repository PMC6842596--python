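"""Langevin dynamics of the structure-based duplex under constant force.

A BAOAB splitting integrator (velocity Verlet in the zero-friction
limit) samples the canonical ensemble of the Go-type Hamiltonian with an
optional constant pulling force applied between the terminal 5' and 3'
hydroxyl oxygens, mimicking a constant-force optical-tweezer experiment.
At a suitable reduced temperature the duplex hops reversibly between the
folded (low end-to-end distance) and unfolded (extended) basins.

The excluded-volume wall is short ranged, so the engine keeps a
periodically rebuilt neighbor list of active repulsive pairs; every
other interaction list is static.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from numba import njit

from .helix_builder import NativeStructure
from .sbm_forcefield import Topology, _eval_forces, force_pn_to_reduced

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "end_to_end",
    "run",
    "calibrate_hopping",
    "transition_count",
    "basin_occupancies",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Integration and thermostat settings (reduced units).

    f_pn is the constant pulling force in piconewton; it is converted
    internally with the 296 K mapping (14 pN = 3.42 k_BT/nm).  f_reduced
    overrides the conversion when set (used for unit tests at T=0).
    """

    timestep: float = 0.002
    gamma: float = 1.0
    temperature: float = 1.0
    n_steps: int = 100_000
    save_stride: int = 20
    f_pn: float = 0.0
    f_reduced: Optional[float] = None
    seed: int = 0
    nb_update: int = 25
    nb_skin: float = 1.0
    x_wall_nm: Optional[float] = None  # flat-bottom cap on the end-to-end
    # distance (tether length of the mimicked tweezer construct)
    k_wall: float = 5.0  # reduced energy / A^2
    record_frames: bool = False
    record_channels: bool = False

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be > 0")
        if self.gamma < 0 or self.temperature < 0:
            raise ValueError("gamma and temperature must be >= 0")
        if self.n_steps < 1 or self.save_stride < 1:
            raise ValueError("n_steps and save_stride must be >= 1")

    @property
    def force_reduced(self) -> float:
        if self.f_reduced is not None:
            return self.f_reduced
        return force_pn_to_reduced(self.f_pn, self.temperature)


@dataclass
class Trajectory:
    """Saved observables of one run (one row per saved frame)."""

    config: SimulationConfig
    x_nm: np.ndarray  # end-to-end (pulling-pair) distance, nm
    e_pot: np.ndarray
    e_kin: np.ndarray
    n_dof: int
    frames: Optional[np.ndarray] = None  # (n_saved, n_atoms, 3), Angstrom
    channels: Optional[Dict[str, np.ndarray]] = None

    @property
    def n_frames(self) -> int:
        return len(self.x_nm)


def end_to_end(frame: np.ndarray, pulling_pair: Tuple[int, int]) -> float:
    """Distance between the two attachment atoms of one frame, in nm."""
    i, j = pulling_pair
    return float(np.linalg.norm(np.asarray(frame)[i] - np.asarray(frame)[j])) / 10.0


@njit(cache=True)
def _rebuild_nb(X, ev_pairs, ev_rc, skin, out):
    n = 0
    for p in range(ev_pairs.shape[0]):
        i, j = ev_pairs[p, 0], ev_pairs[p, 1]
        dx = X[i, 0] - X[j, 0]
        dy = X[i, 1] - X[j, 1]
        dz = X[i, 2] - X[j, 2]
        rc = ev_rc[p] + skin
        if dx * dx + dy * dy + dz * dz < rc * rc:
            out[n] = p
            n += 1
    return n


@njit(cache=True)
def _centroid_dist(X, rings, counts, a, b):
    ax = ay = az = 0.0
    for t in range(counts[a]):
        i = rings[a, t]
        ax += X[i, 0]
        ay += X[i, 1]
        az += X[i, 2]
    bx = by = bz = 0.0
    for t in range(counts[b]):
        i = rings[b, t]
        bx += X[i, 0]
        by += X[i, 1]
        bz += X[i, 2]
    ax /= counts[a]
    ay /= counts[a]
    az /= counts[a]
    bx /= counts[b]
    by /= counts[b]
    bz /= counts[b]
    return math.sqrt((ax - bx) ** 2 + (ay - by) ** 2 + (az - bz) ** 2)


@njit(cache=True)
def _run_kernel(
    X, V, masses,
    bonds, bond_r0, bond_k, angles, angle_t0, angle_k,
    dihedrals, dih_phi0, dih_k1, dih_k3, contacts, contact_sigma, eps_c,
    ev_pairs, ev_rc, r_ex, eps_ex, pull_i, pull_j, f_c, wall_x, wall_k,
    dt, gamma, temperature, n_steps, save_stride, seed, nb_update, skin,
    record_frames, frames_out, x_out, epot_out, ekin_out,
    record_channels, wc_i, wc_j, rings, ring_counts,
    s5_a, s5_b, s3_a, s3_b, pair_out, s5_out, s3_out,
):
    np.random.seed(seed)
    n_atoms = X.shape[0]
    F = np.zeros((n_atoms, 3))
    ev_sel = np.empty(ev_pairs.shape[0], dtype=np.int64)
    n_sel = _rebuild_nb(X, ev_pairs, ev_rc, skin, ev_sel)

    c1 = math.exp(-gamma * dt)
    half_dt = 0.5 * dt

    eb, ea, ed, ec, ee, ep = _eval_forces(
        X, bonds, bond_r0, bond_k, angles, angle_t0, angle_k,
        dihedrals, dih_phi0, dih_k1, dih_k3, contacts, contact_sigma, eps_c,
        ev_pairs, ev_rc, r_ex, eps_ex, pull_i, pull_j, f_c, F, ev_sel[:n_sel],
    )
    blew_up = -1
    isave = 0
    for step in range(1, n_steps + 1):
        # B
        for i in range(n_atoms):
            inv_m = half_dt / masses[i]
            V[i, 0] += inv_m * F[i, 0]
            V[i, 1] += inv_m * F[i, 1]
            V[i, 2] += inv_m * F[i, 2]
        # A
        for i in range(n_atoms):
            X[i, 0] += half_dt * V[i, 0]
            X[i, 1] += half_dt * V[i, 1]
            X[i, 2] += half_dt * V[i, 2]
        # O
        if gamma > 0.0 and temperature >= 0.0:
            for i in range(n_atoms):
                c2 = math.sqrt(temperature * (1.0 - c1 * c1) / masses[i])
                V[i, 0] = c1 * V[i, 0] + c2 * np.random.standard_normal()
                V[i, 1] = c1 * V[i, 1] + c2 * np.random.standard_normal()
                V[i, 2] = c1 * V[i, 2] + c2 * np.random.standard_normal()
        # A
        for i in range(n_atoms):
            X[i, 0] += half_dt * V[i, 0]
            X[i, 1] += half_dt * V[i, 1]
            X[i, 2] += half_dt * V[i, 2]
        # refresh neighbor list
        if step % nb_update == 0:
            n_sel = _rebuild_nb(X, ev_pairs, ev_rc, skin, ev_sel)
        # force + B
        for i in range(n_atoms):
            F[i, 0] = 0.0
            F[i, 1] = 0.0
            F[i, 2] = 0.0
        eb, ea, ed, ec, ee, ep = _eval_forces(
            X, bonds, bond_r0, bond_k, angles, angle_t0, angle_k,
            dihedrals, dih_phi0, dih_k1, dih_k3, contacts, contact_sigma, eps_c,
            ev_pairs, ev_rc, r_ex, eps_ex, pull_i, pull_j, f_c, F, ev_sel[:n_sel],
        )
        if wall_k > 0.0:
            dx = X[pull_i, 0] - X[pull_j, 0]
            dy = X[pull_i, 1] - X[pull_j, 1]
            dz = X[pull_i, 2] - X[pull_j, 2]
            r = math.sqrt(dx * dx + dy * dy + dz * dz)
            if r > wall_x:
                ep += 0.5 * wall_k * (r - wall_x) ** 2
                fmag = -wall_k * (r - wall_x) / r
                F[pull_i, 0] += fmag * dx
                F[pull_i, 1] += fmag * dy
                F[pull_i, 2] += fmag * dz
                F[pull_j, 0] -= fmag * dx
                F[pull_j, 1] -= fmag * dy
                F[pull_j, 2] -= fmag * dz
        for i in range(n_atoms):
            inv_m = half_dt / masses[i]
            V[i, 0] += inv_m * F[i, 0]
            V[i, 1] += inv_m * F[i, 1]
            V[i, 2] += inv_m * F[i, 2]

        if step % save_stride == 0:
            epot = eb + ea + ed + ec + ee + ep
            ekin = 0.0
            for i in range(n_atoms):
                ekin += 0.5 * masses[i] * (V[i, 0] ** 2 + V[i, 1] ** 2 + V[i, 2] ** 2)
            dx = X[pull_i, 0] - X[pull_j, 0]
            dy = X[pull_i, 1] - X[pull_j, 1]
            dz = X[pull_i, 2] - X[pull_j, 2]
            x_out[isave] = math.sqrt(dx * dx + dy * dy + dz * dz) / 10.0
            epot_out[isave] = epot
            ekin_out[isave] = ekin
            if record_frames:
                for i in range(n_atoms):
                    frames_out[isave, i, 0] = X[i, 0]
                    frames_out[isave, i, 1] = X[i, 1]
                    frames_out[isave, i, 2] = X[i, 2]
            if record_channels:
                for k in range(wc_i.shape[0]):
                    ddx = X[wc_i[k], 0] - X[wc_j[k], 0]
                    ddy = X[wc_i[k], 1] - X[wc_j[k], 1]
                    ddz = X[wc_i[k], 2] - X[wc_j[k], 2]
                    pair_out[isave, k] = math.sqrt(ddx * ddx + ddy * ddy + ddz * ddz)
                for k in range(s5_a.shape[0]):
                    s5_out[isave, k] = _centroid_dist(X, rings, ring_counts, s5_a[k], s5_b[k])
                    s3_out[isave, k] = _centroid_dist(X, rings, ring_counts, s3_a[k], s3_b[k])
            isave += 1
            if not math.isfinite(epot) or abs(epot) > 1e9:
                blew_up = step
                break
    return blew_up


def _ring_tables(structure: NativeStructure) -> Tuple[np.ndarray, np.ndarray, Dict[Tuple[str, int], int]]:
    """Padded ring-atom index table, one row per residue."""
    rows: List[np.ndarray] = []
    row_of: Dict[Tuple[str, int], int] = {}
    for chain in ("A", "B"):
        for resi in range(1, structure.n_pairs + 1):
            row_of[(chain, resi)] = len(rows)
            rows.append(structure.base_atom_indices(chain, resi, ring_only=True))
    width = max(len(r) for r in rows)
    rings = np.zeros((len(rows), width), dtype=np.int64)
    counts = np.zeros(len(rows), dtype=np.int64)
    for r, idx in enumerate(rows):
        rings[r, : len(idx)] = idx
        counts[r] = len(idx)
    return rings, counts, row_of


def channel_atom_tables(structure: NativeStructure):
    """Index tables for the per-pair distance channels.

    Returns (wc_i, wc_j, rings, counts, s5_a, s5_b, s3_a, s3_b): the WC
    donor/acceptor atom pair of every base pair, and for every junction
    position k = 1..N-1 the ring-table rows whose centroid distances give
    the 5'-stacking (chain-1 base k vs k+1) and 3'-stacking (chain-2
    partner vs its inward neighbor) channels.
    """
    n = structure.n_pairs
    wc = np.array([structure.wc_atom_indices(k) for k in range(1, n + 1)], dtype=np.int64)
    rings, counts, row_of = _ring_tables(structure)
    s5_a = np.array([row_of[("A", k)] for k in range(1, n)], dtype=np.int64)
    s5_b = np.array([row_of[("A", k + 1)] for k in range(1, n)], dtype=np.int64)
    s3_a = np.array([row_of[("B", n + 1 - k)] for k in range(1, n)], dtype=np.int64)
    s3_b = np.array([row_of[("B", n - k)] for k in range(1, n)], dtype=np.int64)
    return wc[:, 0].copy(), wc[:, 1].copy(), rings, counts, s5_a, s5_b, s3_a, s3_b


def run(
    topology: Topology,
    config: SimulationConfig,
    structure: NativeStructure | None = None,
    initial_coords: np.ndarray | None = None,
) -> Trajectory:
    """Integrate Langevin dynamics and return the saved observables.

    `structure` is required when record_channels is set (it defines the
    junction distance channels) and provides the default start
    configuration (the native state).
    """
    if initial_coords is None:
        if structure is None:
            raise ValueError("need structure or initial_coords")
        X = structure.coords.copy()
    else:
        X = np.array(initial_coords, dtype=float)
    if X.shape != (topology.n_atoms, 3):
        raise ValueError("initial coordinate shape mismatch")
    rng = np.random.default_rng(config.seed)
    if config.temperature > 0:
        V = rng.standard_normal(X.shape) * np.sqrt(config.temperature / topology.masses[:, None])
    else:
        V = np.zeros_like(X)

    n_saved = config.n_steps // config.save_stride
    x_out = np.zeros(n_saved)
    epot_out = np.zeros(n_saved)
    ekin_out = np.zeros(n_saved)
    frames_out = np.zeros((n_saved if config.record_frames else 1, topology.n_atoms, 3))
    if config.record_channels:
        if structure is None:
            raise ValueError("record_channels requires the native structure")
        wc_i, wc_j, rings, counts, s5_a, s5_b, s3_a, s3_b = channel_atom_tables(structure)
        n = structure.n_pairs
        pair_out = np.zeros((n_saved, n))
        s5_out = np.zeros((n_saved, n - 1))
        s3_out = np.zeros((n_saved, n - 1))
    else:
        wc_i = wc_j = s5_a = s5_b = s3_a = s3_b = np.zeros(0, dtype=np.int64)
        rings = np.zeros((1, 1), dtype=np.int64)
        counts = np.ones(1, dtype=np.int64)
        pair_out = np.zeros((1, 1))
        s5_out = np.zeros((1, 1))
        s3_out = np.zeros((1, 1))

    blew_up = _run_kernel(
        X, V, topology.masses,
        topology.bonds, topology.bond_r0, topology.bond_k,
        topology.angles, topology.angle_t0, topology.angle_k,
        topology.dihedrals, topology.dih_phi0, topology.dih_k1, topology.dih_k3,
        topology.contacts, topology.contact_sigma, topology.eps_contact,
        topology.ev_pairs, topology.ev_rc, topology.r_ex, topology.eps_ex,
        topology.pulling_pair[0], topology.pulling_pair[1], config.force_reduced,
        (config.x_wall_nm * 10.0) if config.x_wall_nm is not None else 1e12,
        config.k_wall if config.x_wall_nm is not None else 0.0,
        config.timestep, config.gamma, config.temperature, config.n_steps,
        config.save_stride, config.seed, config.nb_update, config.nb_skin,
        config.record_frames, frames_out, x_out, epot_out, ekin_out,
        config.record_channels, wc_i, wc_j, rings, counts,
        s5_a, s5_b, s3_a, s3_b, pair_out, s5_out, s3_out,
    )
    if blew_up >= 0:
        raise RuntimeError(f"numerical blow-up at step {blew_up} (|E| > 1e9 or non-finite)")
    channels = None
    if config.record_channels:
        channels = {"pairing": pair_out, "stack5": s5_out, "stack3": s3_out}
    return Trajectory(
        config=config,
        x_nm=x_out,
        e_pot=epot_out,
        e_kin=ekin_out,
        n_dof=3 * topology.n_atoms,
        frames=frames_out if config.record_frames else None,
        channels=channels,
    )


# ---------------------------------------------------------------------------
# hopping diagnostics / temperature calibration
# ---------------------------------------------------------------------------


def basin_occupancies(x_nm: np.ndarray, x_folded: float, x_unfolded: float) -> Tuple[float, float]:
    """Fraction of frames below the folded and above the unfolded threshold."""
    x = np.asarray(x_nm)
    return float(np.mean(x < x_folded)), float(np.mean(x > x_unfolded))


def transition_count(x_nm: np.ndarray, x_folded: float, x_unfolded: float) -> int:
    """Folded <-> unfolded transitions with two-threshold hysteresis."""
    state = 0  # unknown
    count = 0
    for x in np.asarray(x_nm):
        if x < x_folded:
            if state == 2:
                count += 1
            state = 1
        elif x > x_unfolded:
            if state == 1:
                count += 1
            state = 2
    return count


def hopping_thresholds(structure: NativeStructure) -> Tuple[float, float]:
    """Default folded/unfolded x thresholds (nm) for a duplex.

    Folded: within 0.65 nm of the native end-to-end distance (duplex
    intact up to terminal fraying); unfolded: at least 1.0 nm beyond it,
    i.e. the junction has moved one or more base pairs into the duplex
    (one released pair extends x by roughly 1 nm at these forces).
    """
    i, j = structure.pulling_pair
    x0 = float(np.linalg.norm(structure.coords[i] - structure.coords[j])) / 10.0
    return x0 + 0.65, x0 + 1.0


@dataclass
class HoppingReport:
    temperature: float
    occupancies: Dict[float, Tuple[float, float]]
    transitions: Dict[float, int]
    score: Dict[float, float]


def calibrate_hopping(
    topology: Topology,
    structure: NativeStructure,
    f_pn: float,
    t_grid: Sequence[float],
    n_steps: int = 400_000,
    min_transitions: int = 4,
    seed: int = 1,
    config: SimulationConfig | None = None,
) -> Tuple[float, HoppingReport]:
    """Pick the grid temperature giving the most balanced two-state hopping.

    Each grid temperature is scored by the product of folded and
    unfolded occupancies; temperatures with fewer than `min_transitions`
    folded<->unfolded transitions are disqualified.  Ties keep the first
    grid entry.  The first quarter of each scoring run is discarded as
    equilibration - the runs start from the native state, which would
    otherwise bias the folded occupancy and favor too-hot grid points.
    """
    if len(t_grid) == 0:
        raise ValueError("empty temperature grid")
    base = config or SimulationConfig()
    x_lo, x_hi = hopping_thresholds(structure)
    occ: Dict[float, Tuple[float, float]] = {}
    trans: Dict[float, int] = {}
    score: Dict[float, float] = {}
    best_t = None
    best_s = -1.0
    for t in t_grid:
        t = float(t)
        if t in occ:  # duplicate grid entry: first occurrence wins
            continue
        cfg = replace(base, temperature=t, f_pn=f_pn, f_reduced=None, n_steps=n_steps, seed=seed)
        traj = run(topology, cfg, structure=structure)
        burn = traj.n_frames // 4
        of, ou = basin_occupancies(traj.x_nm[burn:], x_lo, x_hi)
        k = transition_count(traj.x_nm[burn:], x_lo, x_hi)
        occ[t], trans[t] = (of, ou), k
        s = of * ou if k >= min_transitions else -1.0
        score[t] = s
        if s > best_s:
            best_s, best_t = s, t
    if best_t is None or best_s <= 0.0:
        raise RuntimeError(
            "no grid temperature produced two-state hopping; widen the grid "
            f"(occupancies: {occ}, transitions: {trans})"
        )
    return best_t, HoppingReport(best_t, occ, trans, score)
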