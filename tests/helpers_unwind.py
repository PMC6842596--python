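"""Shared test utilities: minimal topologies, hand-built state series,
toy free-energy tables."""

import numpy as np
import pandas as pd

from unwindability import junction_states as js
from unwindability import thermo_stats as ts
from unwindability.sbm_forcefield import Topology


def minimal_topology(n_atoms, bonds=(), r0=(), k=()):
    """Bare-bones Hamiltonian (bonds only) for integrator physics tests."""
    nb = len(bonds)
    return Topology(
        n_atoms=n_atoms,
        bonds=np.array(bonds, dtype=np.int64).reshape(nb, 2),
        bond_r0=np.array(r0, dtype=float),
        bond_k=np.array(k, dtype=float),
        angles=np.zeros((0, 3), dtype=np.int64),
        angle_t0=np.zeros(0),
        angle_k=np.zeros(0),
        dihedrals=np.zeros((0, 4), dtype=np.int64),
        dih_phi0=np.zeros(0),
        dih_k1=np.zeros(0),
        dih_k3=np.zeros(0),
        contacts=np.zeros((0, 2), dtype=np.int64),
        contact_sigma=np.zeros(0),
        eps_contact=1.0,
        ev_pairs=np.zeros((0, 2), dtype=np.int64),
        ev_rc=np.zeros(0),
        r_ex=2.5,
        eps_ex=1.0,
        masses=np.ones(n_atoms),
        pulling_pair=(0, n_atoms - 1),
    )


def series_from_states(states, n_pairs=2, window=1, context="GC/CG"):
    """Wrap a junction state sequence as a JunctionStateSeries whose
    pair 1 is the junction and the remaining pairs stay closed."""
    n = len(states)
    pair_states = np.full((n, n_pairs), js.CLOSED, dtype=np.int8)
    pair_states[:, 0] = states
    not_open = pair_states != js.OPEN
    junction = np.where(not_open.any(axis=1), not_open.argmax(axis=1) + 1, n_pairs + 1)
    return js.JunctionStateSeries(
        pair_states=pair_states,
        junction=junction,
        states=np.asarray(states, dtype=np.int8),
        contexts=[context] + [None] * (n_pairs - 1),
        window=window,
        thresholds=js.StateThresholds(),
    )


def uniform_weights(n):
    return ts.FrameWeights(weights=np.full(n, 1.0 / n), beta_f_per_nm=0.0, log_norm=0.0)


def py_favoring_table(g_mag=1.0, nucleic_type="DNA"):
    """Every context's g favors flipping the pyrimidine by g_mag k_BT.

    In a WC pair one base is a purine and the other a pyrimidine, so
    the sign is set by which strand (top = junction 5' terminus)
    carries the pyrimidine of the opening pair."""
    rows = []
    for ctx in ts.all_contexts(nucleic_type):
        top_base = ctx[0]
        g = g_mag if top_base in "CTU" else -g_mag
        rows.append({"context": ctx, "g": g, "se": 0.0, "n5": 1, "n3": 1})
    return ts.NNFreeEnergyTable(pd.DataFrame(rows), nucleic_type)


make_series = series_from_states
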