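"""Go-type Hamiltonian: contact map, native minimum, force correctness."""

import numpy as np
import networkx as nx
import pytest

from unwindability import helix_builder as hb
from unwindability import sbm_forcefield as ff


BACKBONE = {"P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "C1'", "O2'"}


def brute_force_contacts(structure, cutoff, residue_exclusion, adjacent_base):
    """Independent contact-map oracle: exhaustive O(N^2) scan with graph
    distances computed by networkx."""
    bonds = ff.covalent_bonds(structure)
    g = nx.Graph(bonds)
    g.add_nodes_from(range(structure.n_atoms))
    X = structure.coords
    out = set()
    for i in range(structure.n_atoms):
        for j in range(i + 1, structure.n_atoms):
            if np.linalg.norm(X[i] - X[j]) > cutoff:
                continue
            sep = abs(int(structure.res_index[i]) - int(structure.res_index[j]))
            if structure.chain_id[i] == structure.chain_id[j] and sep <= residue_exclusion:
                is_stack = (adjacent_base and sep == 1
                            and structure.atom_names[i] not in BACKBONE
                            and structure.atom_names[j] not in BACKBONE)
                if not is_stack:
                    continue
            try:
                if nx.shortest_path_length(g, i, j) <= 3:
                    continue
            except nx.NetworkXNoPath:
                pass
            out.add((i, j))
    return out


@pytest.mark.parametrize("cutoff,rex,adj", [(4.5, 1, True), (4.5, 1, False), (4.0, 0, False)])
def test_contact_map_matches_brute_force(cutoff, rex, adj):
    s = hb.build_duplex("GCGC", "RNA")
    got = set(ff.contact_map(s, cutoff, rex, adjacent_base_contacts=adj))
    assert got == brute_force_contacts(s, cutoff, rex, adj)


def test_contact_map_rejects_bad_cutoff(rna_hexamer):
    with pytest.raises(ValueError):
        ff.contact_map(rna_hexamer, -1.0)


def test_native_is_stationary_point(rna_topology, rna_hexamer):
    e, F = ff.energy_forces(rna_topology, rna_hexamer.coords)
    assert np.abs(F).max() <= 1e-6
    assert e.contact == pytest.approx(-rna_topology.eps_contact * len(rna_topology.contacts))
    assert e.bond == pytest.approx(0.0, abs=1e-12)
    assert e.excluded == pytest.approx(0.0, abs=1e-12)


def test_native_is_local_minimum(rna_topology, rna_hexamer):
    e0, _ = ff.energy_forces(rna_topology, rna_hexamer.coords)
    for k in range(20):
        rng = np.random.default_rng(k)
        X = rna_hexamer.coords + 0.1 * rng.standard_normal(rna_hexamer.coords.shape)
        e, _ = ff.energy_forces(rna_topology, X)
        assert e.total > e0.total


def test_forces_match_finite_differences(rna_topology, rna_hexamer, rng):
    h = 1e-6
    X = rna_hexamer.coords + 0.08 * rng.standard_normal(rna_hexamer.coords.shape)
    _, F = ff.energy_forces(rna_topology, X, f_c=0.3)
    for _ in range(40):
        i = int(rng.integers(0, rna_topology.n_atoms))
        d = int(rng.integers(0, 3))
        Xp, Xm = X.copy(), X.copy()
        Xp[i, d] += h
        Xm[i, d] -= h
        ep, _ = ff.energy_forces(rna_topology, Xp, f_c=0.3)
        em, _ = ff.energy_forces(rna_topology, Xm, f_c=0.3)
        fd = -(ep.total - em.total) / (2 * h)
        assert fd == pytest.approx(F[i, d], rel=1e-4, abs=1e-4)


def test_rigid_body_invariance(rna_topology, rna_hexamer, rng):
    from scipy.spatial.transform import Rotation

    X = rna_hexamer.coords + 0.05 * rng.standard_normal(rna_hexamer.coords.shape)
    e0, F0 = ff.energy_forces(rna_topology, X)
    R = Rotation.random(random_state=7).as_matrix()
    e1, _ = ff.energy_forces(rna_topology, X @ R.T + np.array([5.0, -3.0, 2.0]))
    assert e1.total == pytest.approx(e0.total, abs=1e-9)
    assert np.abs(F0.sum(axis=0)).max() <= 1e-9
    assert np.abs(np.cross(X, F0).sum(axis=0)).max() <= 1e-8


def test_pulling_term_equal_and_opposite(rna_topology, rna_hexamer):
    i, j = rna_topology.pulling_pair
    e0, F0 = ff.energy_forces(rna_topology, rna_hexamer.coords, f_c=0.0)
    e1, F1 = ff.energy_forces(rna_topology, rna_hexamer.coords, f_c=0.5)
    dF = F1 - F0
    u = rna_hexamer.coords[i] - rna_hexamer.coords[j]
    u /= np.linalg.norm(u)
    assert np.allclose(dF[i], 0.5 * u, atol=1e-12)
    assert np.allclose(dF[j], -0.5 * u, atol=1e-12)
    others = np.delete(dF, [i, j], axis=0)
    assert np.abs(others).max() == 0.0


def test_harmonic_bond_closed_form():
    """An isolated stretched bond has energy k_b * delta^2."""
    s = hb.build_duplex("GC", "RNA")
    top = ff.build_topology(s)
    b = 0
    i, j = top.bonds[b]
    X = s.coords.copy()
    u = (X[j] - X[i]) / np.linalg.norm(X[j] - X[i])
    delta = 0.05
    X[j] += delta * u
    # isolate the bond by zeroing everything else
    import copy

    t = copy.deepcopy(top)
    t.angle_k[:] = 0.0
    t.dih_k1[:] = 0.0
    t.dih_k3[:] = 0.0
    t.eps_contact = 0.0
    t.eps_ex = 0.0
    t.bond_k[:] = 0.0
    t.bond_k[b] = top.params.k_bond
    e, _ = ff.energy_forces(t, X)
    assert e.total == pytest.approx(top.params.k_bond * delta**2, rel=1e-9)


def test_strand_separability(rna_topology, rna_hexamer):
    """Without interstrand contacts, rigidly separated strands remain at
    an energy minimum (intra-strand native structure intact)."""
    import copy

    s = rna_hexamer
    chain_of = np.array([0 if c == "A" else 1 for c in s.chain_id])
    keep = chain_of[rna_topology.contacts[:, 0]] == chain_of[rna_topology.contacts[:, 1]]
    t = copy.deepcopy(rna_topology)
    t.contacts = t.contacts[keep]
    t.contact_sigma = t.contact_sigma[keep]
    X = s.coords.copy()
    X[chain_of == 1] += np.array([60.0, 0.0, 0.0])
    e, F = ff.energy_forces(t, X)
    assert np.abs(F).max() <= 1e-6
    assert e.bond == pytest.approx(0.0, abs=1e-12)


def test_topology_json_round_trip(rna_topology):
    back = ff.Topology.from_json(rna_topology.to_json())
    assert back.n_atoms == rna_topology.n_atoms
    assert np.array_equal(back.contacts, rna_topology.contacts)
    assert np.allclose(back.dih_phi0, rna_topology.dih_phi0)
    assert back.pulling_pair == rna_topology.pulling_pair
    # evaluating both on identical coordinates gives identical results
    X = np.random.default_rng(5).standard_normal((rna_topology.n_atoms, 3)) * 40
    ea, Fa = ff.energy_forces(rna_topology, X)
    eb, Fb = ff.energy_forces(back, X)
    assert ea.total == pytest.approx(eb.total)
    assert np.allclose(Fa, Fb)


def test_force_unit_conversion():
    # 14 pN at the 296 K mapping is 3.42 kBT/nm = 0.342 kBT/A
    assert ff.force_pn_to_reduced(14.0, 1.0) == pytest.approx(0.342, abs=0.001)
    assert ff.force_pn_to_reduced(14.0, 2.0) / 2.0 == pytest.approx(0.342, abs=0.001)
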