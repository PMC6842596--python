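"""Structure-based (Go-type) all-heavy-atom Hamiltonian for duplexes.

The native structure defines the energy minimum: harmonic bonds and
angles at their native values, cosine dihedrals (periodicities 1 and 3)
with native phases, 12-6 Lennard-Jones native contacts with the minimum
at the native separation, and a purely repulsive excluded-volume wall
for every other nonbonded pair.  The excluded-volume term is
force-shifted to vanish at its cutoff and the per-pair cutoff never
exceeds the pair's native separation, so the native configuration is an
exact stationary point of the total potential.

Reduced units: the contact well depth eps_c defines the energy unit,
lengths in Angstrom, all masses 1, k_B = 1.  The only physical-unit
interface is the pulling force: f_C = 14 pN corresponds to
3.42 k_BT/nm at 296 K (k_BT = 4.09 pN nm), so beta*f_C is fixed in
1/Angstrom regardless of the reduced simulation temperature.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from numba import njit

from .helix_builder import NativeStructure

__all__ = [
    "FFParams",
    "Topology",
    "EnergyBreakdown",
    "contact_map",
    "build_topology",
    "energy_forces",
    "force_pn_to_reduced",
    "KBT_PN_NM_296K",
]

#: k_B T at 296 K in pN nm
KBT_PN_NM_296K = 4.09


def force_pn_to_reduced(f_pn: float, temperature: float) -> float:
    """Convert a pulling force in pN to reduced energy / Angstrom.

    The reduced temperature is taken to represent 296 K, so
    beta * f is always (f_pn / 40.9) per Angstrom.
    """
    return f_pn / (KBT_PN_NM_296K * 10.0) * temperature


@dataclass(frozen=True)
class FFParams:
    """Force-field stiffnesses and contact-map settings (reduced units)."""

    k_bond: float = 100.0  # eps / A^2
    k_angle: float = 40.0  # eps / rad^2
    k_dih1: float = 1.0
    k_dih3: float = 0.5
    eps_contact: float = 1.0
    eps_ex: float = 1.0
    r_ex: float = 2.5  # excluded-volume radius, A
    ev_cutoff: float = 4.0  # max range of the repulsive wall, A
    contact_cutoff: float = 4.5  # heavy-atom contact distance, A
    residue_exclusion: int = 1  # same-chain pairs with |i-j| <= this get no contact
    adjacent_base_contacts: bool = True  # keep base-base stacking contacts of
    # neighboring residues despite the exclusion window (the stacking
    # interactions carry the purine/pyrimidine junction asymmetry)


@dataclass
class EnergyBreakdown:
    bond: float
    angle: float
    dihedral: float
    contact: float
    excluded: float
    pulling: float

    @property
    def total(self) -> float:
        return self.bond + self.angle + self.dihedral + self.contact + self.excluded + self.pulling


@dataclass
class Topology:
    """Complete Hamiltonian specification derived from a native structure."""

    n_atoms: int
    bonds: np.ndarray  # (nb, 2) int
    bond_r0: np.ndarray
    bond_k: np.ndarray
    angles: np.ndarray  # (na, 3) int
    angle_t0: np.ndarray
    angle_k: np.ndarray
    dihedrals: np.ndarray  # (nd, 4) int
    dih_phi0: np.ndarray
    dih_k1: np.ndarray
    dih_k3: np.ndarray
    contacts: np.ndarray  # (nc, 2) int
    contact_sigma: np.ndarray  # native separations
    eps_contact: float
    ev_pairs: np.ndarray  # (ne, 2) int, all repulsive-only pairs
    ev_rc: np.ndarray  # per-pair wall cutoff
    r_ex: float
    eps_ex: float
    masses: np.ndarray
    pulling_pair: Tuple[int, int]
    params: FFParams = field(default_factory=FFParams)

    def to_json(self) -> str:
        d = {
            "n_atoms": self.n_atoms,
            "bonds": self.bonds.tolist(),
            "bond_r0": self.bond_r0.tolist(),
            "bond_k": self.bond_k.tolist(),
            "angles": self.angles.tolist(),
            "angle_t0": self.angle_t0.tolist(),
            "angle_k": self.angle_k.tolist(),
            "dihedrals": self.dihedrals.tolist(),
            "dih_phi0": self.dih_phi0.tolist(),
            "dih_k1": self.dih_k1.tolist(),
            "dih_k3": self.dih_k3.tolist(),
            "contacts": self.contacts.tolist(),
            "contact_sigma": self.contact_sigma.tolist(),
            "eps_contact": self.eps_contact,
            "ev_pairs": self.ev_pairs.tolist(),
            "ev_rc": self.ev_rc.tolist(),
            "r_ex": self.r_ex,
            "eps_ex": self.eps_ex,
            "masses": self.masses.tolist(),
            "pulling_pair": list(self.pulling_pair),
            "params": asdict(self.params),
        }
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "Topology":
        d = json.loads(text)
        return cls(
            n_atoms=d["n_atoms"],
            bonds=np.array(d["bonds"], dtype=np.int64).reshape(-1, 2),
            bond_r0=np.array(d["bond_r0"]),
            bond_k=np.array(d["bond_k"]),
            angles=np.array(d["angles"], dtype=np.int64).reshape(-1, 3),
            angle_t0=np.array(d["angle_t0"]),
            angle_k=np.array(d["angle_k"]),
            dihedrals=np.array(d["dihedrals"], dtype=np.int64).reshape(-1, 4),
            dih_phi0=np.array(d["dih_phi0"]),
            dih_k1=np.array(d["dih_k1"]),
            dih_k3=np.array(d["dih_k3"]),
            contacts=np.array(d["contacts"], dtype=np.int64).reshape(-1, 2),
            contact_sigma=np.array(d["contact_sigma"]),
            eps_contact=d["eps_contact"],
            ev_pairs=np.array(d["ev_pairs"], dtype=np.int64).reshape(-1, 2),
            ev_rc=np.array(d["ev_rc"]),
            r_ex=d["r_ex"],
            eps_ex=d["eps_ex"],
            masses=np.array(d["masses"]),
            pulling_pair=tuple(d["pulling_pair"]),
            params=FFParams(**d["params"]),
        )


# ---------------------------------------------------------------------------
# covalent topology
# ---------------------------------------------------------------------------

_BACKBONE_BONDS = [
    ("P", "OP1"), ("P", "OP2"), ("P", "O5'"), ("O5'", "C5'"), ("C5'", "C4'"),
    ("C4'", "O4'"), ("C4'", "C3'"), ("C3'", "O3'"), ("C3'", "C2'"),
    ("C2'", "C1'"), ("C1'", "O4'"), ("C2'", "O2'"),
]

_BASE_BONDS = {
    "pur": [("N9", "C8"), ("C8", "N7"), ("N7", "C5"), ("C5", "C6"), ("C6", "N1"),
            ("N1", "C2"), ("C2", "N3"), ("N3", "C4"), ("C4", "C5"), ("C4", "N9"),
            ("C1'", "N9")],
    "pyr": [("N1", "C2"), ("C2", "N3"), ("N3", "C4"), ("C4", "C5"), ("C5", "C6"),
            ("C6", "N1"), ("C2", "O2"), ("C1'", "N1")],
}
_EXO_BONDS = {"A": [("C6", "N6")], "G": [("C6", "O6"), ("C2", "N2")],
              "C": [("C4", "N4")], "T": [("C4", "O4"), ("C5", "C7")], "U": [("C4", "O4")]}


def covalent_bonds(structure: NativeStructure) -> List[Tuple[int, int]]:
    """Bond list (atom index pairs) from the standard nucleotide chemistry."""
    bonds: List[Tuple[int, int]] = []

    def maybe(chain: str, resi: int, a: str, b: str) -> None:
        try:
            bonds.append((structure.atom(chain, resi, a), structure.atom(chain, resi, b)))
        except KeyError:
            pass

    n = structure.n_pairs
    for chain, seq in (("A", structure.seq1), ("B", structure.seq2)):
        for resi, code in enumerate(seq, start=1):
            for a, b in _BACKBONE_BONDS:
                maybe(chain, resi, a, b)
            kind = "pur" if code in ("A", "G") else "pyr"
            for a, b in _BASE_BONDS[kind]:
                maybe(chain, resi, a, b)
            for a, b in _EXO_BONDS[code]:
                maybe(chain, resi, a, b)
            if resi < n:
                bonds.append((structure.atom(chain, resi, "O3'"), structure.atom(chain, resi + 1, "P")))
    # dedupe / orient
    seen = set()
    out = []
    for i, j in bonds:
        key = (min(i, j), max(i, j))
        if key not in seen:
            seen.add(key)
            out.append(key)
    return out


def _adjacency(n_atoms: int, bonds: Sequence[Tuple[int, int]]) -> List[List[int]]:
    adj: List[List[int]] = [[] for _ in range(n_atoms)]
    for i, j in bonds:
        adj[i].append(j)
        adj[j].append(i)
    for a in adj:
        a.sort()
    return adj


def _angles_from_bonds(adj: List[List[int]]) -> List[Tuple[int, int, int]]:
    out = []
    for j, nbrs in enumerate(adj):
        for ai in range(len(nbrs)):
            for bi in range(ai + 1, len(nbrs)):
                out.append((nbrs[ai], j, nbrs[bi]))
    return out


def _dihedrals_from_bonds(adj: List[List[int]], bonds: Sequence[Tuple[int, int]]) -> List[Tuple[int, int, int, int]]:
    """One proper dihedral per central bond (lowest-index flanking atoms)."""
    out = []
    for j, k in bonds:
        cand_i = [a for a in adj[j] if a != k]
        cand_l = [a for a in adj[k] if a != j]
        if cand_i and cand_l:
            i, l = cand_i[0], cand_l[0]
            if i != l:
                out.append((i, j, k, l))
    return out


def _bonded_exclusions(adj: List[List[int]]) -> set:
    """Pairs within three bonds of each other (1-2, 1-3, 1-4)."""
    excl = set()
    n = len(adj)
    for i in range(n):
        frontier = {i}
        seen = {i}
        for _ in range(3):
            nxt = set()
            for a in frontier:
                for b in adj[a]:
                    if b not in seen:
                        nxt.add(b)
            for b in nxt:
                excl.add((min(i, b), max(i, b)))
            seen |= nxt
            frontier = nxt
    return excl


_BACKBONE_NAMES = {"P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "C1'", "O2'"}


def _is_base_atom(name: str) -> bool:
    return name not in _BACKBONE_NAMES


def contact_map(
    structure: NativeStructure,
    cutoff: float = 4.5,
    residue_exclusion: int = 1,
    bonds: Sequence[Tuple[int, int]] | None = None,
    adjacent_base_contacts: bool = True,
) -> List[Tuple[int, int]]:
    """Native-contact pairs: heavy atoms within `cutoff` in the native
    state, excluding bonded-topology neighbors (up to 1-4) and same-chain
    pairs separated by `residue_exclusion` residues or fewer.

    With adjacent_base_contacts, base-base pairs of directly neighboring
    residues are kept despite the exclusion window: these are the
    stacking interactions of the junction bases, without which the
    sequence dependence of base-pair opening is lost.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if bonds is None:
        bonds = covalent_bonds(structure)
    adj = _adjacency(structure.n_atoms, bonds)
    excl = _bonded_exclusions(adj)
    X = structure.coords
    n = structure.n_atoms
    chain = structure.chain_id
    resi = structure.res_index
    names = structure.atom_names
    out = []
    d2max = cutoff * cutoff
    for i in range(n):
        di = X[i + 1:] - X[i]
        d2 = np.einsum("ij,ij->i", di, di)
        for off in np.nonzero(d2 <= d2max)[0]:
            j = i + 1 + off
            sep = abs(int(resi[i]) - int(resi[j]))
            if chain[i] == chain[j] and sep <= residue_exclusion:
                stacking = (
                    adjacent_base_contacts
                    and sep == 1
                    and _is_base_atom(names[i])
                    and _is_base_atom(names[j])
                )
                if not stacking:
                    continue
            if (i, j) in excl:
                continue
            out.append((i, j))
    return out


def build_topology(structure: NativeStructure, params: FFParams | None = None) -> Topology:
    """Assemble the complete structure-based Hamiltonian.

    The native configuration is an exact stationary point: every bonded
    term takes its native value, each contact LJ well has its minimum at
    the native separation, and the excluded-volume wall is cut off at
    (at most) each pair's native distance with a force-shifted form.
    """
    if params is None:
        params = FFParams()
    X = structure.coords
    n = structure.n_atoms
    bonds = covalent_bonds(structure)
    adj = _adjacency(n, bonds)
    # connectivity check per strand
    for chain in ("A", "B"):
        idx = [i for i in range(n) if structure.chain_id[i] == chain]
        seen = {idx[0]}
        stack = [idx[0]]
        while stack:
            a = stack.pop()
            for b in adj[a]:
                if b not in seen and structure.chain_id[b] == chain:
                    seen.add(b)
                    stack.append(b)
        if len(seen) != len(idx):
            raise ValueError(f"disconnected covalent graph within chain {chain}")

    angles = _angles_from_bonds(adj)
    dihedrals = _dihedrals_from_bonds(adj, bonds)
    contacts = contact_map(structure, params.contact_cutoff, params.residue_exclusion, bonds,
                           params.adjacent_base_contacts)
    excl = _bonded_exclusions(adj)
    for i, j in bonds:
        excl.add((min(i, j), max(i, j)))
    contact_set = set(contacts)

    barr = np.array(bonds, dtype=np.int64)
    bond_r0 = np.linalg.norm(X[barr[:, 0]] - X[barr[:, 1]], axis=1)
    aarr = np.array(angles, dtype=np.int64)
    angle_t0 = np.array([_angle(X[i], X[j], X[k]) for i, j, k in angles])
    darr = np.array(dihedrals, dtype=np.int64).reshape(-1, 4)
    dih_phi0 = np.array([_dihedral(X[i], X[j], X[k], X[l]) for i, j, k, l in dihedrals])
    carr = np.array(contacts, dtype=np.int64).reshape(-1, 2)
    contact_sigma = np.linalg.norm(X[carr[:, 0]] - X[carr[:, 1]], axis=1) if len(contacts) else np.zeros(0)

    ev = []
    ev_rc = []
    for i in range(n):
        d = np.linalg.norm(X[i + 1:] - X[i], axis=1)
        for off in range(len(d)):
            j = i + 1 + off
            key = (i, j)
            if key in excl or key in contact_set:
                continue
            ev.append(key)
            ev_rc.append(min(params.ev_cutoff, d[off]))
    return Topology(
        n_atoms=n,
        bonds=barr,
        bond_r0=bond_r0,
        bond_k=np.full(len(bonds), params.k_bond),
        angles=aarr,
        angle_t0=angle_t0,
        angle_k=np.full(len(angles), params.k_angle),
        dihedrals=darr,
        dih_phi0=dih_phi0,
        dih_k1=np.full(len(dihedrals), params.k_dih1),
        dih_k3=np.full(len(dihedrals), params.k_dih3),
        contacts=carr,
        contact_sigma=contact_sigma,
        eps_contact=params.eps_contact,
        ev_pairs=np.array(ev, dtype=np.int64).reshape(-1, 2),
        ev_rc=np.array(ev_rc),
        r_ex=params.r_ex,
        eps_ex=params.eps_ex,
        masses=np.ones(n),
        pulling_pair=structure.pulling_pair,
        params=params,
    )


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    u, v = a - b, c - b
    cos = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.acos(max(-1.0, min(1.0, cos)))


def _dihedral(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> float:
    b1, b2, b3 = b - a, c - b, d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    return math.atan2(np.dot(m, n2), np.dot(n1, n2))


# ---------------------------------------------------------------------------
# numba force kernel
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=False)
def _eval_forces(
    X, bonds, bond_r0, bond_k, angles, angle_t0, angle_k,
    dihedrals, dih_phi0, dih_k1, dih_k3, contacts, contact_sigma, eps_c,
    ev_pairs, ev_rc, r_ex, eps_ex, pull_i, pull_j, f_c, F,
    ev_sel,
):
    """Accumulate forces into F; returns the six energy components.

    ev_sel restricts the excluded-volume evaluation to a subset of pair
    rows (the engine's neighbor list); pass arange(n_ev) to use all.
    """
    e_bond = 0.0
    for b in range(bonds.shape[0]):
        i, j = bonds[b, 0], bonds[b, 1]
        dx = X[i, 0] - X[j, 0]
        dy = X[i, 1] - X[j, 1]
        dz = X[i, 2] - X[j, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - bond_r0[b]
        e_bond += bond_k[b] * dr * dr
        fmag = -2.0 * bond_k[b] * dr / r
        F[i, 0] += fmag * dx
        F[i, 1] += fmag * dy
        F[i, 2] += fmag * dz
        F[j, 0] -= fmag * dx
        F[j, 1] -= fmag * dy
        F[j, 2] -= fmag * dz

    e_angle = 0.0
    for a in range(angles.shape[0]):
        i, j, k = angles[a, 0], angles[a, 1], angles[a, 2]
        ux, uy, uz = X[i, 0] - X[j, 0], X[i, 1] - X[j, 1], X[i, 2] - X[j, 2]
        vx, vy, vz = X[k, 0] - X[j, 0], X[k, 1] - X[j, 1], X[k, 2] - X[j, 2]
        ru = math.sqrt(ux * ux + uy * uy + uz * uz)
        rv = math.sqrt(vx * vx + vy * vy + vz * vz)
        c = (ux * vx + uy * vy + uz * vz) / (ru * rv)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        th = math.acos(c)
        dth = th - angle_t0[a]
        e_angle += angle_k[a] * dth * dth
        s = math.sqrt(1.0 - c * c)
        if s < 1e-8:
            s = 1e-8
        coef = -2.0 * angle_k[a] * dth / s  # dV/dcos(theta) factor applied below
        # d cos / d r_i = (v/|u||v| - cos * u/|u|^2)
        gix = coef * -(vx / (ru * rv) - c * ux / (ru * ru))
        giy = coef * -(vy / (ru * rv) - c * uy / (ru * ru))
        giz = coef * -(vz / (ru * rv) - c * uz / (ru * ru))
        gkx = coef * -(ux / (ru * rv) - c * vx / (rv * rv))
        gky = coef * -(uy / (ru * rv) - c * vy / (rv * rv))
        gkz = coef * -(uz / (ru * rv) - c * vz / (rv * rv))
        F[i, 0] += gix
        F[i, 1] += giy
        F[i, 2] += giz
        F[k, 0] += gkx
        F[k, 1] += gky
        F[k, 2] += gkz
        F[j, 0] -= gix + gkx
        F[j, 1] -= giy + gky
        F[j, 2] -= giz + gkz

    e_dih = 0.0
    for d in range(dihedrals.shape[0]):
        i, j, k, l = dihedrals[d, 0], dihedrals[d, 1], dihedrals[d, 2], dihedrals[d, 3]
        b1x, b1y, b1z = X[j, 0] - X[i, 0], X[j, 1] - X[i, 1], X[j, 2] - X[i, 2]
        b2x, b2y, b2z = X[k, 0] - X[j, 0], X[k, 1] - X[j, 1], X[k, 2] - X[j, 2]
        b3x, b3y, b3z = X[l, 0] - X[k, 0], X[l, 1] - X[k, 1], X[l, 2] - X[k, 2]
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        rb2 = math.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        mx = n1y * b2z - n1z * b2y
        my = n1z * b2x - n1x * b2z
        mz = n1x * b2y - n1y * b2x
        y = (mx * n2x + my * n2y + mz * n2z) / rb2
        x = n1x * n2x + n1y * n2y + n1z * n2z
        phi = math.atan2(y, x)
        dphi = phi - dih_phi0[d]
        e_dih += dih_k1[d] * (1.0 - math.cos(dphi)) + dih_k3[d] * (1.0 - math.cos(3.0 * dphi))
        dV = dih_k1[d] * math.sin(dphi) + 3.0 * dih_k3[d] * math.sin(3.0 * dphi)
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        if n1sq < 1e-12 or n2sq < 1e-12:
            continue
        fix = -dV * rb2 / n1sq * n1x
        fiy = -dV * rb2 / n1sq * n1y
        fiz = -dV * rb2 / n1sq * n1z
        flx = dV * rb2 / n2sq * n2x
        fly = dV * rb2 / n2sq * n2y
        flz = dV * rb2 / n2sq * n2z
        t = (b1x * b2x + b1y * b2y + b1z * b2z) / (rb2 * rb2)
        s = (b3x * b2x + b3y * b2y + b3z * b2z) / (rb2 * rb2)
        fjx = -(1.0 + t) * fix + s * flx
        fjy = -(1.0 + t) * fiy + s * fly
        fjz = -(1.0 + t) * fiz + s * flz
        fkx = t * fix - (1.0 + s) * flx
        fky = t * fiy - (1.0 + s) * fly
        fkz = t * fiz - (1.0 + s) * flz
        F[i, 0] += fix
        F[i, 1] += fiy
        F[i, 2] += fiz
        F[j, 0] += fjx
        F[j, 1] += fjy
        F[j, 2] += fjz
        F[k, 0] += fkx
        F[k, 1] += fky
        F[k, 2] += fkz
        F[l, 0] += flx
        F[l, 1] += fly
        F[l, 2] += flz

    e_cont = 0.0
    for cix in range(contacts.shape[0]):
        i, j = contacts[cix, 0], contacts[cix, 1]
        dx = X[i, 0] - X[j, 0]
        dy = X[i, 1] - X[j, 1]
        dz = X[i, 2] - X[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        s2 = contact_sigma[cix] * contact_sigma[cix] / r2
        s6 = s2 * s2 * s2
        s12 = s6 * s6
        e_cont += eps_c * (s12 - 2.0 * s6)
        fmag = eps_c * 12.0 * (s12 - s6) / r2
        F[i, 0] += fmag * dx
        F[i, 1] += fmag * dy
        F[i, 2] += fmag * dz
        F[j, 0] -= fmag * dx
        F[j, 1] -= fmag * dy
        F[j, 2] -= fmag * dz

    e_ev = 0.0
    for pp in range(ev_sel.shape[0]):
        p = ev_sel[pp]
        i, j = ev_pairs[p, 0], ev_pairs[p, 1]
        rc = ev_rc[p]
        dx = X[i, 0] - X[j, 0]
        dy = X[i, 1] - X[j, 1]
        dz = X[i, 2] - X[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rc * rc:
            continue
        r = math.sqrt(r2)
        if r < 1e-6:
            r = 1e-6
        sr = r_ex / r
        sr12 = sr ** 12
        src = r_ex / rc
        src12 = src ** 12
        slope = 12.0 * eps_ex * src12 / rc
        e_ev += eps_ex * (sr12 - src12) + slope * (r - rc)
        fmag = (12.0 * eps_ex * sr12 / r - slope) / r
        F[i, 0] += fmag * dx
        F[i, 1] += fmag * dy
        F[i, 2] += fmag * dz
        F[j, 0] -= fmag * dx
        F[j, 1] -= fmag * dy
        F[j, 2] -= fmag * dz

    e_pull = 0.0
    if f_c != 0.0:
        dx = X[pull_i, 0] - X[pull_j, 0]
        dy = X[pull_i, 1] - X[pull_j, 1]
        dz = X[pull_i, 2] - X[pull_j, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        e_pull = -f_c * r
        fmag = f_c / r
        F[pull_i, 0] += fmag * dx
        F[pull_i, 1] += fmag * dy
        F[pull_i, 2] += fmag * dz
        F[pull_j, 0] -= fmag * dx
        F[pull_j, 1] -= fmag * dy
        F[pull_j, 2] -= fmag * dz

    return e_bond, e_angle, e_dih, e_cont, e_ev, e_pull


def energy_forces(
    topology: Topology, coords: np.ndarray, f_c: float = 0.0
) -> Tuple[EnergyBreakdown, np.ndarray]:
    """Total potential energy breakdown and per-atom forces.

    f_c is the constant pulling force in reduced energy/Angstrom acting
    to increase the attachment-pair distance (potential -f_c * x).
    """
    X = np.ascontiguousarray(coords, dtype=np.float64)
    if X.shape != (topology.n_atoms, 3):
        raise ValueError(f"coordinate shape {X.shape} does not match topology ({topology.n_atoms}, 3)")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite coordinates")
    F = np.zeros_like(X)
    eb, ea, ed, ec, ee, ep = _eval_forces(
        X, topology.bonds, topology.bond_r0, topology.bond_k,
        topology.angles, topology.angle_t0, topology.angle_k,
        topology.dihedrals, topology.dih_phi0, topology.dih_k1, topology.dih_k3,
        topology.contacts, topology.contact_sigma, topology.eps_contact,
        topology.ev_pairs, topology.ev_rc, topology.r_ex, topology.eps_ex,
        topology.pulling_pair[0], topology.pulling_pair[1], f_c, F,
        np.arange(topology.ev_pairs.shape[0], dtype=np.int64),
    )
    return EnergyBreakdown(eb, ea, ed, ec, ee, ep), F
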