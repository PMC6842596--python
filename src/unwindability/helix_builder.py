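"""Idealized A-form and B-form nucleic-acid duplex construction.

Builds all-heavy-atom native structures of short double helices from
sequence alone.  Bases are planar idealized rings placed in a canonical
Watson-Crick pair frame; the sugar-phosphate backbone is generated so
that the covalent O3'(i)-P(i+1) linkage is consistent with the helical
twist and rise.  The resulting geometry is deliberately simple - no
propeller twist, sugar pucker or sequence-dependent fine structure - but
it is self-consistent, which is all a structure-based (Go-type)
Hamiltonian requires of its reference state.

Conventions
-----------
* Coordinates in Angstrom, right-handed helix axis along +z.
* Chain 1 ("A") is the strand whose 5' end sits at base-pair 1, the end
  where the pulling attachments (terminal hydroxyl oxygens) live.
* Residue i of chain 1 pairs with residue N+1-i of chain 2 ("B").
* The pair reference point is the midpoint of the two glycosidic C1'
  atoms; consecutive reference points are separated by exactly the
  configured rise along the helix axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

__all__ = [
    "HelixParameters",
    "NativeStructure",
    "A_FORM",
    "B_FORM",
    "reverse_complement",
    "build_duplex",
    "write_pdb",
    "read_pdb",
]

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T", "U"}
DNA_ALPHABET = {"A", "C", "G", "T"}
RNA_ALPHABET = {"A", "C", "G", "U"}
_COMPLEMENT_DNA = {"A": "T", "T": "A", "C": "G", "G": "C"}
_COMPLEMENT_RNA = {"A": "U", "U": "A", "C": "G", "G": "C"}

#: heavy atoms forming the aromatic ring(s); used for base centroids
RING_ATOMS = {
    "A": ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"),
    "G": ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"),
    "C": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "T": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "U": ("N1", "C2", "N3", "C4", "C5", "C6"),
}

#: Watson-Crick donor/acceptor heavy atom used to detect pairing
WC_ATOM = {"A": "N1", "G": "N1", "C": "N3", "T": "N3", "U": "N3"}

#: glycosidic base nitrogen
GLYCOSIDIC_N = {"A": "N9", "G": "N9", "C": "N1", "T": "N1", "U": "N1"}

_RING_BOND = 1.38  # aromatic C-C/C-N bond length
_EXO_BOND = 1.30  # exocyclic substituent bond length
_GLYC_BOND = 1.47  # C1'-N glycosidic bond
_WC_DIST = 2.90  # N1(purine)...N3(pyrimidine) heavy-atom distance
_O3P_BOND = 1.60  # inter-residue O3'-P linkage


@dataclass(frozen=True)
class HelixParameters:
    """Rigid-body helicoidal parameters of an ideal duplex.

    twist_deg   : helical twist per base-pair step (degrees, >0, <=60)
    rise        : axial translation per step (Angstrom)
    x_disp      : displacement of the pair frame along its x axis
                  (+x points into the major groove); large negative
                  values push the pairs off-axis as in A-form helices
    inclination_deg : rotation of the pair plane about the pair long
                  axis; nonzero in A-form
    """

    form: str
    twist_deg: float
    rise: float
    x_disp: float = 0.0
    inclination_deg: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.twist_deg <= 60.0):
            raise ValueError(f"twist must be in (0, 60] deg, got {self.twist_deg}")
        if not (2.0 < self.rise < 4.0):
            raise ValueError(f"rise must be in (2, 4) Angstrom, got {self.rise}")
        if self.form not in ("A", "B"):
            raise ValueError(f"form must be 'A' or 'B', got {self.form!r}")


# Fiber-diffraction-style defaults.  The A-form x-displacement buries the
# base pairs on the major-groove side of the axis, which is what makes
# 5'-junction bases less enclosed than their 3' partners.
A_FORM = HelixParameters(form="A", twist_deg=32.7, rise=2.81, x_disp=-4.4, inclination_deg=19.0)
B_FORM = HelixParameters(form="B", twist_deg=36.0, rise=3.38, x_disp=0.0, inclination_deg=0.0)

DEFAULT_PARAMS = {"A": A_FORM, "B": B_FORM}


def reverse_complement(sequence: str, nucleic_type: str) -> str:
    """Watson-Crick reverse complement, 5'->3' in and out."""
    if not sequence:
        raise ValueError("empty sequence")
    nt = nucleic_type.upper()
    if nt == "DNA":
        table, alphabet = _COMPLEMENT_DNA, DNA_ALPHABET
    elif nt == "RNA":
        table, alphabet = _COMPLEMENT_RNA, RNA_ALPHABET
    else:
        raise ValueError(f"nucleic_type must be DNA or RNA, got {nucleic_type!r}")
    seq = sequence.upper()
    bad = set(seq) - alphabet
    if bad:
        raise ValueError(f"invalid {nt} characters: {sorted(bad)}")
    return "".join(table[c] for c in reversed(seq))


# ---------------------------------------------------------------------------
# planar base templates
# ---------------------------------------------------------------------------


def _hexagon(center: np.ndarray, angles_deg: Dict[str, float], radius: float = _RING_BOND) -> Dict[str, np.ndarray]:
    out = {}
    for name, ang in angles_deg.items():
        a = math.radians(ang)
        out[name] = center + radius * np.array([math.cos(a), math.sin(a), 0.0])
    return out


def _build_pyrimidine(code: str) -> Dict[str, np.ndarray]:
    """Pyrimidine on the +y side of the pair frame, N3 facing the partner."""
    center = np.array([0.0, _WC_DIST / 2 + _RING_BOND, 0.0])
    ring = _hexagon(center, {"N1": 150, "C2": 210, "N3": 270, "C4": 330, "C5": 30, "C6": 90})
    atoms = dict(ring)

    def exo(name: str, host: str) -> None:
        d = (ring[host] - center) / _RING_BOND
        atoms[name] = ring[host] + _EXO_BOND * d

    exo("O2", "C2")
    if code == "C":
        exo("N4", "C4")
    elif code in ("T", "U"):
        exo("O4", "C4")
        if code == "T":
            exo("C7", "C5")
    return atoms


def _build_purine(code: str) -> Dict[str, np.ndarray]:
    """Purine on the -y side of the pair frame, N1 facing the partner."""
    center = np.array([0.0, -(_WC_DIST / 2 + _RING_BOND), 0.0])
    ring = _hexagon(center, {"N1": 90, "C2": 150, "N3": 210, "C4": 270, "C5": 330, "C6": 30})
    # five-membered ring fused on the C4-C5 edge, pointing away from the
    # six-ring center
    c4, c5 = ring["C4"], ring["C5"]
    mid = 0.5 * (c4 + c5)
    edge = c5 - c4
    normal = np.array([edge[1], -edge[0], 0.0]) / np.linalg.norm(edge)
    if np.dot(normal, mid - center) < 0:
        normal = -normal
    apothem = _RING_BOND / (2 * math.tan(math.pi / 5))
    circum = _RING_BOND / (2 * math.sin(math.pi / 5))
    pcen = mid + apothem * normal
    ang4 = math.atan2(c4[1] - pcen[1], c4[0] - pcen[0])
    ang5 = math.atan2(c5[1] - pcen[1], c5[0] - pcen[0])
    # step direction that walks C4 -> N9 -> C8 -> N7 -> C5
    step = 2 * math.pi / 5
    if (ang4 + step) % (2 * math.pi) == ang5 % (2 * math.pi):
        step = -step
    atoms = dict(ring)
    for i, name in enumerate(("N9", "C8", "N7"), start=1):
        a = ang4 + i * step
        cand = pcen + circum * np.array([math.cos(a), math.sin(a), 0.0])
        if i == 3 and np.linalg.norm(cand - c5) > 1.9 * _RING_BOND:
            # walked the wrong way round; restart reversed
            return _build_purine_reversed(code, ring, pcen, circum, ang4)
        atoms[name] = cand

    def exo(name: str, host: str) -> None:
        d = (ring[host] - center) / _RING_BOND
        atoms[name] = ring[host] + _EXO_BOND * d

    if code == "A":
        exo("N6", "C6")
    elif code == "G":
        exo("O6", "C6")
        exo("N2", "C2")
    return atoms


def _build_purine_reversed(code, ring, pcen, circum, ang4):  # pragma: no cover
    step = -2 * math.pi / 5
    atoms = dict(ring)
    for i, name in enumerate(("N9", "C8", "N7"), start=1):
        a = ang4 + i * step
        atoms[name] = pcen + circum * np.array([math.cos(a), math.sin(a), 0.0])
    center = np.array([0.0, -(_WC_DIST / 2 + _RING_BOND), 0.0])

    def exo(name: str, host: str) -> None:
        d = (ring[host] - center) / _RING_BOND
        atoms[name] = ring[host] + _EXO_BOND * d

    if code == "A":
        exo("N6", "C6")
    elif code == "G":
        exo("O6", "C6")
        exo("N2", "C2")
    return atoms


def _attach_c1p(atoms: Dict[str, np.ndarray], code: str) -> None:
    """Place the glycosidic C1' radially outward from the attachment ring."""
    gname = GLYCOSIDIC_N[code]
    g = atoms[gname]
    if code in PURINES:
        ring_names = ("C4", "N9", "C8", "N7", "C5")
    else:
        ring_names = tuple(RING_ATOMS[code])
    center = np.mean([atoms[n] for n in ring_names], axis=0)
    d = g - center
    d /= np.linalg.norm(d)
    atoms["C1'"] = g + _GLYC_BOND * d


def _pair_frame(code_top: str, code_bot: str) -> Tuple[Dict[str, np.ndarray], Dict[str, np.ndarray]]:
    """Base atoms of a WC pair with the *top* base on the +y side.

    The pair is rigid-aligned so that the two C1' atoms lie at
    (-2.2, +/-d, 0) with the C1'-C1' axis along y; this keeps the
    backbone attachment points sequence-independent (WC isomorphism).
    """
    if code_top in PYRIMIDINES:
        top = _build_pyrimidine(code_top)
        bot = _build_purine(code_bot)
        _attach_c1p(top, code_top)
        _attach_c1p(bot, code_bot)
    else:
        # build with the purine at the bottom, then flip strands with the
        # in-plane dyad (y -> -y, chirality preserved together with z -> -z,
        # which is a no-op for planar bases)
        bot0 = _build_pyrimidine(code_bot)
        top0 = _build_purine(code_top)
        _attach_c1p(bot0, code_bot)
        _attach_c1p(top0, code_top)
        flip = np.array([1.0, -1.0, -1.0])
        top = {k: v * flip for k, v in top0.items()}
        bot = {k: v * flip for k, v in bot0.items()}

    c1t, c1b = top["C1'"], bot["C1'"]
    mid = 0.5 * (c1t + c1b)
    axis = c1t - c1b
    half = 0.5 * np.linalg.norm(axis)
    ang = math.atan2(axis[0], axis[1])  # rotation needed to align axis to +y
    ca, sa = math.cos(ang), math.sin(ang)
    rot = np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])
    target_mid = np.array([-2.2, 0.0, 0.0])

    def xf(p: np.ndarray) -> np.ndarray:
        return rot @ (p - mid) + target_mid

    top = {k: xf(v) for k, v in top.items()}
    bot = {k: xf(v) for k, v in bot.items()}
    # numerical cleanliness: pin C1' exactly
    top["C1'"] = target_mid + np.array([0.0, half, 0.0])
    bot["C1'"] = target_mid + np.array([0.0, -half, 0.0])
    return top, bot


# ---------------------------------------------------------------------------
# backbone
# ---------------------------------------------------------------------------


def _rz(theta: float) -> np.ndarray:
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _backbone_template(c1: np.ndarray, twist: float, rise: float, is_rna: bool) -> Dict[str, np.ndarray]:
    """Backbone atoms of the top (chain-1) strand in the local pair frame.

    Chain 1 runs 5'->3' with increasing pair index, so its phosphate sits
    below the pair plane (toward 5', at -z) and the O3' is placed such
    that O3'(k) connects to P(k+1) = Rz(twist) P + rise*z with the exact
    O3'-P bond length.
    """
    outward = c1 - np.array([0.0, 0.0, c1[2]])
    outward = outward / np.linalg.norm(outward)
    p = _rz(-0.55 * twist) @ (c1 + 2.1 * outward) + np.array([0.0, 0.0, -0.52 * rise])
    p_next = _rz(twist) @ p + np.array([0.0, 0.0, rise])
    zhat = np.array([0.0, 0.0, 1.0])
    o3 = p_next + _O3P_BOND * _unit(c1 + 0.6 * outward + 1.2 * zhat - p_next)
    o5 = p + 1.59 * _unit(c1 + np.array([0.0, 0.0, 0.4]) - p)
    c4 = c1 + 2.35 * _unit(0.5 * (o3 + o5) - c1 + 0.6 * outward)
    # opposite out-of-plane biases keep every backbone angle well away
    # from collinearity (dihedral forces are singular at 180 degrees)
    c3 = _bridge(c4, o3, 1.53, 1.42, outward - 1.2 * zhat)
    c5 = _bridge(c4, o5, 1.51, 1.44, outward)
    ring_n = _unit(np.cross(c4 - c1, outward))
    if np.dot(ring_n, o3 - c4) > 0:  # keep O4' on the face away from O3'
        ring_n = -ring_n
    o4 = 0.5 * (c1 + c4) + 0.85 * ring_n
    # C2' bridges C1'-C3'; push it out of the O4'/O3' pseudo-plane (sugar
    # pucker direction), choosing the side farther from the backbone oxygens
    puck = _unit(np.cross(c3 - c1, ring_n))
    cands = [_bridge(c1, c3, 1.53, 1.53, sgn * puck) for sgn in (1.0, -1.0)]
    c2 = max(cands, key=lambda q: min(np.linalg.norm(q - a) for a in (o3, o4, o5, p)))
    atoms = {
        "P": p,
        "OP1": p + 1.48 * _unit(outward + np.array([0.0, 0.0, -0.8])),
        "OP2": p + 1.48 * _unit(outward + np.array([0.0, 0.0, 0.8])),
        "O5'": o5,
        "C5'": c5,
        "C4'": c4,
        "O4'": o4,
        "C3'": c3,
        "O3'": o3,
        "C2'": c2,
    }
    if is_rna:
        atoms["O2'"] = c2 + 1.41 * _unit(c2 - 0.5 * (c1 + c3))
    return atoms


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _bridge(a: np.ndarray, b: np.ndarray, ra: float, rb: float, bias: np.ndarray) -> np.ndarray:
    """Point at distance ra from a and rb from b, pushed toward bias.

    Falls back to a proportional point on the a-b segment when the two
    spheres do not intersect (degenerate input geometry).
    """
    ab = b - a
    d = np.linalg.norm(ab)
    u = ab / d
    if d >= ra + rb or d <= abs(ra - rb):
        return a + (ra / (ra + rb)) * ab
    x = (d * d + ra * ra - rb * rb) / (2 * d)
    h = math.sqrt(max(ra * ra - x * x, 0.0))
    w = bias - np.dot(bias, u) * u
    nw = np.linalg.norm(w)
    if nw < 1e-9:
        w = np.array([u[1], -u[0], 0.0])
        nw = np.linalg.norm(w)
    return a + x * u + h * (w / nw)


# ---------------------------------------------------------------------------
# NativeStructure
# ---------------------------------------------------------------------------


@dataclass
class NativeStructure:
    """All-heavy-atom native state of an idealized duplex."""

    atom_names: List[str]
    elements: List[str]
    res_index: np.ndarray  # 1-based within chain
    chain_id: List[str]  # 'A' or 'B'
    res_code: List[str]  # nucleotide letter per atom
    coords: np.ndarray  # (n_atoms, 3) Angstrom
    seq1: str
    seq2: str
    form: str
    nucleic_type: str
    _index: Dict[Tuple[str, int, str], int] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.res_index = np.asarray(self.res_index, dtype=int)
        if self._index is None:
            self._index = {
                (c, int(r), n): i
                for i, (c, r, n) in enumerate(zip(self.chain_id, self.res_index, self.atom_names))
            }

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_pairs(self) -> int:
        return len(self.seq1)

    def atom(self, chain: str, resi: int, name: str) -> int:
        """Flat index of an atom, or KeyError."""
        return self._index[(chain, resi, name)]

    def pair_residues(self, k: int) -> Tuple[Tuple[str, int], Tuple[str, int]]:
        """Chain/residue of base pair k (1-based, k=1 is the pulled end)."""
        n = self.n_pairs
        if not (1 <= k <= n):
            raise ValueError(f"pair index {k} out of range 1..{n}")
        return ("A", k), ("B", n + 1 - k)

    def pair_codes(self, k: int) -> Tuple[str, str]:
        (ca, ra), (cb, rb) = self.pair_residues(k)
        return self.seq1[ra - 1], self.seq2[rb - 1]

    def base_atom_indices(self, chain: str, resi: int, ring_only: bool = True) -> np.ndarray:
        code = self.seq1[resi - 1] if chain == "A" else self.seq2[resi - 1]
        names = set(RING_ATOMS[code]) if ring_only else None
        idx = [
            i
            for i, (c, r, n) in enumerate(zip(self.chain_id, self.res_index, self.atom_names))
            if c == chain and r == resi and (names is None or n in names)
        ]
        return np.array(idx, dtype=int)

    def base_centroid(self, chain: str, resi: int, coords: np.ndarray | None = None) -> np.ndarray:
        xyz = self.coords if coords is None else coords
        return xyz[self.base_atom_indices(chain, resi)].mean(axis=0)

    def wc_atom_indices(self, k: int) -> Tuple[int, int]:
        """Indices of the WC donor/acceptor heavy atoms of pair k."""
        (ca, ra), (cb, rb) = self.pair_residues(k)
        code_a, code_b = self.pair_codes(k)
        return self.atom(ca, ra, WC_ATOM[code_a]), self.atom(cb, rb, WC_ATOM[code_b])

    def wc_distance(self, k: int, coords: np.ndarray | None = None) -> float:
        i, j = self.wc_atom_indices(k)
        xyz = self.coords if coords is None else coords
        return float(np.linalg.norm(xyz[i] - xyz[j]))

    @property
    def pulling_pair(self) -> Tuple[int, int]:
        """(5'O of chain-1 residue 1, 3'O of chain-2 terminal residue)."""
        return self.atom("A", 1, "O5'"), self.atom("B", self.n_pairs, "O3'")

    def pair_reference_points(self) -> np.ndarray:
        """Midpoints of the glycosidic C1' atoms, one per base pair."""
        pts = []
        for k in range(1, self.n_pairs + 1):
            (ca, ra), (cb, rb) = self.pair_residues(k)
            pts.append(0.5 * (self.coords[self.atom(ca, ra, "C1'")] + self.coords[self.atom(cb, rb, "C1'")]))
        return np.array(pts)

    def nn_context(self, k: int) -> str:
        """Nearest-neighbor context label of junction pair k.

        Written as the chain-1 dinucleotide (junction base first, inward
        neighbor second) over the chain-2 partners, e.g. 'CC/GG'.  Both
        strands are retained so strand-swapped duplexes get distinct
        labels.  The terminal-most pair uses its single inward neighbor.
        """
        n = self.n_pairs
        if not (1 <= k < n):
            raise ValueError(f"junction pair {k} has no inward neighbor (n={n})")
        b1, b2 = self.pair_codes(k)
        c1, c2 = self.pair_codes(k + 1)
        return f"{b1}{c1}/{b2}{c2}"


def _element_of(name: str) -> str:
    return "P" if name == "P" else name[0]


def build_duplex(
    sequence: str,
    nucleic_type: str = "RNA",
    params: HelixParameters | None = None,
) -> NativeStructure:
    """Build an ideal duplex native structure from the chain-1 sequence.

    The second strand is the reverse complement; A-form geometry is the
    default for RNA and B-form for DNA.
    """
    nt = nucleic_type.upper()
    seq1 = sequence.upper()
    if len(seq1) < 2:
        raise ValueError("need at least 2 base pairs")
    seq2 = reverse_complement(seq1, nt)  # validates the alphabet
    if params is None:
        params = A_FORM if nt == "RNA" else B_FORM
    twist = math.radians(params.twist_deg)
    incl = math.radians(params.inclination_deg)
    rise = params.rise
    is_rna = nt == "RNA"
    n = len(seq1)

    ci, si = math.cos(incl), math.sin(incl)
    ry = np.array([[ci, 0.0, si], [0.0, 1.0, 0.0], [-si, 0.0, ci]])
    disp = np.array([params.x_disp, 0.0, 0.0])
    flip = np.array([1.0, -1.0, -1.0])  # local dyad: chain-1 <-> chain-2

    # per-pair local atoms; bases are inclined and displaced first so the
    # backbone can be generated consistently with the pure helical step
    # Rz(twist) + rise that place() applies afterwards
    strand1: List[Dict[str, np.ndarray]] = []
    strand2: List[Dict[str, np.ndarray]] = []
    for k in range(n):
        b1 = seq1[k]
        b2 = seq2[n - 1 - k]
        top, bot = _pair_frame(b1, b2)
        top = {name: ry @ p + disp for name, p in top.items()}
        bot = {name: ry @ p + disp for name, p in bot.items()}
        top.update(_backbone_template(top["C1'"], twist, rise, is_rna))
        # chain 2 backbone is the dyad image of the chain-1 template
        bb2 = {name: p * flip for name, p in _backbone_template(bot["C1'"] * flip, twist, rise, is_rna).items()}
        bot.update(bb2)
        strand1.append(top)
        strand2.append(bot)

    def place(p: np.ndarray, k: int) -> np.ndarray:
        return _rz(k * twist) @ p + np.array([0.0, 0.0, k * rise])

    atom_names: List[str] = []
    elements: List[str] = []
    res_index: List[int] = []
    chain_id: List[str] = []
    res_code: List[str] = []
    coords: List[np.ndarray] = []

    order = ["P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "O2'", "C1'"]

    def emit(chain: str, resi: int, code: str, atoms: Dict[str, np.ndarray], k: int, drop_phosphate: bool) -> None:
        names = [a for a in order if a in atoms] + [a for a in atoms if a not in order]
        for name in names:
            if drop_phosphate and name in ("P", "OP1", "OP2"):
                continue
            atom_names.append(name)
            elements.append(_element_of(name))
            res_index.append(resi)
            chain_id.append(chain)
            res_code.append(code)
            coords.append(place(atoms[name], k))

    # chain 1: residue r at pair k=r-1; residue 1 is 5'-terminal (no phosphate)
    for r in range(1, n + 1):
        emit("A", r, seq1[r - 1], strand1[r - 1], r - 1, drop_phosphate=(r == 1))
    # chain 2: residue j at pair k=n-j; residue 1 is its 5' terminus
    for j in range(1, n + 1):
        emit("B", j, seq2[j - 1], strand2[n - j], n - j, drop_phosphate=(j == 1))

    return NativeStructure(
        atom_names=atom_names,
        elements=elements,
        res_index=np.array(res_index),
        chain_id=chain_id,
        res_code=res_code,
        coords=np.array(coords),
        seq1=seq1,
        seq2=seq2,
        form=params.form,
        nucleic_type=nt,
    )


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

_PDB_RES = {
    ("RNA", "A"): "A", ("RNA", "C"): "C", ("RNA", "G"): "G", ("RNA", "U"): "U",
    ("DNA", "A"): "DA", ("DNA", "C"): "DC", ("DNA", "G"): "DG", ("DNA", "T"): "DT",
}
_RES_PDB = {v: (t, c) for (t, c), v in _PDB_RES.items()}


def write_pdb(structure: NativeStructure) -> str:
    """Serialize a NativeStructure as PDB ATOM/TER/END text."""
    lines = []
    serial = 1
    prev_chain = None
    for i in range(structure.n_atoms):
        chain = structure.chain_id[i]
        if prev_chain is not None and chain != prev_chain:
            lines.append("TER")
        prev_chain = chain
        name = structure.atom_names[i]
        res = _PDB_RES[(structure.nucleic_type, structure.res_code[i])]
        x, y, z = structure.coords[i]
        pdb_name = name if len(name) == 4 else f" {name:<3s}"
        lines.append(
            f"ATOM  {serial:5d} {pdb_name}{'':1s}{res:>3s} {chain}{structure.res_index[i]:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          {structure.elements[i]:>2s}"
        )
        serial += 1
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def read_pdb(text: str, form: str | None = None) -> NativeStructure:
    """Parse PDB ATOM records back into a NativeStructure.

    The two chains must be complementary strands of a duplex; the form
    tag is taken from the argument (default 'A' for RNA, 'B' for DNA).
    """
    atom_names: List[str] = []
    res_index: List[int] = []
    chain_id: List[str] = []
    res_names: List[str] = []
    coords: List[List[float]] = []
    for line in text.splitlines():
        if not line.startswith("ATOM"):
            continue
        if len(line) < 54:
            raise ValueError(f"malformed ATOM record: {line!r}")
        atom_names.append(line[12:16].strip())
        res_names.append(line[17:20].strip())
        chain_id.append(line[21].strip() or "A")
        res_index.append(int(line[22:26]))
        coords.append([float(line[30:38]), float(line[38:46]), float(line[46:54])])
    if not atom_names:
        raise ValueError("no ATOM records found")
    for rn in res_names:
        if rn not in _RES_PDB:
            raise ValueError(f"non-nucleic residue {rn!r}")
    types = {_RES_PDB[rn][0] for rn in res_names if _RES_PDB[rn][1] not in ("A", "C", "G")}
    nt = types.pop() if len(types) == 1 else ("RNA" if not types else None)
    if nt is None:
        raise ValueError("mixed DNA/RNA residues")
    chains = sorted(set(chain_id))
    if len(chains) != 2:
        raise ValueError(f"not a duplex: found {len(chains)} chain(s)")

    def chain_seq(c: str) -> str:
        seen: Dict[int, str] = {}
        for cid, ri, rn in zip(chain_id, res_index, res_names):
            if cid == c:
                seen[ri] = _RES_PDB[rn][1]
        return "".join(seen[r] for r in sorted(seen))

    seq1, seq2 = chain_seq(chains[0]), chain_seq(chains[1])
    if len(seq1) != len(seq2):
        raise ValueError("not a duplex: chain lengths differ")
    if seq2 != reverse_complement(seq1, nt):
        raise ValueError("not a duplex: chains are not reverse complements")
    res_code = ["" for _ in atom_names]
    for i, (cid, ri) in enumerate(zip(chain_id, res_index)):
        res_code[i] = (seq1 if cid == chains[0] else seq2)[ri - 1]
    if form is None:
        form = "A" if nt == "RNA" else "B"
    remap = {chains[0]: "A", chains[1]: "B"}
    return NativeStructure(
        atom_names=atom_names,
        elements=[_element_of(n) for n in atom_names],
        res_index=np.array(res_index),
        chain_id=[remap[c] for c in chain_id],
        res_code=res_code,
        coords=np.array(coords),
        seq1=seq1,
        seq2=seq2,
        form=form,
        nucleic_type=nt,
    )
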