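"""Geometric detection of cross-interface hydrogen bonds and fnat_hb.

Detection follows the classic HBplus-style geometric criteria:

* donor-acceptor distance d(D,A) < 3.9 Å;
* if a hydrogen is present on the donor or can be placed by ideal
  geometry, d(H,A) < 2.5 Å and angle D-H-A > 90°;
* if the acceptor has an antecedent heavy atom AA, angle D-A-AA > 90°.

Charged donor / carboxylate acceptor pairs within 4.0 Å are short-range
salt bridges; they are flagged and counted among the hydrogen bonds.

Polar hydrogens are placed deterministically for donors whose geometry is
fixed by the heavy atoms (backbone N, Arg, Asn/Gln amides, Trp NE1, His
ring nitrogens).  Rotatable hydroxyls and amines (Ser/Thr/Tyr OH, Lys NZ)
have no unique H position without a dihedral search, so they fall back to
the heavy-atom-only criterion (distance plus antecedent angle).

fnat_hb is the fraction of native (reference) hydrogen bonds recovered by
a model, computed analogously to fnat.  Bond identity is atom-level
(donor atom, acceptor atom) by default; residue-level matching is
available for threaded models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .structure import ComplexStructure, CorrespondenceMap, Residue, ResidueKey

__all__ = [
    "HBond",
    "HBondSet",
    "donors_acceptors",
    "detect_interface_hbonds",
    "fnat_hb",
]

# ---------------------------------------------------------------------------
# Donor / acceptor chemistry tables (standard amino acids)
# ---------------------------------------------------------------------------

# Side-chain donors per residue type: atom -> placement rule
#   "bisector": one H opposite the bisector of the two heavy neighbours
#   "amide":    two H in the plane of a planar N-H2 group
#   "rotatable": no deterministic H; heavy-atom criterion only
_SIDECHAIN_DONORS: dict[str, dict[str, str]] = {
    "SER": {"OG": "rotatable"},
    "THR": {"OG1": "rotatable"},
    "TYR": {"OH": "rotatable"},
    "LYS": {"NZ": "rotatable"},
    "ARG": {"NE": "bisector", "NH1": "amide", "NH2": "amide"},
    "TRP": {"NE1": "bisector"},
    "HIS": {"ND1": "bisector", "NE2": "bisector"},
    "ASN": {"ND2": "amide"},
    "GLN": {"NE2": "amide"},
}

# Side-chain acceptors: atom -> antecedent heavy atom (for the D-A-AA angle)
_SIDECHAIN_ACCEPTORS: dict[str, dict[str, str]] = {
    "ASP": {"OD1": "CG", "OD2": "CG"},
    "GLU": {"OE1": "CD", "OE2": "CD"},
    "ASN": {"OD1": "CG"},
    "GLN": {"OE1": "CD"},
    "SER": {"OG": "CB"},
    "THR": {"OG1": "CB"},
    "TYR": {"OH": "CZ"},
    "HIS": {"ND1": "CG", "NE2": "CD2"},
}

# Heavy neighbours of each donor, used for ideal H placement.
_DONOR_NEIGHBOURS: dict[tuple[str, str], tuple[str, ...]] = {
    ("ARG", "NE"): ("CD", "CZ"),
    ("ARG", "NH1"): ("CZ", "NE"),   # (bonded neighbour, in-plane reference)
    ("ARG", "NH2"): ("CZ", "NE"),
    ("ASN", "ND2"): ("CG", "OD1"),
    ("GLN", "NE2"): ("CD", "OE1"),
    ("TRP", "NE1"): ("CD1", "CE2"),
    ("HIS", "ND1"): ("CG", "CE1"),
    ("HIS", "NE2"): ("CD2", "CE1"),
}

_CHARGED_DONOR_ATOMS = {
    ("LYS", "NZ"),
    ("ARG", "NE"),
    ("ARG", "NH1"),
    ("ARG", "NH2"),
    ("HIS", "ND1"),
    ("HIS", "NE2"),
}
_CARBOXYLATE_ACCEPTORS = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}

_STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

_NH_LENGTH = 1.01  # Å, ideal N-H; also used for placed amide hydrogens


@dataclass(frozen=True)
class HBond:
    """One detected cross-interface hydrogen bond (or salt bridge)."""

    donor: tuple[ResidueKey, str]
    acceptor: tuple[ResidueKey, str]
    d_da: float
    is_salt_bridge: bool = False

    @property
    def key(self) -> tuple[ResidueKey, str, ResidueKey, str]:
        return (self.donor[0], self.donor[1], self.acceptor[0], self.acceptor[1])


class HBondSet:
    """Hydrogen bonds keyed by (donor residue, donor atom, acceptor residue, acceptor atom)."""

    def __init__(self, bonds: list[HBond] | None = None) -> None:
        self._bonds: dict[tuple, HBond] = {}
        for b in bonds or []:
            self._bonds[b.key] = b

    @property
    def bonds(self) -> list[HBond]:
        return list(self._bonds.values())

    def keys(self) -> set[tuple]:
        return set(self._bonds)

    def residue_pairs(self) -> set[tuple[ResidueKey, ResidueKey]]:
        return {(b.donor[0], b.acceptor[0]) for b in self._bonds.values()}

    def __len__(self) -> int:
        return len(self._bonds)

    def __contains__(self, key: tuple) -> bool:
        return key in self._bonds

    def __iter__(self):
        return iter(self._bonds.values())


def donors_acceptors(residue: Residue) -> tuple[dict[str, str], dict[str, str | None]]:
    """Donor and acceptor atoms of a residue, per standard chemistry.

    Returns ``(donors, acceptors)``: donors map atom name to the H
    placement rule; acceptors map atom name to the antecedent atom name
    (``None`` if no antecedent applies).  The backbone nitrogen is a donor
    except for proline; the backbone carbonyl O (and terminal OXT) are
    acceptors.  Unknown residue types yield empty tables.
    """
    if residue.name not in _STANDARD_RESIDUES:
        import warnings

        warnings.warn(f"unknown residue type {residue.name!r}; no donors/acceptors", stacklevel=2)
        return {}, {}
    donors: dict[str, str] = {}
    acceptors: dict[str, str | None] = {}
    if residue.name != "PRO" and residue.atom("N") is not None:
        donors["N"] = "backbone"
    if residue.atom("O") is not None:
        acceptors["O"] = "C"
    if residue.atom("OXT") is not None:
        acceptors["OXT"] = "C"
    for atom, rule in _SIDECHAIN_DONORS.get(residue.name, {}).items():
        if residue.atom(atom) is not None:
            donors[atom] = rule
    for atom, antecedent in _SIDECHAIN_ACCEPTORS.get(residue.name, {}).items():
        if residue.atom(atom) is not None:
            acceptors[atom] = antecedent
    return donors, acceptors


# ---------------------------------------------------------------------------
# Ideal-geometry hydrogen placement
# ---------------------------------------------------------------------------


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def _bisector_h(d: np.ndarray, n1: np.ndarray, n2: np.ndarray) -> np.ndarray:
    """H opposite the bisector of the two heavy neighbours of the donor."""
    direction = -_unit(_unit(n1 - d) + _unit(n2 - d))
    return d + _NH_LENGTH * direction


def _amide_h(d: np.ndarray, bonded: np.ndarray, in_plane: np.ndarray) -> list[np.ndarray]:
    """Two H of a planar NH2 group, 120° from the N-C bond, in the group plane."""
    u = _unit(bonded - d)
    normal = _unit(np.cross(bonded - d, in_plane - d))
    if np.linalg.norm(normal) < 1e-8:  # degenerate geometry
        return []
    e2 = np.cross(normal, u)
    c, s = math.cos(math.radians(120.0)), math.sin(math.radians(120.0))
    return [d + _NH_LENGTH * (c * u + s * e2), d + _NH_LENGTH * (c * u - s * e2)]


def _placed_hydrogens(
    structure_prev_c: np.ndarray | None, residue: Residue, donor_atom: str, rule: str
) -> list[np.ndarray] | None:
    """Hydrogen positions for a donor, or None when not placeable (rotatable)."""
    d = residue.atom(donor_atom).coords
    if rule == "backbone":
        ca = residue.atom("CA")
        if ca is None or structure_prev_c is None:
            return None
        return [_bisector_h(d, ca.coords, structure_prev_c)]
    if rule == "bisector":
        n1name, n2name = _DONOR_NEIGHBOURS[(residue.name, donor_atom)]
        n1, n2 = residue.atom(n1name), residue.atom(n2name)
        if n1 is None or n2 is None:
            return None
        return [_bisector_h(d, n1.coords, n2.coords)]
    if rule == "amide":
        bonded_name, plane_name = _DONOR_NEIGHBOURS[(residue.name, donor_atom)]
        bonded, plane = residue.atom(bonded_name), residue.atom(plane_name)
        if bonded is None or plane is None:
            return None
        return _amide_h(d, bonded.coords, plane.coords) or None
    return None  # rotatable


def _explicit_hydrogens(residue: Residue, donor_atom: str) -> list[np.ndarray]:
    """Hydrogens already in the structure, bonded to the donor (within 1.25 Å)."""
    d = residue.atom(donor_atom).coords
    return [
        a.coords
        for a in residue.atoms
        if a.is_hydrogen and np.linalg.norm(a.coords - d) < 1.25
    ]


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    v1, v2 = _unit(a - b), _unit(c - b)
    return math.degrees(math.acos(float(np.clip(np.dot(v1, v2), -1.0, 1.0))))


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------


def _preceding_c(structure: ComplexStructure, residue: Residue) -> np.ndarray | None:
    """Carbonyl C of the chain predecessor (for backbone amide H placement)."""
    idx = structure.residues.index(residue)
    if idx == 0:
        return None
    prev = structure.residues[idx - 1]
    if prev.chain_id != residue.chain_id:
        return None
    c = prev.atom("C")
    if c is None:
        return None
    # require an actual peptide bond, not a chain break
    n = residue.atom("N")
    if n is None or np.linalg.norm(c.coords - n.coords) > 1.8:
        return None
    return c.coords


def detect_interface_hbonds(
    structure: ComplexStructure,
    d_da_max: float = 3.9,
    d_ha_max: float = 2.5,
    min_angle: float = 90.0,
    salt_bridge_max: float = 4.0,
) -> HBondSet:
    """Detect cross-interface hydrogen bonds (including salt bridges).

    Every donor on one side of the receptor/peptide partition is tested
    against every acceptor on the other side.  Ordinary bonds require
    d(D,A) < ``d_da_max``; charged-donor/carboxylate pairs are accepted up
    to ``salt_bridge_max`` and flagged ``is_salt_bridge`` (pairs that also
    satisfy the ordinary distance keep the flag).
    """
    donor_list: list[tuple[Residue, str, str]] = []
    acceptor_list: list[tuple[Residue, str, str | None]] = []
    for res in structure.residues:
        donors, acceptors = donors_acceptors(res)
        for atom, rule in donors.items():
            donor_list.append((res, atom, rule))
        for atom, antecedent in acceptors.items():
            acceptor_list.append((res, atom, antecedent))

    bonds: list[HBond] = []
    for dres, datom, rule in donor_list:
        dside = structure.side_of(dres.chain_id)
        dpos = dres.atom(datom).coords
        hydrogens = _explicit_hydrogens(dres, datom)
        if not hydrogens:
            placed = _placed_hydrogens(_preceding_c(structure, dres), dres, datom, rule)
            hydrogens = placed if placed is not None else []
            heavy_only = placed is None
        else:
            heavy_only = False
        is_charged = (dres.name, datom) in _CHARGED_DONOR_ATOMS
        for ares, aatom, antecedent in acceptor_list:
            if structure.side_of(ares.chain_id) == dside:
                continue
            apos = ares.atom(aatom).coords
            d_da = float(np.linalg.norm(dpos - apos))
            salt = is_charged and (ares.name, aatom) in _CARBOXYLATE_ACCEPTORS
            limit = salt_bridge_max if salt else d_da_max
            if not d_da < limit:
                continue
            if antecedent is not None:
                aa = ares.atom(antecedent)
                if aa is not None and not _angle(dpos, apos, aa.coords) > min_angle:
                    continue
            # salt bridges are electrostatic: heavy-atom geometry suffices
            if hydrogens and not heavy_only and not salt:
                ok = any(
                    np.linalg.norm(h - apos) < d_ha_max and _angle(dpos, h, apos) > min_angle
                    for h in hydrogens
                )
                if not ok:
                    continue
            bonds.append(
                HBond(
                    donor=(dres.key, datom),
                    acceptor=(ares.key, aatom),
                    d_da=d_da,
                    is_salt_bridge=salt,
                )
            )
    return HBondSet(bonds)


def fnat_hb(
    reference_hb: HBondSet,
    model_hb: HBondSet,
    correspondence: CorrespondenceMap,
    match: str = "atom",
) -> float:
    """Fraction of native interface hydrogen bonds recovered by the model.

    ``match='atom'`` requires the same donor and acceptor atoms;
    ``match='residue'`` only the same donor/acceptor residue pair (useful
    for threaded models).  Returns NaN when the reference has no interface
    hydrogen bonds.
    """
    if len(reference_hb) == 0:
        return float("nan")
    if match not in ("atom", "residue"):
        raise ValueError(f"match must be 'atom' or 'residue', got {match!r}")
    recovered = 0
    model_pairs = model_hb.residue_pairs()
    for bond in reference_hb:
        dmap = correspondence.model_key(bond.donor[0])
        amap = correspondence.model_key(bond.acceptor[0])
        if dmap is None or amap is None:
            continue
        if match == "atom":
            if (dmap, bond.donor[1], amap, bond.acceptor[1]) in model_hb:
                recovered += 1
        else:
            if (dmap, amap) in model_pairs:
                recovered += 1
    return recovered / len(reference_hb)
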