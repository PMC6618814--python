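"""Hydrogen-bond chemistry tables, geometric detection and fnat_hb."""

import math

import numpy as np
import pytest

from pepqa import (
    ComplexStructure,
    HBond,
    HBondSet,
    contacts,
    detect_interface_hbonds,
    donors_acceptors,
    fnat_hb,
)
from pepqa.structure import CorrespondenceMap

from conftest import apply_global_transform, make_residue, random_rigid_transform


def test_donor_acceptor_tables():
    ser = make_residue("A", 1, "SER", {
        "N": (0, 0, 0), "CA": (1.5, 0, 0), "C": (2, 1.3, 0), "O": (1.5, 2.4, 0),
        "CB": (2, -1.3, 0), "OG": (3.4, -1.3, 0),
    })
    donors, acceptors = donors_acceptors(ser)
    assert set(donors) == {"N", "OG"}
    assert set(acceptors) == {"O", "OG"}

    pro = make_residue("A", 2, "PRO", {
        "N": (0, 0, 0), "CA": (1.5, 0, 0), "C": (2, 1.3, 0), "O": (1.5, 2.4, 0),
        "CB": (2, -1.3, 0), "CG": (1.2, -2.5, 0), "CD": (-0.2, -1.4, 0),
    })
    donors, acceptors = donors_acceptors(pro)
    assert "N" not in donors  # proline nitrogen has no H
    assert set(acceptors) == {"O"}

    gly = make_residue("A", 3, "GLY", {
        "N": (0, 0, 0), "CA": (1.5, 0, 0), "C": (2, 1.3, 0), "O": (1.5, 2.4, 0),
    })
    donors, acceptors = donors_acceptors(gly)
    assert set(donors) == {"N"} and set(acceptors) == {"O"}


def _donor_acceptor_complex(n_to_o: float) -> ComplexStructure:
    """Receptor Gly chain donating its backbone N-H to a peptide Gly carbonyl.

    The donor N-H (placed from the preceding carbonyl and CA) points along
    +y straight at the acceptor O, whose antecedent C sits behind it.
    """
    prev = make_residue("A", 1, "GLY", {
        "N": (-3.0, -1.2, 0), "CA": (-2.2, 0.0, 0), "C": (-1.35, 0.0, 0), "O": (-1.35, -1.23, 0),
    })
    donor = make_residue("A", 2, "GLY", {
        "N": (0.0, 0.0, 0.0), "CA": (0.8, -1.2, 0), "C": (2.25, -1.2, 0), "O": (2.9, -2.2, 0),
    })
    acceptor = make_residue("B", 1, "GLY", {
        "N": (1.4, n_to_o + 1.9, 0), "CA": (0.3, n_to_o + 1.25, 0),
        "C": (0.0, n_to_o + 1.23, 0),
        "O": (0.0, n_to_o, 0.0),
    })
    return ComplexStructure([prev, donor, acceptor], {"A"}, {"B"})


def test_ideal_backbone_hbond_detected():
    s = _donor_acceptor_complex(2.9)
    bonds = detect_interface_hbonds(s)
    keys = {b.key for b in bonds}
    assert ((("A", 2, ""), "N", ("B", 1, ""), "O")) in keys


def test_distant_pair_not_detected():
    s = _donor_acceptor_complex(4.2)
    assert (((("A", 2, ""), "N", ("B", 1, ""), "O"))) not in {b.key for b in detect_interface_hbonds(s)}


def test_salt_bridge_flagged_and_included():
    """Lys NZ vs Asp carboxylate at 3.95 Å: beyond the H-bond distance but a salt bridge."""
    lys = make_residue("A", 1, "LYS", {
        "N": (0, 0, 0), "CA": (1.5, 0, 0), "C": (2.0, 1.4, 0), "O": (1.3, 2.4, 0),
        "CB": (2.2, -1.2, 0), "CG": (3.7, -1.1, 0), "CD": (4.4, -2.4, 0),
        "CE": (5.9, -2.3, 0), "NZ": (6.6, -3.6, 0),
    })
    asp = make_residue("B", 1, "ASP", {
        "N": (14.7, -1.2, 0), "CA": (14.1, -2.45, 0), "C": (14.8, -3.7, 0), "O": (16.0, -3.75, 0),
        "CB": (12.6, -2.4, 0), "CG": (11.85, -3.6, 0),
        "OD1": (10.55, -3.6, 0), "OD2": (12.5, -4.65, 0),
    })
    s = ComplexStructure([lys, asp], {"A"}, {"B"})
    d = np.linalg.norm(lys.atom("NZ").coords - asp.atom("OD1").coords)
    assert 3.9 < d < 4.0  # in the salt-bridge-only window
    bonds = [b for b in detect_interface_hbonds(s) if b.donor[1] == "NZ"]
    assert any(b.is_salt_bridge and b.acceptor[1] == "OD1" for b in bonds)


def _brute_force_hbonds(structure, d_da_max=3.9, salt_max=4.0):
    """Independent heavy-atom-level enumeration of the detection criteria.

    Places no hydrogens: checks D-A distance (with the salt-bridge window)
    and the acceptor antecedent angle only, so it yields a superset of the
    detector's output; the detector may only remove pairs via H geometry.
    """
    from pepqa.hbonds import (
        _CARBOXYLATE_ACCEPTORS,
        _CHARGED_DONOR_ATOMS,
        _SIDECHAIN_ACCEPTORS,
        _SIDECHAIN_DONORS,
    )

    found = set()
    for dres in structure.residues:
        dside = structure.side_of(dres.chain_id)
        donor_atoms = dict(_SIDECHAIN_DONORS.get(dres.name, {}))
        if dres.name != "PRO" and dres.atom("N") is not None:
            donor_atoms["N"] = "backbone"
        for ares in structure.residues:
            if structure.side_of(ares.chain_id) == dside:
                continue
            acceptor_atoms = dict(_SIDECHAIN_ACCEPTORS.get(ares.name, {}))
            if ares.atom("O") is not None:
                acceptor_atoms["O"] = "C"
            for datom in donor_atoms:
                if dres.atom(datom) is None:
                    continue
                for aatom, antecedent in acceptor_atoms.items():
                    if ares.atom(aatom) is None:
                        continue
                    dpos, apos = dres.atom(datom).coords, ares.atom(aatom).coords
                    d = np.linalg.norm(dpos - apos)
                    salt = (dres.name, datom) in _CHARGED_DONOR_ATOMS and (
                        ares.name, aatom) in _CARBOXYLATE_ACCEPTORS
                    if not d < (salt_max if salt else d_da_max):
                        continue
                    aa = ares.atom(antecedent) if antecedent else None
                    if aa is not None:
                        v1 = dpos - apos
                        v2 = aa.coords - apos
                        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                        if not math.degrees(math.acos(np.clip(cosang, -1, 1))) > 90.0:
                            continue
                    found.add((dres.key, datom, ares.key, aatom))
    return found


def test_detector_consistent_with_heavy_atom_oracle(toy_complex):
    """Detected bonds are exactly the heavy-atom candidates that pass H geometry."""
    detected = {b.key for b in detect_interface_hbonds(toy_complex)}
    candidates = _brute_force_hbonds(toy_complex)
    assert detected <= candidates
    # every candidate lost must involve a donor with placeable hydrogens
    # (rotatable donors are judged on heavy atoms only, so they never drop out)
    from pepqa.hbonds import _SIDECHAIN_DONORS

    for key in candidates - detected:
        dres = toy_complex.residue(key[0])
        rule = _SIDECHAIN_DONORS.get(dres.name, {}).get(key[1], "backbone")
        assert rule in ("backbone", "bisector", "amide")


def test_detection_invariant_under_global_rigid_transform(toy_complex):
    rng = np.random.default_rng(23)
    base = {b.key for b in detect_interface_hbonds(toy_complex)}
    for _ in range(2):
        rot, shift = random_rigid_transform(rng)
        moved = apply_global_transform(toy_complex, rot, shift)
        assert {b.key for b in detect_interface_hbonds(moved)} == base


def test_hbonds_are_subset_of_contacts(toy_complex):
    """Every ordinary H-bond's residue pair is a 4 Å contact (salt bridges may not be)."""
    contact_pairs = contacts(toy_complex).pairs
    for bond in detect_interface_hbonds(toy_complex):
        if bond.is_salt_bridge:
            continue
        dkey, akey = bond.donor[0], bond.acceptor[0]
        pair = (dkey, akey) if toy_complex.side_of(dkey[0]) == "receptor" else (akey, dkey)
        assert pair in contact_pairs


def _hb(i, datom="N", aatom="O"):
    return HBond(donor=(("A", i, ""), datom), acceptor=(("B", i, ""), aatom), d_da=2.9)


def _identity_map(n):
    keys = [("A", i, "") for i in range(n)] + [("B", i, "") for i in range(n)]
    return CorrespondenceMap([(k, k) for k in keys], {})


def test_fnat_hb_identity_partial_and_empty():
    ref = HBondSet([_hb(i) for i in range(5)])
    assert fnat_hb(ref, ref, _identity_map(5)) == 1.0
    model = HBondSet([_hb(i) for i in range(4)])  # one donor rotated away
    assert fnat_hb(ref, model, _identity_map(5)) == pytest.approx(0.8)
    assert math.isnan(fnat_hb(HBondSet([]), model, _identity_map(5)))


def test_fnat_hb_residue_level_matching():
    """Residue-pair matching tolerates a different donor atom on the same residues."""
    ref = HBondSet([_hb(0, datom="NZ")])
    model = HBondSet([_hb(0, datom="NE")])
    cmap = _identity_map(1)
    assert fnat_hb(ref, model, cmap, match="atom") == 0.0
    assert fnat_hb(ref, model, cmap, match="residue") == 1.0
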