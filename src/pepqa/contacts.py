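"""Interface residues, native contacts, clashes and fnat.

The three distance criteria of the CAPRI peptide assessment scheme:

* interface residues — CB (CA for Gly) within 8.0 Å of a CB/CA across the
  receptor/peptide partition;
* native contacts — residue pairs with any two heavy atoms across the
  interface closer than 4.0 Å (residue-based);
* clashes — cross-interface heavy-atom pairs closer than 3.0 Å
  (atom-based: every qualifying pair is counted).

All cutoffs are strict ``<``.  Hydrogens are excluded unless explicitly
requested; docking models rarely carry them and assessment practice
compares heavy atoms.

fnat is the fraction of the reference (native) contact set recovered by a
model; its denominator is always the native set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure import ComplexStructure, CorrespondenceMap, Residue, ResidueKey

__all__ = [
    "ContactSet",
    "InterfaceSet",
    "interface_residues",
    "contacts",
    "count_clashes",
    "fnat",
]


@dataclass
class ContactSet:
    """Cross-partition residue contacts: pairs (receptor key, peptide key)."""

    pairs: frozenset[tuple[ResidueKey, ResidueKey]]

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class InterfaceSet:
    """Residues (both sides) at the interface of one structure."""

    residues: frozenset[ResidueKey]
    derived_from: str = "reference"
    receptor: frozenset[ResidueKey] = field(default_factory=frozenset)
    peptide: frozenset[ResidueKey] = field(default_factory=frozenset)

    def __contains__(self, key: ResidueKey) -> bool:
        return key in self.residues

    def __len__(self) -> int:
        return len(self.residues)


def _representative_atom(res: Residue) -> np.ndarray | None:
    """CB coordinates, CA for Gly; CA fallback (with warning) if CB absent."""
    target = "CA" if res.name == "GLY" else "CB"
    atom = res.atom(target)
    if atom is None and target == "CB":
        atom = res.atom("CA")
        if atom is not None:
            warnings.warn(f"residue {res.key} ({res.name}) lacks CB; using CA", stacklevel=3)
    if atom is None:
        warnings.warn(f"residue {res.key} has neither CB nor CA; excluded from interface", stacklevel=3)
        return None
    return atom.coords


def interface_residues(structure: ComplexStructure, cutoff: float = 8.0) -> InterfaceSet:
    """Residues whose CB (CA for Gly) is within ``cutoff`` of one across the interface."""
    rec, pep = [], []
    for res in structure.residues:
        coords = _representative_atom(res)
        if coords is None:
            continue
        side = structure.side_of(res.chain_id)
        (rec if side == "receptor" else pep).append((res.key, coords))
    rec_keys_set: set[ResidueKey] = set()
    pep_keys_set: set[ResidueKey] = set()
    if rec and pep:
        rc = np.array([c for _, c in rec])
        pc = np.array([c for _, c in pep])
        dist = np.linalg.norm(rc[:, None, :] - pc[None, :, :], axis=-1)
        ii, jj = np.nonzero(dist < cutoff)
        rec_keys_set = {rec[i][0] for i in ii}
        pep_keys_set = {pep[j][0] for j in jj}
    return InterfaceSet(
        residues=frozenset(rec_keys_set | pep_keys_set),
        derived_from="reference",
        receptor=frozenset(rec_keys_set),
        peptide=frozenset(pep_keys_set),
    )


def _partition_atoms(
    structure: ComplexStructure, include_hydrogens: bool
) -> tuple[np.ndarray, list[ResidueKey], np.ndarray, list[ResidueKey]]:
    rc, rk, pc, pk = [], [], [], []
    for res, atom in structure.iter_atoms(heavy_only=not include_hydrogens):
        if structure.side_of(res.chain_id) == "receptor":
            rc.append(atom.coords)
            rk.append(res.key)
        else:
            pc.append(atom.coords)
            pk.append(res.key)
    return np.array(rc), rk, np.array(pc), pk


def contacts(
    structure: ComplexStructure,
    cutoff: float = 4.0,
    include_hydrogens: bool = False,
) -> ContactSet:
    """Residue-based cross-interface contacts: closest atom pair under ``cutoff``."""
    rc, rk, pc, pk = _partition_atoms(structure, include_hydrogens)
    pairs: set[tuple[ResidueKey, ResidueKey]] = set()
    if len(rc) and len(pc):
        tree = cKDTree(pc)
        for i, neighbours in enumerate(tree.query_ball_point(rc, cutoff)):
            for j in neighbours:
                if np.linalg.norm(rc[i] - pc[j]) < cutoff:  # strict <
                    pairs.add((rk[i], pk[j]))
    return ContactSet(frozenset(pairs))


def count_clashes(
    structure: ComplexStructure,
    cutoff: float = 3.0,
    include_hydrogens: bool = False,
) -> int:
    """Number of cross-interface atom pairs closer than ``cutoff`` (atom-based)."""
    rc, _, pc, _ = _partition_atoms(structure, include_hydrogens)
    if not len(rc) or not len(pc):
        return 0
    tree = cKDTree(pc)
    n = 0
    for i, neighbours in enumerate(tree.query_ball_point(rc, cutoff)):
        for j in neighbours:
            if np.linalg.norm(rc[i] - pc[j]) < cutoff:
                n += 1
    return n


def fnat(
    reference_contacts: ContactSet,
    model_contacts: ContactSet,
    correspondence: CorrespondenceMap,
) -> float:
    """Fraction of native contacts recovered by the model.

    A native pair counts as recovered when both residues map to model
    residues and the mapped pair is a model contact.  The denominator is
    the full native set.
    """
    if len(reference_contacts) == 0:
        raise ValueError("reference structure has no cross-interface contacts")
    recovered = 0
    for rkey, pkey in reference_contacts.pairs:
        mr = correspondence.model_key(rkey)
        mp = correspondence.model_key(pkey)
        if mr is not None and mp is not None and (mr, mp) in model_contacts.pairs:
            recovered += 1
    return recovered / len(reference_contacts)
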