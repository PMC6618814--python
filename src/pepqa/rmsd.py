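"""Kabsch superposition and the three RMSD measures (L-, I-, S-RMSD).

* L-RMSD (ligand RMSD): superpose the model on the reference using the
  paired receptor backbone atoms, then measure the RMSD over paired
  peptide backbone atoms under that transform — the peptide is never
  refitted.
* I-RMSD (interface backbone RMSD): fit and evaluate on backbone atoms of
  the reference-defined interface residues (8 Å CB criterion).
* S-RMSD (interface side-chain RMSD): same construction and same
  superposition frame as I-RMSD, but evaluated over the side-chain heavy
  atoms of those interface residues.  Chemically indistinguishable atom
  namings (Phe/Tyr ring, Asp/Glu carboxylate, Arg NH, Leu CD, Val CG) are
  resolved per residue to the swap that minimises that residue's summed
  squared deviation.

The interface is always defined on the reference: the native structure
defines *the* interface, and the model is measured against it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .contacts import interface_residues
from .structure import (
    BACKBONE_ATOMS,
    ComplexStructure,
    CorrespondenceMap,
    ResidueKey,
)

__all__ = ["RigidTransform", "kabsch", "ligand_rmsd", "interface_rmsd", "SYMMETRY_SWAPS"]

#: Symmetry-equivalent side-chain atom renamings, applied as one whole-residue
#: swap (e.g. a Phe ring flip exchanges CD1<->CD2 *and* CE1<->CE2 together).
SYMMETRY_SWAPS: dict[str, dict[str, str]] = {
    "PHE": {"CD1": "CD2", "CD2": "CD1", "CE1": "CE2", "CE2": "CE1"},
    "TYR": {"CD1": "CD2", "CD2": "CD1", "CE1": "CE2", "CE2": "CE1"},
    "ASP": {"OD1": "OD2", "OD2": "OD1"},
    "GLU": {"OE1": "OE2", "OE2": "OE1"},
    "ARG": {"NH1": "NH2", "NH2": "NH1"},
    "LEU": {"CD1": "CD2", "CD2": "CD1"},
    "VAL": {"CG1": "CG2", "CG2": "CG1"},
}


@dataclass
class RigidTransform:
    """Proper rigid motion x -> R x + t (rotation then translation)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("reflections are not rigid transforms")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares superposition of ``mobile`` onto ``target``.

    Returns the proper rigid transform (no reflection) minimising the RMSD
    between the transformed mobile points and the target, and that minimal
    RMSD.  Requires at least 3 points; collinear point sets still return a
    fit but trigger a warning since the in-plane rotation is underdetermined.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape:
        raise ValueError("point sets must have equal shapes")
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise ValueError("need at least 3 points of dimension 3")

    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    p = mobile - mc
    q = target - tc
    h = p.T @ q
    u, s, vt = np.linalg.svd(h)
    # rank deficiency: points collinear (rank 1) or coincident (rank 0)
    if np.sum(s > 1e-9 * max(s[0], 1e-300)) < 2:
        warnings.warn("degenerate (collinear) point set; superposition underdetermined", stacklevel=2)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    transform = RigidTransform(rot, tc - rot @ mc)
    return transform, _rmsd(transform.apply(mobile), target)


def _paired_coords(
    reference: ComplexStructure,
    model: ComplexStructure,
    correspondence: CorrespondenceMap,
    ref_keys: set[ResidueKey] | None,
    side: str | None,
    atom_filter,
) -> tuple[np.ndarray, np.ndarray, list[tuple[ResidueKey, str]]]:
    """Matched (reference, model) coordinate arrays over selected atom pairs."""
    ref_pts, mod_pts, labels = [], [], []
    for (rkey, mkey) in correspondence.residue_pairs:
        if ref_keys is not None and rkey not in ref_keys:
            continue
        rres = reference.residue(rkey)
        mres = model.residue(mkey)
        if side is not None and reference.side_of(rres.chain_id) != side:
            continue
        for rname, mname in correspondence.atom_pairs[(rkey, mkey)]:
            if not atom_filter(rname):
                continue
            ra, ma = rres.atom(rname), mres.atom(mname)
            if ra is None or ma is None or ra.is_hydrogen or ma.is_hydrogen:
                continue
            ref_pts.append(ra.coords)
            mod_pts.append(ma.coords)
            labels.append((rkey, rname))
    if not ref_pts:
        return np.empty((0, 3)), np.empty((0, 3)), []
    return np.array(ref_pts), np.array(mod_pts), labels


def ligand_rmsd(
    reference: ComplexStructure,
    model: ComplexStructure,
    correspondence: CorrespondenceMap,
) -> float:
    """CAPRI ligand (peptide) RMSD after a receptor-backbone superposition."""
    is_backbone = lambda name: name in BACKBONE_ATOMS
    rec_ref, rec_mod, _ = _paired_coords(reference, model, correspondence, None, "receptor", is_backbone)
    pep_ref, pep_mod, _ = _paired_coords(reference, model, correspondence, None, "peptide", is_backbone)
    if len(rec_ref) < 3:
        raise ValueError(f"only {len(rec_ref)} paired receptor backbone atoms; need >= 3 for the fit")
    if len(pep_ref) < 1:
        raise ValueError("no paired peptide backbone atoms to evaluate")
    transform, _ = kabsch(rec_mod, rec_ref)
    return _rmsd(transform.apply(pep_mod), pep_ref)


def interface_rmsd(
    reference: ComplexStructure,
    model: ComplexStructure,
    correspondence: CorrespondenceMap,
    atomset: str = "backbone",
    interface_cutoff: float = 8.0,
    fit_on: str = "backbone",
) -> float:
    """Interface RMSD over backbone (I-RMSD) or side-chain (S-RMSD) atoms.

    The interface is taken from the reference at ``interface_cutoff``.
    ``atomset='backbone'`` fits and evaluates on interface backbone atoms.
    ``atomset='sidechain'`` evaluates side-chain heavy atoms in the frame
    fitted on interface backbone atoms (set ``fit_on='sidechain'`` to refit
    on the side chains themselves, for sensitivity analysis).

    Returns NaN with a warning when no paired side-chain atoms exist at the
    interface (e.g. an all-glycine interface).
    """
    if atomset not in ("backbone", "sidechain"):
        raise ValueError(f"atomset must be 'backbone' or 'sidechain', got {atomset!r}")
    iface = interface_residues(reference, cutoff=interface_cutoff).residues
    is_backbone = lambda name: name in BACKBONE_ATOMS
    is_sidechain = lambda name: name not in BACKBONE_ATOMS

    bb_ref, bb_mod, _ = _paired_coords(reference, model, correspondence, set(iface), None, is_backbone)
    if atomset == "backbone":
        if len(bb_ref) < 3:
            raise ValueError("fewer than 3 paired interface backbone atoms")
        _, value = kabsch(bb_mod, bb_ref)
        return value

    sc_ref, sc_mod, sc_labels = _paired_coords(
        reference, model, correspondence, set(iface), None, is_sidechain
    )
    if len(sc_ref) == 0:
        warnings.warn("no paired side-chain atoms at the interface; S-RMSD undefined", stacklevel=2)
        return float("nan")
    if fit_on == "sidechain":
        if len(sc_ref) < 3:
            raise ValueError("fewer than 3 paired interface side-chain atoms for a side-chain fit")
        transform, _ = kabsch(sc_mod, sc_ref)
    else:
        if len(bb_ref) < 3:
            raise ValueError("fewer than 3 paired interface backbone atoms for the fit")
        transform, _ = kabsch(bb_mod, bb_ref)
    sc_mod_fit = transform.apply(sc_mod)

    # Per-residue symmetry-swap resolution: pick identity or the swapped
    # naming, whichever gives the smaller summed squared deviation.
    by_residue: dict[ResidueKey, list[int]] = {}
    for idx, (rkey, _) in enumerate(sc_labels):
        by_residue.setdefault(rkey, []).append(idx)

    total_ss = 0.0
    for rkey, indices in by_residue.items():
        res = reference.residue(rkey)
        swap = SYMMETRY_SWAPS.get(res.name)
        direct = sc_ref[indices]
        ss_identity = float(np.sum((direct - sc_mod_fit[indices]) ** 2))
        if swap is None:
            total_ss += ss_identity
            continue
        name_to_idx = {sc_labels[i][1]: i for i in indices}
        swapped_rows = []
        for i in indices:
            name = sc_labels[i][1]
            j = name_to_idx.get(swap.get(name, name), i)
            swapped_rows.append(sc_mod_fit[j])
        ss_swapped = float(np.sum((direct - np.array(swapped_rows)) ** 2))
        total_ss += min(ss_identity, ss_swapped)
    return float(np.sqrt(total_ss / len(sc_ref)))
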