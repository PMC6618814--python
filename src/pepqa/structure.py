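"""Molecular structures with a receptor/peptide chain partition.

A docking model and its reference crystal structure are both represented as
a :class:`ComplexStructure`: an ordered list of residues whose chains are
partitioned into *receptor* chains and *peptide* (ligand) chains.  All
interface metrics are defined across that partition.

Parsing and writing of the fixed-width PDB dialect goes through gemmi;
this module owns the policy layer on top of it: altloc resolution (highest
occupancy, ties broken by file order), exclusion of waters and of HETATM
records other than MSE (mapped to MET), and chain designation.

Residue identity is the key ``(chain_id, number, icode)``.  No sequence
alignment is attempted when pairing a model against a reference: docking
submissions are expected to use the target numbering, and misnumbered
inputs are the user's responsibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "ComplexStructure",
    "CorrespondenceMap",
    "ResidueKey",
    "read_structure",
    "write_structure",
    "build_correspondence",
    "select_atoms",
    "BACKBONE_ATOMS",
]

#: Atom key triple: (chain id, residue number, insertion code).
ResidueKey = tuple[str, int, str]

#: Main-chain atom names used for superposition and I-RMSD.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})

_WATER_NAMES = {"HOH", "WAT", "DOD"}

#: Nonstandard residues mapped onto their standard parent on read.
_PARENT_RESIDUE = {"MSE": "MET"}
_PARENT_ATOM_RENAME = {"MSE": {"SE": "SD"}}


@dataclass
class Atom:
    """A single atom record after altloc resolution."""

    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    bfactor: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r}: coordinates must be a finite 3-vector")
        if not self.name:
            raise ValueError("atom name must be non-empty")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Residue:
    chain_id: str
    number: int
    icode: str
    name: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.number, self.icode)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Residue {self.name} {self.chain_id}{self.number}{self.icode.strip()}>"


class ComplexStructure:
    """A complex whose chains are split into receptor and peptide sets.

    Parameters
    ----------
    residues:
        Ordered residues; each must belong to a designated chain.
    receptor_chains, peptide_chains:
        Disjoint, non-empty sets of chain identifiers.
    """

    def __init__(
        self,
        residues: Sequence[Residue],
        receptor_chains: Iterable[str],
        peptide_chains: Iterable[str],
    ) -> None:
        self.receptor_chains = frozenset(receptor_chains)
        self.peptide_chains = frozenset(peptide_chains)
        if not self.receptor_chains or not self.peptide_chains:
            raise ValueError("receptor and peptide chain sets must both be non-empty")
        overlap = self.receptor_chains & self.peptide_chains
        if overlap:
            raise ValueError(f"chains cannot be both receptor and peptide: {sorted(overlap)}")
        designated = self.receptor_chains | self.peptide_chains
        for r in residues:
            if r.chain_id not in designated:
                raise ValueError(f"residue {r.key} is on an undesignated chain")
        self.residues: list[Residue] = list(residues)
        self._by_key = {r.key: r for r in self.residues}
        if len(self._by_key) != len(self.residues):
            raise ValueError("duplicate residue keys (chain, number, icode)")

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, key: ResidueKey) -> Residue | None:
        return self._by_key.get(key)

    def side_of(self, chain_id: str) -> Literal["receptor", "peptide"]:
        if chain_id in self.receptor_chains:
            return "receptor"
        if chain_id in self.peptide_chains:
            return "peptide"
        raise KeyError(chain_id)

    def receptor_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.chain_id in self.receptor_chains]

    def peptide_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.chain_id in self.peptide_chains]

    def iter_atoms(self, heavy_only: bool = False) -> Iterator[tuple[Residue, Atom]]:
        for r in self.residues:
            for a in r.atoms:
                if heavy_only and a.is_hydrogen:
                    continue
                yield r, a

    def copy(self) -> "ComplexStructure":
        residues = [
            Residue(
                r.chain_id,
                r.number,
                r.icode,
                r.name,
                [Atom(a.name, a.element, a.coords.copy(), a.occupancy, a.altloc, a.bfactor) for a in r.atoms],
            )
            for r in self.residues
        ]
        return ComplexStructure(residues, self.receptor_chains, self.peptide_chains)


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one atom per name: highest occupancy, ties broken by file order."""
    best: dict[str, Atom] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in best:
            best[a.name] = a
            order.append(a.name)
        elif a.occupancy > best[a.name].occupancy:
            best[a.name] = a
    return [best[n] for n in order]


def read_structure(
    path: str | Path,
    receptor_chains: Iterable[str],
    peptide_chains: Iterable[str],
) -> ComplexStructure:
    """Read a PDB file and designate receptor and peptide chains.

    Waters and HETATM records are excluded, except MSE which is mapped to
    MET (SE renamed to SD) with a warning.  Hydrogens are retained in the
    structure but excluded from all metrics except hydrogen-bond detection.
    Alternate locations are resolved to the highest-occupancy conformer
    (ties: first in file).

    Raises
    ------
    ValueError
        If a designated chain is absent or contains no protein residues.
    """
    receptor_chains = frozenset(receptor_chains)
    peptide_chains = frozenset(peptide_chains)
    designated = receptor_chains | peptide_chains

    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise ValueError(f"{path}: no models in file")
    model = st[0]

    residues: list[Residue] = []
    seen_chains: set[str] = set()
    for chain in model:
        seen_chains.add(chain.name)
        if chain.name not in designated:
            continue
        for gres in chain:
            name = gres.name
            if name in _WATER_NAMES:
                continue
            if gres.het_flag == "H" and name not in _PARENT_RESIDUE:
                continue
            rename = _PARENT_ATOM_RENAME.get(name, {})
            if name in _PARENT_RESIDUE:
                warnings.warn(
                    f"nonstandard residue {name} at {chain.name}{gres.seqid.num} mapped to "
                    f"{_PARENT_RESIDUE[name]}",
                    stacklevel=2,
                )
                name = _PARENT_RESIDUE[gres.name]
            atoms = [
                Atom(
                    name=rename.get(ga.name, ga.name),
                    element=ga.element.name,
                    coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    occupancy=ga.occ,
                    altloc=ga.altloc if ga.altloc != "\x00" else "",
                    bfactor=ga.b_iso,
                )
                for ga in gres
            ]
            atoms = _resolve_altlocs(atoms)
            icode = gres.seqid.icode.strip()
            residues.append(Residue(chain.name, gres.seqid.num, icode, name, atoms))

    for cid in sorted(designated):
        if cid not in seen_chains:
            raise ValueError(f"{path}: designated chain {cid!r} not present in file")
        if not any(r.chain_id == cid for r in residues):
            raise ValueError(f"{path}: designated chain {cid!r} has no protein residues")

    return ComplexStructure(residues, receptor_chains, peptide_chains)


def write_structure(
    structure: ComplexStructure,
    path: str | Path,
    remarks: Sequence[str] = (),
) -> None:
    """Write a ComplexStructure as a PDB file (coordinates to 0.001 Å).

    ``remarks`` are emitted as ``REMARK 999`` lines before the coordinates.
    """
    st = gemmi.Structure()
    st.name = "pepqa"
    model = gemmi.Model("1")
    chain_order: list[str] = []
    chains: dict[str, gemmi.Chain] = {}
    for r in structure.residues:
        if r.chain_id not in chains:
            chains[r.chain_id] = gemmi.Chain(r.chain_id)
            chain_order.append(r.chain_id)
        gres = gemmi.Residue()
        gres.name = r.name
        gres.seqid = gemmi.SeqId(r.number, r.icode if r.icode else " ")
        gres.het_flag = "A"
        for a in r.atoms:
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element)
            ga.pos = gemmi.Position(*a.coords)
            ga.occ = a.occupancy
            ga.b_iso = a.bfactor
            if a.altloc:
                ga.altloc = a.altloc
            gres.add_atom(ga)
        chains[r.chain_id].add_residue(gres)
    for cid in chain_order:
        model.add_chain(chains[cid])
    st.add_model(model)

    body = st.make_pdb_string()
    header = "".join(f"REMARK 999 {line}\n" for line in remarks)
    Path(path).write_text(header + body)


@dataclass
class CorrespondenceMap:
    """Residue- and atom-level pairing between a reference and a model.

    Atom pairs only join identically named atoms.  When a paired residue's
    name differs between reference and model (threaded models), only the
    backbone atoms are paired, so side-chain metrics honestly exclude it.
    """

    residue_pairs: list[tuple[ResidueKey, ResidueKey]]
    atom_pairs: dict[tuple[ResidueKey, ResidueKey], list[tuple[str, str]]]
    unpaired_reference: list[ResidueKey] = field(default_factory=list)
    unpaired_model: list[ResidueKey] = field(default_factory=list)
    mismatched_names: list[tuple[ResidueKey, ResidueKey]] = field(default_factory=list)

    def model_key(self, reference_key: ResidueKey) -> ResidueKey | None:
        if not hasattr(self, "_ref_to_model"):
            self._ref_to_model = dict(self.residue_pairs)
        return self._ref_to_model.get(reference_key)


def build_correspondence(
    reference: ComplexStructure,
    model: ComplexStructure,
    chain_map: dict[str, str] | None = None,
) -> CorrespondenceMap:
    """Pair residues and atoms of a model against the reference.

    Residues are paired by ``(mapped chain, number, icode)``; atoms by
    identical name among heavy atoms.  Unpaired residues are recorded, not
    fatal.  ``chain_map`` maps reference chain ids to model chain ids and
    defaults to the identity on the designated chains.
    """
    if chain_map is None:
        chain_map = {c: c for c in reference.receptor_chains | reference.peptide_chains}
    missing = (reference.receptor_chains | reference.peptide_chains) - set(chain_map)
    if missing:
        raise ValueError(f"chain_map does not cover reference chains {sorted(missing)}")

    residue_pairs: list[tuple[ResidueKey, ResidueKey]] = []
    atom_pairs: dict[tuple[ResidueKey, ResidueKey], list[tuple[str, str]]] = {}
    unpaired_ref: list[ResidueKey] = []
    mismatched: list[tuple[ResidueKey, ResidueKey]] = []
    matched_model: set[ResidueKey] = set()

    for ref_res in reference.residues:
        mkey = (chain_map[ref_res.chain_id], ref_res.number, ref_res.icode)
        mod_res = model.residue(mkey)
        if mod_res is None:
            unpaired_ref.append(ref_res.key)
            continue
        pair = (ref_res.key, mod_res.key)
        residue_pairs.append(pair)
        matched_model.add(mod_res.key)
        backbone_only = ref_res.name != mod_res.name
        if backbone_only:
            mismatched.append(pair)
            warnings.warn(
                f"residue name mismatch at {ref_res.key}: {ref_res.name} vs {mod_res.name}; "
                "pairing backbone atoms only",
                stacklevel=2,
            )
        model_names = {a.name for a in mod_res.heavy_atoms()}
        pairs: list[tuple[str, str]] = []
        for a in ref_res.heavy_atoms():
            if backbone_only and a.name not in BACKBONE_ATOMS:
                continue
            if a.name in model_names:
                pairs.append((a.name, a.name))
        atom_pairs[pair] = pairs

    unpaired_model = [r.key for r in model.residues if r.key not in matched_model]
    return CorrespondenceMap(residue_pairs, atom_pairs, unpaired_ref, unpaired_model, mismatched)


def select_atoms(
    residue: Residue,
    selector: Literal["backbone", "sidechain", "all-heavy"],
) -> list[Atom]:
    """Select heavy atoms of a residue by role.

    ``backbone`` is {N, CA, C, O}; ``sidechain`` is every other heavy atom
    (CB included; empty for Gly); ``all-heavy`` is their union.  Hydrogens
    are never returned.
    """
    heavy = residue.heavy_atoms()
    if selector == "all-heavy":
        return heavy
    if selector == "backbone":
        return [a for a in heavy if a.name in BACKBONE_ATOMS]
    if selector == "sidechain":
        return [a for a in heavy if a.name not in BACKBONE_ATOMS]
    raise ValueError(f"unknown selector {selector!r}")
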