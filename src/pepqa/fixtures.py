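"""Synthetic peptide-receptor complexes and controlled model ensembles.

Everything the metrics need can be exercised without downloading any real
structure.  :func:`make_toy_complex` builds an idealised β-sheet complex:
receptor strands (one for ``flat`` geometry, two flanking strands forming
a groove for ``groove``) and a peptide strand laid between them, with
inter-strand backbone hydrogen bonding.  Backbones are constructed from
ideal internal coordinates (NeRF chain extension with antiparallel-β
dihedrals); side chains are grafted from ideal residue templates
(chemical component dictionary geometry via biotite), so bond lengths and
angles are ideal by construction.

:func:`perturb` derives model ensembles from a reference:

* ``rigid`` — a rigid transform of the whole peptide (receptor untouched),
  so L-RMSD has a closed form for pure translations;
* ``sidechain`` — Gaussian noise on side-chain chi angles with the
  backbone untouched, so I-RMSD stays 0 while S-RMSD grows;
* ``mixed`` — both.

:func:`make_ddg_ensemble` emits synthetic alanine-scanning ΔΔG tables
with hotspots planted at chosen residues, for testing the hit-rate and
recovery aggregation end to end.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contacts import contacts
from .hbonds import detect_interface_hbonds
from .structure import Atom, ComplexStructure, Residue

__all__ = [
    "FixtureSpec",
    "PerturbationSpec",
    "make_toy_complex",
    "perturb",
    "make_ddg_ensemble",
    "fixture_remarks",
    "CHI_ATOMS",
]

# Ideal backbone internal coordinates (Engh-Huber-style values).
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8
# Antiparallel β-strand dihedrals.
_PHI_BETA, _PSI_BETA, _OMEGA = -139.0, 135.0, 180.0

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

#: Alphabet for random sequences: all standard residues except proline
#: (no backbone donor, breaks strand hydrogen bonding).
_RANDOM_ALPHABET = "ARNDCQEGHILKMFSTWYV"

#: Standard side-chain chi-angle definitions (atoms a1-a2-a3-a4); rotating
#: chi_k about the a2-a3 bond moves every side-chain atom distal to a3.
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"), ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"), ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"), ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
}

_BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}


@dataclass
class FixtureSpec:
    """Parameters of a toy complex.

    ``geometry='groove'`` splits the receptor into two strands flanking the
    peptide; ``'flat'`` uses a single receptor strand beside it.
    """

    n_receptor_residues: int = 24
    n_peptide_residues: int = 8
    receptor_sequence: str | None = None
    peptide_sequence: str | None = None
    geometry: str = "groove"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_peptide_residues < 3:
            raise ValueError("peptide must have at least 3 residues")
        if self.geometry not in ("groove", "flat"):
            raise ValueError(f"geometry must be 'groove' or 'flat', got {self.geometry!r}")
        if self.geometry == "groove" and self.n_receptor_residues < 8:
            raise ValueError("groove geometry needs at least 8 receptor residues")
        if self.geometry == "flat" and self.n_receptor_residues < 4:
            raise ValueError("flat geometry needs at least 4 receptor residues")


@dataclass
class PerturbationSpec:
    """Parameters of a model ensemble derived from one reference."""

    kind: str = "rigid"
    translation: float | tuple[float, float, float] = 0.0
    rotation_deg: float = 0.0
    rotation_axis: tuple[float, float, float] | None = None
    chi_noise_deg: float = 0.0
    n_models: int = 1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("rigid", "sidechain", "mixed"):
            raise ValueError(f"kind must be rigid|sidechain|mixed, got {self.kind!r}")
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")


# ---------------------------------------------------------------------------
# Internal-coordinate backbone construction
# ---------------------------------------------------------------------------


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, dihedral_deg: float,
) -> np.ndarray:
    """NeRF placement: position d with given c-d bond, b-c-d angle, a-b-c-d dihedral."""
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    ang, dih = math.radians(angle_deg), math.radians(dihedral_deg)
    local = np.array(
        [-bond * math.cos(ang), bond * math.sin(ang) * math.cos(dih), bond * math.sin(ang) * math.sin(dih)]
    )
    return c + local[0] * bc + local[1] * m + local[2] * n


def _build_strand_backbone(n_res: int) -> list[dict[str, np.ndarray]]:
    """N/CA/C/O coordinates of an ideal antiparallel-β strand."""
    res: list[dict[str, np.ndarray]] = []
    n0 = np.zeros(3)
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    ang = math.radians(_A_N_CA_C)
    c0 = ca0 + _B_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    res.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        prev = res[-1]
        n = _place_atom(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, _PSI_BETA)
        ca = _place_atom(prev["CA"], prev["C"], n, _B_N_CA, _A_C_N_CA, _OMEGA)
        c = _place_atom(prev["C"], n, ca, _B_CA_C, _A_N_CA_C, _PHI_BETA)
        res.append({"N": n, "CA": ca, "C": c})
    for i, r in enumerate(res):
        psi = _PSI_BETA  # trans carbonyl for the C-terminal residue as well
        r["O"] = _place_atom(r["N"], r["CA"], r["C"], _B_C_O, _A_CA_C_O, psi + 180.0)
    return res


def _canonical_frame(backbone: list[dict[str, np.ndarray]]) -> list[dict[str, np.ndarray]]:
    """Rotate/translate a strand so its axis is +x and carbonyls point in ±y."""
    ca = np.array([r["CA"] for r in backbone])
    x_axis = _unit(ca[-1] - ca[0])
    co = np.mean([_unit(r["O"] - r["C"]) for r in backbone], axis=0)
    y_axis = _unit(co - np.dot(co, x_axis) * x_axis)
    z_axis = np.cross(x_axis, y_axis)
    rot = np.array([x_axis, y_axis, z_axis])  # rows: world directions of new axes
    centre = ca.mean(axis=0)
    return [{name: rot @ (pos - centre) for name, pos in r.items()} for r in backbone]


def _transform_strand(
    backbone: list[dict[str, np.ndarray]], rot: np.ndarray, shift: np.ndarray
) -> list[dict[str, np.ndarray]]:
    return [{name: rot @ pos + shift for name, pos in r.items()} for r in backbone]


_FLIP_Z = np.diag([-1.0, -1.0, 1.0])   # antiparallel, same sheet face
_FLIP_Y = np.diag([-1.0, 1.0, -1.0])   # antiparallel, flipped pleat


def _strand_arrays(strand) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = np.array([r["N"] for r in strand])
    o = np.array([r["O"] for r in strand])
    allb = np.array([pos for r in strand for pos in r.values()])
    return n, o, allb


def _best_strand_placement(
    peptide_bb, strand_bb, z_side: float
) -> list[dict[str, np.ndarray]]:
    """Place an antiparallel receptor strand beside the peptide.

    Strand carbonyls alternate along ±z in the canonical frame, so sheet
    neighbours sit at a z offset.  Deterministic grid search over the
    strand register (x shift), sheet separation (z), a small axial slip
    (y) and the two antiparallel flips, maximising inter-strand backbone
    N···O pairing while penalising steric overlap.
    """
    na, oa, pa = _strand_arrays(peptide_bb)
    dxs = np.arange(-6.0, 6.0, 0.2)
    best, best_score = None, -math.inf
    for rot in (_FLIP_Z, _FLIP_Y):
        nb0, ob0, pb0 = _strand_arrays(_transform_strand(strand_bb, rot, np.zeros(3)))
        for sep in np.arange(4.0, 6.2, 0.1):
            for dy in (-1.0, -0.5, 0.0, 0.5, 1.0):
                base = np.array([0.0, dy, z_side * sep])
                shifts = base + dxs[:, None] * np.array([1.0, 0.0, 0.0])  # (k, 3)
                # distances for all registers at once: (k, |A|, |B|)
                d1 = np.linalg.norm(na[None, :, None, :] - (ob0[None, None, :, :] + shifts[:, None, None, :]), axis=-1)
                d2 = np.linalg.norm((nb0[None, None, :, :] + shifts[:, None, None, :]) - oa[None, :, None, :], axis=-1)
                dp = np.linalg.norm(pa[None, :, None, :] - (pb0[None, None, :, :] + shifts[:, None, None, :]), axis=-1)
                scores = (
                    ((d1 > 2.6) & (d1 < 3.3)).sum(axis=(1, 2))
                    + ((d2 > 2.6) & (d2 < 3.3)).sum(axis=(1, 2))
                    - 10.0 * (dp < 2.5).sum(axis=(1, 2))
                )
                k = int(np.argmax(scores))
                if scores[k] > best_score + 1e-9:
                    best = _transform_strand(strand_bb, rot, shifts[k])
                    best_score = float(scores[k])
    return best


# ---------------------------------------------------------------------------
# Side-chain grafting from ideal residue templates
# ---------------------------------------------------------------------------

_template_cache: dict[str, tuple[np.ndarray, list[tuple[str, str]], np.ndarray]] = {}


def _residue_template(resname: str):
    """Ideal-geometry heavy-atom template of a residue (CCD, via biotite).

    Returns (frame coords of N/CA/C, [(sidechain atom, element)...],
    side-chain coords in template frame).
    """
    if resname not in _template_cache:
        import biotite.structure.info as struc_info

        tmpl = struc_info.residue(resname)
        heavy = tmpl[~np.isin(tmpl.element, ["H", "D"])]
        names = list(heavy.atom_name)
        frame = np.array([heavy.coord[names.index(a)] for a in ("N", "CA", "C")], dtype=float)
        side_idx = [
            i for i, n in enumerate(names) if n not in _BACKBONE_NAMES
        ]
        side_atoms = [(names[i], str(heavy.element[i])) for i in side_idx]
        side_coords = heavy.coord[side_idx].astype(float)
        _template_cache[resname] = (frame, side_atoms, side_coords)
    return _template_cache[resname]


def _graft_sidechain(resname: str, bb: dict[str, np.ndarray]) -> list[Atom]:
    """Side-chain atoms positioned by superposing the ideal template on the backbone."""
    if resname == "GLY":
        return []
    from .rmsd import kabsch

    frame, side_atoms, side_coords = _residue_template(resname)
    target = np.array([bb["N"], bb["CA"], bb["C"]])
    transform, _ = kabsch(frame, target)
    placed = transform.apply(side_coords)
    return [Atom(name, element, coords) for (name, element), coords in zip(side_atoms, placed)]


def _make_residue(chain_id: str, number: int, resname: str, bb: dict[str, np.ndarray]) -> Residue:
    atoms = [
        Atom("N", "N", bb["N"]),
        Atom("CA", "C", bb["CA"]),
        Atom("C", "C", bb["C"]),
        Atom("O", "O", bb["O"]),
    ]
    atoms.extend(_graft_sidechain(resname, bb))
    return Residue(chain_id, number, "", resname, atoms)


def _sidechain_badness(structure: ComplexStructure, res: Residue, min_dist: float) -> tuple[int, float]:
    """Severe-overlap count and depth of a residue's side chain against all others."""
    side = [a.coords for a in res.atoms if a.name not in _BACKBONE_NAMES]
    if not side:
        return 0, 0.0
    others = np.array(
        [a.coords for other in structure.residues if other is not res for a in other.atoms]
    )
    dist = np.linalg.norm(np.array(side)[:, None, :] - others[None, :, :], axis=-1)
    bad = dist < min_dist
    return int(bad.sum()), float(np.sum(min_dist - dist[bad]))


def _truncate_to_alanine(res: Residue) -> None:
    res.atoms = [a for a in res.atoms if a.name in ("N", "CA", "C", "O", "CB")]
    res.name = "ALA" if res.atom("CB") is not None else "GLY"
    if res.name == "GLY":
        return


def _relieve_clashes(structure: ComplexStructure, min_dist: float = 2.2) -> None:
    """Deterministically remove severe side-chain overlaps.

    Offending residues first try coarse chi1/chi2 rotamer flips (120°
    steps); side chains that cannot be packed are truncated to alanine.
    Idealised strands carry no rotamer optimisation, so this pass is what
    keeps the fixture free of interpenetrating atoms.
    """
    for _ in range(3):
        offenders = [
            res for res in structure.residues if _sidechain_badness(structure, res, min_dist)[0] > 0
        ]
        if not offenders:
            return
        for res in offenders:
            chis = CHI_ATOMS.get(res.name, [])[:2]
            if chis:
                options = [(0.0, 0.0)]
                for d1 in (0.0, 120.0, 240.0):
                    for d2 in (0.0, 120.0, 240.0) if len(chis) > 1 else (0.0,):
                        options.append((d1, d2))
                original = {a.name: a.coords.copy() for a in res.atoms}
                best_choice, best_bad = None, None
                for d1, d2 in options:
                    for a in res.atoms:
                        a.coords = original[a.name].copy()
                    if d1:
                        _rotate_chi(res, chis[0], d1)
                    if d2 and len(chis) > 1:
                        _rotate_chi(res, chis[1], d2)
                    bad = _sidechain_badness(structure, res, min_dist)
                    if best_bad is None or bad < best_bad:
                        best_bad, best_choice = bad, (d1, d2)
                for a in res.atoms:
                    a.coords = original[a.name].copy()
                if best_choice[0]:
                    _rotate_chi(res, chis[0], best_choice[0])
                if best_choice[1] and len(chis) > 1:
                    _rotate_chi(res, chis[1], best_choice[1])
                if best_bad[0] == 0:
                    continue
            _truncate_to_alanine(res)


def _pick_sequence(rng: np.random.Generator, n: int, explicit: str | None) -> list[str]:
    if explicit is not None:
        seq = [_ONE_TO_THREE.get(c.upper()) for c in explicit]
        if None in seq:
            raise ValueError(f"unknown one-letter code in sequence {explicit!r}")
        if len(seq) != n:
            raise ValueError(f"sequence length {len(seq)} != requested {n} residues")
        return seq
    letters = rng.choice(list(_RANDOM_ALPHABET), size=n)
    return [_ONE_TO_THREE[c] for c in letters]


def make_toy_complex(spec: FixtureSpec) -> ComplexStructure:
    """Build an idealised β-sheet peptide-receptor complex.

    The result is guaranteed to have at least 5 cross-partition residue
    contacts at 4 Å and at least one cross-partition hydrogen bond;
    otherwise an error is raised (the spec cannot be satisfied).
    """
    rng = np.random.default_rng(spec.rng_seed)
    pep_seq = _pick_sequence(rng, spec.n_peptide_residues, spec.peptide_sequence)
    rec_seq = _pick_sequence(rng, spec.n_receptor_residues, spec.receptor_sequence)

    pep_bb = _canonical_frame(_build_strand_backbone(spec.n_peptide_residues))

    if spec.geometry == "groove":
        n1 = spec.n_receptor_residues // 2
        n2 = spec.n_receptor_residues - n1
        strands = [
            (_canonical_frame(_build_strand_backbone(n1)), +1.0),
            (_canonical_frame(_build_strand_backbone(n2)), -1.0),
        ]
    else:
        strands = [(_canonical_frame(_build_strand_backbone(spec.n_receptor_residues)), +1.0)]

    residues: list[Residue] = []
    number = 1
    seq_pos = 0
    for strand_bb, side in strands:
        placed = _best_strand_placement(pep_bb, strand_bb, side)
        for bb in placed:
            residues.append(_make_residue("A", number, rec_seq[seq_pos], bb))
            number += 1
            seq_pos += 1
        number += 2  # numbering gap marks the chain break between strands

    for i, bb in enumerate(pep_bb):
        residues.append(_make_residue("B", i + 1, pep_seq[i], bb))

    structure = ComplexStructure(residues, receptor_chains={"A"}, peptide_chains={"B"})
    _relieve_clashes(structure)

    n_contacts = len(contacts(structure, cutoff=4.0))
    n_hbonds = len(detect_interface_hbonds(structure))
    if n_contacts < 5 or n_hbonds < 1:
        raise ValueError(
            f"fixture geometry guarantee violated: {n_contacts} contacts, {n_hbonds} H-bonds "
            f"(need >= 5 and >= 1); adjust the spec"
        )
    return structure


def fixture_remarks(spec: FixtureSpec) -> list[str]:
    """REMARK lines recording the generating spec (seed included)."""
    return [
        "pepqa synthetic fixture",
        f"n_receptor_residues={spec.n_receptor_residues} n_peptide_residues={spec.n_peptide_residues}",
        f"geometry={spec.geometry} rng_seed={spec.rng_seed}",
    ]


# ---------------------------------------------------------------------------
# Perturbation ensembles
# ---------------------------------------------------------------------------


def _rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = _unit(np.asarray(axis, dtype=float))
    a = math.radians(angle_deg)
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(a) * k + (1 - math.cos(a)) * (k @ k)


def _bonded_pairs(res: Residue) -> dict[str, set[str]]:
    """Intra-residue heavy-atom connectivity inferred from distances."""
    heavy = res.heavy_atoms()
    adj: dict[str, set[str]] = {a.name: set() for a in heavy}
    for i, a in enumerate(heavy):
        for b in heavy[i + 1 :]:
            limit = 2.2 if ("S" in (a.element, b.element)) else 1.95
            if np.linalg.norm(a.coords - b.coords) < limit:
                adj[a.name].add(b.name)
                adj[b.name].add(a.name)
    return adj


def _distal_atoms(res: Residue, pivot: str, ahead: str) -> set[str]:
    """Atoms reachable from ``ahead`` without passing back through ``pivot``."""
    adj = _bonded_pairs(res)
    seen = {pivot, ahead}
    stack = [ahead]
    while stack:
        for nxt in adj.get(stack.pop(), ()):
            if nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    seen.discard(pivot)
    seen.discard(ahead)
    return seen


def _rotate_chi(res: Residue, chi: tuple[str, str, str, str], delta_deg: float) -> None:
    _, a2, a3, _ = chi
    p2, p3 = res.atom(a2), res.atom(a3)
    if p2 is None or p3 is None:
        return
    rot = _rotation_matrix(p3.coords - p2.coords, delta_deg)
    moving = _distal_atoms(res, a2, a3)  # a2/a3 lie on the axis and stay put
    for atom in res.atoms:
        if atom.name in moving:
            atom.coords = rot @ (atom.coords - p3.coords) + p3.coords


def _perturb_sidechains(structure: ComplexStructure, rng: np.random.Generator, sd_deg: float) -> None:
    for res in structure.residues:
        for chi in CHI_ATOMS.get(res.name, []):
            delta = float(rng.normal(0.0, sd_deg)) if sd_deg > 0 else 0.0
            if delta != 0.0:
                _rotate_chi(res, chi, delta)


def perturb(reference: ComplexStructure, spec: PerturbationSpec) -> list[ComplexStructure]:
    """Generate a deterministic ensemble of perturbed models.

    Rigid perturbations move the peptide only (rotation about the peptide
    centroid, then translation); side-chain perturbations add Gaussian
    noise to every chi angle, leaving all backbones untouched.  Models
    keep the reference numbering, so correspondence is the identity.
    """
    rng = np.random.default_rng(spec.rng_seed)
    models: list[ComplexStructure] = []
    for _ in range(spec.n_models):
        model = reference.copy()
        if spec.kind in ("sidechain", "mixed"):
            _perturb_sidechains(model, rng, spec.chi_noise_deg)
        if spec.kind in ("rigid", "mixed"):
            if isinstance(spec.translation, (int, float)):
                direction = rng.normal(size=3)
                direction = direction / np.linalg.norm(direction)
                shift = float(spec.translation) * direction
            else:
                shift = np.asarray(spec.translation, dtype=float)
            if spec.rotation_deg:
                axis = (
                    np.asarray(spec.rotation_axis, dtype=float)
                    if spec.rotation_axis is not None
                    else rng.normal(size=3)
                )
                rot = _rotation_matrix(axis, spec.rotation_deg)
            else:
                rot = np.eye(3)
            pep_atoms = [a for r in model.peptide_residues() for a in r.atoms]
            centroid = np.mean([a.coords for a in pep_atoms], axis=0)
            for atom in pep_atoms:
                atom.coords = rot @ (atom.coords - centroid) + centroid + shift
        models.append(model)
    return models


# ---------------------------------------------------------------------------
# Synthetic ΔΔG ensembles
# ---------------------------------------------------------------------------


def make_ddg_ensemble(
    universe: list[tuple[str, int, str]],
    planted_hotspots: set[tuple[str, int, str]],
    n_models: int,
    hot_mean: float = 2.0,
    cold_mean: float = 0.0,
    noise_sd: float = 0.5,
    rng_seed: int = 0,
    wt_names: dict[tuple[str, int, str], str] | None = None,
) -> pd.DataFrame:
    """Synthetic alanine-scan tables with planted hotspots.

    For each model and residue, ddg ~ Normal(hot_mean, noise_sd) at
    planted hotspots and Normal(cold_mean, noise_sd) elsewhere.  Returns a
    tidy table in the canonical ΔΔG layout (one row per model × residue).
    """
    if hot_mean <= cold_mean:
        raise ValueError("hot_mean must exceed cold_mean")
    unknown = planted_hotspots - set(universe)
    if unknown:
        raise ValueError(f"planted hotspots outside the universe: {sorted(unknown)}")
    rng = np.random.default_rng(rng_seed)
    rows = []
    for m in range(n_models):
        model_id = f"model_{m:03d}"
        for key in universe:
            mean = hot_mean if key in planted_hotspots else cold_mean
            ddg = mean + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            rows.append(
                {
                    "model_id": model_id,
                    "chain": key[0],
                    "resnum": key[1],
                    "icode": key[2],
                    "wt": (wt_names or {}).get(key, "XAA"),
                    "mut": "ALA",
                    "ddg": round(float(ddg), 4),
                }
            )
    return pd.DataFrame(rows)
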