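"""Shared fixtures: synthetic complexes and hand-built mini-structures."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from pepqa import ComplexStructure, FixtureSpec, make_toy_complex
from pepqa.structure import Atom, Residue


@pytest.fixture(scope="session")
def toy_complex() -> ComplexStructure:
    """Default groove fixture: 24-residue receptor (two strands), 8-residue peptide."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return make_toy_complex(FixtureSpec())


@pytest.fixture(scope="session")
def flat_complex() -> ComplexStructure:
    """Smaller single-strand fixture for cheaper tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return make_toy_complex(FixtureSpec(geometry="flat", n_receptor_residues=10, rng_seed=7))


def make_residue(chain: str, number: int, name: str, atoms: dict[str, np.ndarray], icode: str = "") -> Residue:
    """Hand-build a residue from {atom name: coords}; element from the name."""
    built = []
    for atom_name, coords in atoms.items():
        element = "".join(c for c in atom_name if c.isalpha())[0]
        built.append(Atom(atom_name, element, np.asarray(coords, dtype=float)))
    return Residue(chain, number, icode, name, built)


def two_residue_complex(dist: float, name_a: str = "ALA", name_b: str = "ALA") -> ComplexStructure:
    """One receptor and one peptide residue with CB-CB separation ``dist``."""
    res_a = make_residue("A", 1, name_a, {
        "N": (0, 1.4, 0), "CA": (0, 0, 0), "C": (1.4, 0, 0), "O": (1.4, -1.2, 0), "CB": (-1.0, -1.0, 0),
    })
    res_b = make_residue("B", 1, name_b, {
        "N": (0, 1.4, dist), "CA": (0, 0, dist), "C": (1.4, 0, dist), "O": (1.4, -1.2, dist),
        "CB": (-1.0, -1.0, dist),
    })
    return ComplexStructure([res_a, res_b], {"A"}, {"B"})


def random_rigid_transform(rng: np.random.Generator):
    """A uniformly random proper rotation and a random translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    return rot, rng.normal(scale=10.0, size=3)


def apply_global_transform(structure: ComplexStructure, rot: np.ndarray, shift: np.ndarray) -> ComplexStructure:
    """Rigidly move the whole structure (receptor and peptide together)."""
    moved = structure.copy()
    for _, atom in moved.iter_atoms():
        atom.coords = rot @ atom.coords + shift
    return moved
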