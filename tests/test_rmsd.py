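"""Kabsch superposition and the L-/I-/S-RMSD measures."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pepqa import (
    PerturbationSpec,
    build_correspondence,
    interface_residues,
    interface_rmsd,
    kabsch,
    ligand_rmsd,
    perturb,
)
from pepqa.fixtures import _rotate_chi
from pepqa.structure import BACKBONE_ATOMS

from conftest import apply_global_transform, random_rigid_transform


def test_kabsch_identity():
    pts = np.random.default_rng(0).normal(size=(10, 3))
    transform, rmsd = kabsch(pts, pts)
    assert rmsd == pytest.approx(0.0, abs=1e-9)
    np.testing.assert_allclose(transform.rotation, np.eye(3), atol=1e-9)
    np.testing.assert_allclose(transform.translation, 0.0, atol=1e-9)


def test_kabsch_recovers_exact_rigid_motion():
    rng = np.random.default_rng(1)
    pts = rng.normal(size=(12, 3))
    rot_z90 = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
    target = pts @ rot_z90.T + np.array([1.0, 2.0, 3.0])
    transform, rmsd = kabsch(pts, target)
    assert rmsd == pytest.approx(0.0, abs=1e-9)
    np.testing.assert_allclose(transform.rotation, rot_z90, atol=1e-9)
    np.testing.assert_allclose(transform.apply(pts), target, atol=1e-9)


def test_kabsch_agrees_with_scipy_align_vectors():
    """Independent oracle: scipy's constrained Procrustes solution."""
    rng = np.random.default_rng(2)
    for _ in range(5):
        mobile = rng.normal(size=(10, 3))
        target = mobile + rng.normal(scale=0.3, size=(10, 3))
        _, rmsd = kabsch(mobile, target)
        mc, tc = mobile.mean(axis=0), target.mean(axis=0)
        rot, rssd = Rotation.align_vectors(target - tc, mobile - mc)
        oracle = rssd / math.sqrt(len(mobile))
        assert rmsd == pytest.approx(oracle, abs=1e-3)


def test_kabsch_is_optimal_among_random_transforms():
    rng = np.random.default_rng(3)
    mobile = rng.normal(size=(8, 3))
    target = mobile + rng.normal(scale=0.5, size=(8, 3))
    _, best = kabsch(mobile, target)
    for _ in range(50):
        rot, shift = random_rigid_transform(rng)
        other = np.sqrt(np.mean(np.sum((mobile @ rot.T + shift - target) ** 2, axis=1)))
        assert best <= other + 1e-9


def test_kabsch_rejects_tiny_and_warns_on_collinear():
    with pytest.raises(ValueError):
        kabsch(np.zeros((2, 3)), np.zeros((2, 3)))
    line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
    with pytest.warns(UserWarning, match="collinear"):
        kabsch(line, line + np.array([0.0, 1.0, 0.0]))


# ---------------------------------------------------------------------------
# L-RMSD
# ---------------------------------------------------------------------------


def test_ligand_rmsd_identity_is_zero(toy_complex):
    cmap = build_correspondence(toy_complex, toy_complex)
    assert ligand_rmsd(toy_complex, toy_complex, cmap) == pytest.approx(0.0, abs=1e-9)


@pytest.mark.parametrize("magnitude", [0.5, 2.5, 7.0])
def test_ligand_rmsd_equals_pure_translation_magnitude(toy_complex, magnitude):
    model = perturb(toy_complex, PerturbationSpec(kind="rigid", translation=(magnitude, 0, 0)))[0]
    cmap = build_correspondence(toy_complex, model)
    assert ligand_rmsd(toy_complex, model, cmap) == pytest.approx(magnitude, abs=1e-9)


def test_ligand_rmsd_matches_two_step_oracle(toy_complex):
    """Rotation+translation case against an explicit fit-then-sum computation."""
    model = perturb(
        toy_complex,
        PerturbationSpec(kind="rigid", translation=(1.0, 0.5, -0.3), rotation_deg=25.0,
                         rotation_axis=(0, 0, 1)),
    )[0]
    cmap = build_correspondence(toy_complex, model)
    value = ligand_rmsd(toy_complex, model, cmap)

    # oracle: receptor fit and peptide deviation computed explicitly here
    def backbone(structure, side):
        res = structure.receptor_residues() if side == "receptor" else structure.peptide_residues()
        return np.array([r.atom(n).coords for r in res for n in ("N", "CA", "C", "O") if r.atom(n)])

    rec_ref, rec_mod = backbone(toy_complex, "receptor"), backbone(model, "receptor")
    transform, _ = kabsch(rec_mod, rec_ref)
    pep_ref, pep_mod = backbone(toy_complex, "peptide"), backbone(model, "peptide")
    moved = transform.apply(pep_mod)
    oracle = math.sqrt(np.mean(np.sum((moved - pep_ref) ** 2, axis=1)))
    assert value == pytest.approx(oracle, abs=1e-9)


# ---------------------------------------------------------------------------
# I-RMSD and S-RMSD
# ---------------------------------------------------------------------------


def test_interface_rmsd_identity_zero_in_both_modes(toy_complex):
    cmap = build_correspondence(toy_complex, toy_complex)
    assert interface_rmsd(toy_complex, toy_complex, cmap, "backbone") == pytest.approx(0.0, abs=1e-9)
    assert interface_rmsd(toy_complex, toy_complex, cmap, "sidechain") == pytest.approx(0.0, abs=1e-9)


def test_phe_ring_flip_has_zero_s_rmsd(toy_complex):
    """A 180° ring flip is chemically identical: symmetry swap absorbs it."""
    iface = interface_residues(toy_complex).residues
    model = toy_complex.copy()
    phe = next(r for r in model.residues if r.name in ("PHE", "TYR") and r.key in iface)
    _rotate_chi(phe, ("CA", "CB", "CG", "CD1"), 180.0)
    # the flip really moved atoms ...
    orig = toy_complex.residue(phe.key)
    assert not np.allclose(phe.atom("CD1").coords, orig.atom("CD1").coords)
    # ... but swapped naming makes it equivalent (template rings are
    # symmetric only to ~1e-3 Å, which bounds the residual)
    cmap = build_correspondence(toy_complex, model)
    assert interface_rmsd(toy_complex, model, cmap, "backbone") == pytest.approx(0.0, abs=1e-6)
    assert interface_rmsd(toy_complex, model, cmap, "sidechain") == pytest.approx(0.0, abs=5e-3)


def test_chi_scrambling_matches_direct_sum_oracle(toy_complex):
    """Backbone untouched: I-RMSD stays 0 and S-RMSD equals the explicit deviation sum."""
    model = perturb(toy_complex, PerturbationSpec(kind="sidechain", chi_noise_deg=25.0, rng_seed=5))[0]
    cmap = build_correspondence(toy_complex, model)
    assert interface_rmsd(toy_complex, model, cmap, "backbone") == pytest.approx(0.0, abs=1e-9)
    s = interface_rmsd(toy_complex, model, cmap, "sidechain")
    assert s > 0

    # oracle: per-atom squared deviations with per-residue symmetry minimisation
    from pepqa.rmsd import SYMMETRY_SWAPS

    iface = interface_residues(toy_complex).residues
    total, count = 0.0, 0
    for rkey in iface:
        ref_res = toy_complex.residue(rkey)
        mod_res = model.residue(rkey)
        names = [a.name for a in ref_res.heavy_atoms()
                 if a.name not in BACKBONE_ATOMS and mod_res.atom(a.name) is not None]
        if not names:
            continue
        swap = SYMMETRY_SWAPS.get(ref_res.name, {})
        ss_id = sum(np.sum((ref_res.atom(n).coords - mod_res.atom(n).coords) ** 2) for n in names)
        ss_sw = sum(
            np.sum((ref_res.atom(n).coords - mod_res.atom(swap.get(n, n)).coords) ** 2)
            for n in names
        )
        total += min(ss_id, ss_sw)
        count += len(names)
    oracle = math.sqrt(total / count)
    assert s == pytest.approx(oracle, abs=1e-9)


def test_s_rmsd_nan_for_glycine_interface():
    """An interface with no side chains has no defined S-RMSD."""
    from conftest import make_residue
    from pepqa import ComplexStructure

    def gly_chain(chain, z):
        residues = []
        for i in range(4):
            residues.append(make_residue(chain, i + 1, "GLY", {
                "N": (3.8 * i, 1.4, z), "CA": (3.8 * i, 0, z),
                "C": (3.8 * i + 1.4, 0, z), "O": (3.8 * i + 1.4, -1.2, z),
            }))
        return residues

    s = ComplexStructure(gly_chain("A", 0.0) + gly_chain("B", 4.5), {"A"}, {"B"})
    cmap = build_correspondence(s, s)
    with pytest.warns(UserWarning, match="S-RMSD undefined"):
        value = interface_rmsd(s, s, cmap, "sidechain")
    assert math.isnan(value)


def test_all_rmsds_invariant_under_global_rigid_transform(toy_complex):
    rng = np.random.default_rng(17)
    model = perturb(toy_complex, PerturbationSpec(kind="mixed", translation=(1.0, 0, 0),
                                                  chi_noise_deg=15.0, rng_seed=2))[0]
    cmap = build_correspondence(toy_complex, model)
    base = (
        ligand_rmsd(toy_complex, model, cmap),
        interface_rmsd(toy_complex, model, cmap, "backbone"),
        interface_rmsd(toy_complex, model, cmap, "sidechain"),
    )
    for _ in range(3):
        rot, shift = random_rigid_transform(rng)
        moved = apply_global_transform(model, rot, shift)
        cmap2 = build_correspondence(toy_complex, moved)
        values = (
            ligand_rmsd(toy_complex, moved, cmap2),
            interface_rmsd(toy_complex, moved, cmap2, "backbone"),
            interface_rmsd(toy_complex, moved, cmap2, "sidechain"),
        )
        np.testing.assert_allclose(values, base, atol=1e-6)
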