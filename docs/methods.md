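# Methods

This note documents the models, conventions and numerical choices behind
`pepqa`, in the order the data flows: structures → correspondence →
metrics → classification → hotspot aggregation → synthetic fixtures.

## Structures and correspondence

A complex is an ordered residue list with a hard partition of chains into
*receptor* and *peptide* sets; every metric is defined across that
partition. Parsing policy on top of gemmi's PDB reader:

* Alternate locations resolve to the highest-occupancy conformer, ties
  broken by file order — parsing is deterministic.
* Waters and HETATM records are dropped, except selenomethionine (MSE),
  which is mapped to MET (SE → SD) with a warning.
* Hydrogens are kept in the structure but excluded from every metric
  except hydrogen-bond detection.

Model-versus-reference correspondence pairs residues by
`(chain, number, insertion code)` after an optional chain renaming, and
atoms by identical PDB name. No sequence alignment is attempted: blind
docking submissions use the target numbering, and silently aligning
misnumbered inputs would hide a data problem rather than fix it.
Unpaired residues or atoms are recorded and reported, never fatal. When a
paired residue's *name* differs (threaded models), only backbone atoms
are paired: backbone metrics still work while the side-chain metric
honestly excludes the residue.

`select_atoms` defines backbone as {N, CA, C, O} and side chain as every
other heavy atom (CB included, Gly empty). Terminal OXT falls in the
side-chain set by this rule; the fixture generator does not emit OXT, and
for real structures one misassigned terminal oxygen is dwarfed by the
interface atom count.

## Contacts, clashes, interfaces

All three detectors use strict `<` against their cutoffs (8.0 Å CB/CB
for interface membership, 4.0 Å any-heavy-atom for residue contacts,
3.0 Å for atom-based clash counting), so boundary equality excludes.
Heavy atoms only: most docking models carry no hydrogens, and assessment
practice compares heavy-atom geometry; an `include_hydrogens` knob exists
for sensitivity analysis. fnat's denominator is always the reference
contact set — the measure is asymmetric by design, and non-native model
contacts can never raise or lower it. The clash count is informational
only; no disqualification rule is applied.

## Superposition and the RMSD family

The Kabsch fit is the SVD solution with the determinant correction that
forbids reflections. Collinear point sets still return a fit (the
in-plane rotation is underdetermined) but warn. Tests cross-check the
implementation against scipy's `Rotation.align_vectors` and against
random rigid transforms (optimality).

* L-RMSD fits on *all* paired receptor backbone atoms and evaluates the
  paired peptide backbone under that transform, with no refit — hence
  the exact identity L-RMSD = |t| for a pure peptide translation, which
  the tests assert to 1e-9.
* The interface for I-/S-RMSD is defined on the reference only: the
  native structure defines *the* interface, and a model is measured
  against it. A model-side interface would let a wrong model choose its
  own yardstick.
* S-RMSD evaluates side-chain heavy atoms in the I-RMSD superposition
  frame rather than refitting on side chains: the measure is meant to ask
  "given the backbone placement, are the side chains right?", and a
  side-chain refit would reward internally consistent but misplaced
  rotamer sets. A `fit_on="sidechain"` knob exists for sensitivity
  analysis.
* Symmetry-equivalent namings (Phe/Tyr CD1/CD2 + CE1/CE2, Asp OD1/OD2,
  Glu OE1/OE2, Arg NH1/NH2, Leu CD1/CD2, Val CG1/CG2) are resolved per
  residue as one whole-residue swap, choosing the naming that minimises
  that residue's summed squared deviation. His is not swapped: its ring
  nitrogens are chemically distinct. Missing model side-chain atoms are
  skipped (their pairs are simply absent), not penalised.
* An interface with no paired side-chain atoms (e.g. all-glycine) has no
  S-RMSD; the value is NaN with a warning, and classification falls back
  to the standard scheme.

## Hydrogen bonds and fnat_hb

Detection is geometric, in the HBplus tradition: donor–acceptor distance
< 3.9 Å; hydrogen–acceptor distance < 2.5 Å and D–H–A angle > 90° when a
hydrogen is available; acceptor-antecedent angle D–A–AA > 90°. All
thresholds are configurable. Donor/acceptor chemistry is a fixed
per-residue table (backbone N donor except Pro; backbone O acceptor;
standard side-chain assignments for Ser/Thr/Tyr/Lys/Arg/Trp/His/Asn/Gln
donors and Asp/Glu/Asn/Gln/Ser/Thr/Tyr/His acceptors).

Hydrogen positions: explicit hydrogens are used when present (identified
as H atoms within 1.25 Å of the donor). Otherwise polar hydrogens are
placed by ideal geometry wherever the heavy atoms fix them — backbone
amide (from the preceding carbonyl and CA, skipped across chain breaks),
Arg, Asn/Gln amides, Trp NE1, His ring nitrogens — using a 1.01 Å N–H
length, the in-plane bisector rule for single hydrogens and ±120°
in-plane placement for planar NH2 groups. Rotatable hydroxyls and amines
(Ser/Thr/Tyr OH, Lys NZ) have no unique H position without a dihedral
search, so they are judged on heavy-atom criteria alone — deterministic,
at the cost of being slightly permissive for those donors.

Charged-donor/carboxylate pairs (Lys NZ, Arg NE/NH*, His ring N+ versus
Asp/Glu carboxylate O) within 4.0 Å are salt bridges: flagged, counted
among the hydrogen bonds (not as a separate metric), and judged on
heavy-atom geometry since the interaction is electrostatic.

fnat_hb mirrors fnat: the fraction of the native bond set recovered,
NaN when the native set is empty. Bond identity is atom-level
(donor atom, acceptor atom) by default; `match="residue"` relaxes to the
donor/acceptor residue pair for threaded models.

## Classification

The standard clauses are evaluated better-class-first; the fnat interval
edges 0.8, 0.5, 0.2 belong to the higher class (consistent with
better-first evaluation) and RMSD thresholds are inclusive. Every
returned class records `rule_fired` for auditability.

The refined scheme has two parameters: a backbone loosening added to all
L-/I-RMSD thresholds, and per-class S-RMSD caps. A class is awarded
under loosened thresholds only if S-RMSD is within that class's cap, and
the result never falls below the standard label. The defaults
(loosening 0.5 Å; caps High 0.5, Medium 1.0, Acceptable 2.0 Å) are this
package's own placeholders, exposed as configuration: fixing them
properly needs a larger benchmark of assessed models than any single
target set provides. With zero loosening and infinite caps the refined
scheme reduces exactly to the standard one (tested on a metric grid).

Metric correlations are Spearman rank correlations (scipy) over
{fnat, fnat_hb, L-, I-, S-RMSD} with pairwise NaN deletion; entries with
fewer than 3 usable pairs or a constant column are NaN.

## Hotspot flagging and hit-rate maps

A residue is a predicted hotspot in a model when its ΔΔG ≥ 0.95
(predictor units, ≈ kcal/mol); the threshold sits just below the round
1.0 to absorb predictor noise around it, and is inclusive. Aggregation
keys are `(chain, resnum, icode)` only — never the residue name — so
models threaded with different sequences pool onto positions. Tables
from different predictors aggregate separately by default (pooling is a
flag), since per-protocol distributions are the meaningful unit.
Hit-rate maps obey two invariants the tests enforce: the per-residue hit
counts sum to the per-model flag counts (conservation), and raising the
cutoff never increases any count (monotonicity). The annotation writer
stores per-residue counts or rates in the B-factor field, which any
structure viewer can colour by.

## Synthetic fixtures

The generator builds an idealised antiparallel β-sheet complex: strand
backbones from ideal internal coordinates (NeRF extension; N–CA 1.458,
CA–C 1.525, C–N 1.329, C=O 1.231 Å; φ = −139°, ψ = 135°), side chains
grafted rigidly from ideal residue templates (chemical component
dictionary geometry via biotite), receptor strands placed beside the
peptide by a deterministic grid search over register, sheet separation
and flip that maximises inter-strand backbone N···O pairing. A
deterministic relief pass removes severe side-chain overlaps (coarse
chi1/chi2 flips, alanine truncation as a last resort). The default spec
(24 receptor residues in two groove-forming strands, 8 peptide residues,
random non-proline sequences from a seeded generator) yields ~40 native
contacts and ~17 native hydrogen bonds, and construction fails loudly if
a spec cannot guarantee at least 5 contacts and 1 hydrogen bond.

Perturbation ensembles are the controlled substrate for every metric:
rigid transforms of the peptide only (closed-form L-RMSD for pure
translations), Gaussian chi-angle noise with the backbone untouched
(I-RMSD exactly 0, S-RMSD > 0), or both. Chi rotations move the atoms
distal to the rotated bond, found by BFS over distance-inferred
intra-residue connectivity. Synthetic ΔΔG ensembles draw
Normal(hot_mean, σ) at planted hotspots and Normal(cold_mean, σ)
elsewhere; defaults hot 2.0, cold 0.0, σ 0.5 — a separation that makes
zero-noise recovery exact and noisy recovery match the Normal tail
probability, both asserted in tests.

What the fixtures deliberately do *not* emulate: real rotamer
distributions, packing energetics, backbone irregularity, waters,
alternate conformations, or the correlated error structure of real
docking ensembles. Green tests on fixtures therefore demonstrate the
*correctness of the measures and aggregation* — boundary semantics,
closed forms, invariances, oracle agreement — not predictive performance
on real submissions.

## Problem sizes and determinism

The default test fixture is ~270 atoms (well under the 500-atom bound
the brute-force oracles are run at); ΔΔG ensembles in tests use up to
200 models × 10 residues. Every stochastic component (sequences,
perturbation directions, ΔΔG noise) flows from an explicit integer seed
through a named NumPy generator; fixture PDBs carry their spec and seed
in REMARK records, and CLI outputs are byte-reproducible given the same
inputs and configuration.

## Known limitations

* Strict key matching means renumbered models pair nothing; the failure
  mode is loud (no paired atoms → error), not silent.
* Agreement with any particular HBplus build is not claimed: versions
  and parameters vary, and the criteria here are the published defaults.
* Hydroxyl/amine donors are assessed without H geometry (see above), so
  a rotated hydroxyl that points away from its acceptor still counts.
* The refined scheme's numeric defaults are placeholders by design.
* Multi-interface assessment (a peptide bound at two sites) is out of
  scope; one receptor/peptide partition per run.
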