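# pepqa

Quality assessment of peptide–protein docking models.

When a docking protocol produces a model of a peptide bound to a receptor,
the community-standard way to judge it is to compare it against the solved
crystal structure using a small set of geometric measures and to bin it into
one of four quality classes. `pepqa` implements that assessment scheme for
peptide complexes as a tested Python library and CLI, together with two
complementary measures that capture how well a model recovers the
*chemistry* of an interface — its side-chain placement and its hydrogen-bond
network — and an ensemble analysis that asks how much even poor models can
reveal about binding hotspots.

Intended users: docking-method developers benchmarking their protocols,
assessors scoring blind-prediction submissions, and structural biologists
deciding whether a model is accurate enough to plan mutagenesis.

## The measures

With receptor chains R and peptide chain p, reference (native) structure N
and model M:

* **Interface residues** — residues whose CB (CA for Gly) lies within
  8.0 Å of a CB/CA across the R/p partition (strict `<`).
* **Native contacts** — residue pairs with any two heavy atoms across the
  interface closer than 4.0 Å; **fnat** is the fraction of the native
  contact set recovered by M.
* **Clashes** — cross-interface heavy-atom pairs closer than 3.0 Å
  (atom-based count, reported but never used to disqualify).
* **L-RMSD** — RMSD over peptide backbone atoms {N, CA, C, O} after
  superposing M on N using the receptor backbone (Kabsch least squares; the
  peptide is never refitted).
* **I-RMSD** — RMSD over backbone atoms of the native-defined interface
  residues, fitted on those same atoms.
* **S-RMSD** — the same construction evaluated over interface *side-chain*
  heavy atoms in the I-RMSD frame, with chemically indistinguishable
  namings (Phe/Tyr ring, Asp/Glu carboxylate, Arg NH, Leu CD, Val CG)
  resolved per residue to the minimal deviation.
* **fnat_hb** — the fraction of native cross-interface hydrogen bonds
  (HBplus-style geometric criteria, short-range salt bridges included)
  recovered by M.

Classes, evaluated better-first (fnat band edges belong to the higher
class, RMSD thresholds inclusive):

| Class      | Condition |
|------------|-----------|
| High       | fnat ≥ 0.8 and (L-RMSD ≤ 1.0 Å or I-RMSD ≤ 0.5 Å) |
| Medium     | 0.5 ≤ fnat < 0.8 and (L ≤ 2.0 or I ≤ 1.0); or fnat ≥ 0.8 and L > 1.0 and I > 0.5 |
| Acceptable | 0.2 ≤ fnat < 0.5 and (L ≤ 4.0 or I ≤ 2.0); or fnat ≥ 0.5 and L > 2.0 and I > 1.0 |
| Incorrect  | the rest |

A parametric *refined* scheme loosens the backbone RMSD thresholds by a
configurable amount but only awards a class when S-RMSD stays under a
per-class cap, so only models with well-modelled side chains benefit; it
never demotes a model below its standard class.

The hotspot module consumes per-model, per-residue ΔΔG tables from any
computational alanine-scanning predictor, flags residues with
ΔΔG ≥ 0.95 (≈ kcal/mol) as predicted hotspots, and aggregates flags across
a model ensemble into per-residue hit-rate maps, recovery histograms
against a curated hotspot list, and B-factor-annotated structures for
visualisation.

## Worked example

No downloads needed — the package generates its own toy complexes
(idealised β-sheet peptide–receptor fixtures):

```
pepqa simulate --geometry groove --seed 1 --n-models 3 --kind rigid \
    --translation 2.0 --out-dir demo/
pepqa assess demo/REF.pdb demo/model_*.pdb \
    --receptor-chains A --peptide-chains B --out demo/metrics.tsv
cat demo/metrics.tsv
```

```
# pepqa 0.1.0 assess
# loosening=0.5 peptide_chains=B receptor_chains=A reference=demo/REF.pdb
model	fnat	fnat_hb	l_rmsd	i_rmsd	s_rmsd	clashes	n_native_contacts	n_native_hbonds	capri_class	refined_class
model_000.pdb	0.643	0.471	2.000	0.893	0.849	71	42	17	Medium	Medium
model_001.pdb	0.643	0.529	2.000	0.893	0.846	69	42	17	Medium	Medium
model_002.pdb	0.643	0.471	2.000	0.893	0.848	98	42	17	Medium	Medium
```

Each row is one model: every rigid 2 Å displacement of the peptide yields
L-RMSD exactly 2.000 (the receptor fit is exact, so the ligand RMSD equals
the displacement), an interface backbone RMSD under 1 Å, and about
two-thirds of the 42 native contacts and half of the 17 native hydrogen
bonds recovered — a Medium model by the first Medium clause.  The clash
counts show the displaced peptide pressing into the receptor groove.

The same works against real structures: pass a crystal reference and
docking submissions renumbered to the target.

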