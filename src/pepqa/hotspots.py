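"""Hotspot flagging from alanine-scanning ΔΔG tables and ensemble hit-rate maps.

The alanine-scanning predictors themselves (Robetta, FoldX, mCSM, ...) are
*not* run here; this module consumes their per-model, per-residue ΔΔG
exports.  A residue is flagged as a predicted binding hotspot in a model
when its ΔΔG meets the cutoff (default +0.95, in the predictor's
kcal/mol-like units — just below 1.0 to absorb minor noise around that
round number).  The flag rule is inclusive: ddg >= cutoff.

Across a model ensemble, per-residue hit counts and hit rates summarise
how consistently each position is called a hotspot; recovery histograms
compare each model's flags against a curated reference hotspot list.
Aggregation is keyed by (chain, resnum, icode) only, so threaded models
with different sequences pool onto the same positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .structure import ComplexStructure, ResidueKey

__all__ = [
    "DDG_COLUMNS",
    "read_ddg_table",
    "read_hotspot_reference",
    "flag_hotspots",
    "hit_rates",
    "recovery_histogram",
    "annotate_structure",
    "HotspotReference",
]

#: Canonical ΔΔG table columns (TSV with header).
DDG_COLUMNS = ["model_id", "chain", "resnum", "icode", "wt", "mut", "ddg"]

#: Reference hotspot list columns.
REFERENCE_COLUMNS = ["chain", "resnum", "icode", "side", "note"]


@dataclass
class HotspotReference:
    """Curated reference hotspots, split by interface side."""

    entries: pd.DataFrame  # columns: chain, resnum, icode, side, note

    def keys(self, side: str | None = None) -> set[ResidueKey]:
        df = self.entries
        if side is not None:
            if side not in ("receptor", "peptide"):
                raise ValueError(f"side must be 'receptor' or 'peptide', got {side!r}")
            df = df[df["side"] == side]
        return {(r.chain, int(r.resnum), r.icode) for r in df.itertuples()}


def _normalise_icode(series: pd.Series) -> pd.Series:
    return series.fillna("").astype(str).str.strip().replace({"nan": "", "-": ""})


def read_ddg_table(path: str | Path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a per-model per-residue ΔΔG TSV.

    ``column_map`` renames predictor-specific headers onto the canonical
    ones (e.g. ``{"pdb": "model_id", "total_energy": "ddg"}``).  Records
    with missing ΔΔG are dropped with a warning; duplicate
    (model, chain, resnum, icode, mut) keys are an error.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chain": str})
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in DDG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    df = df[DDG_COLUMNS].copy()
    df["icode"] = _normalise_icode(df["icode"])
    df["resnum"] = df["resnum"].astype(int)
    df["ddg"] = pd.to_numeric(df["ddg"], errors="coerce")
    n_bad = int(df["ddg"].isna().sum())
    if n_bad:
        import warnings

        warnings.warn(f"{path}: skipped {n_bad} records with missing ddg", stacklevel=2)
        df = df.dropna(subset=["ddg"])
    key_cols = ["model_id", "chain", "resnum", "icode", "mut"]
    if df.duplicated(subset=key_cols).any():
        dupes = df[df.duplicated(subset=key_cols, keep=False)].head()
        raise ValueError(f"{path}: duplicate mutation records, e.g.\n{dupes}")
    return df.reset_index(drop=True)


def read_hotspot_reference(path: str | Path) -> HotspotReference:
    """Read a reference hotspot list TSV: chain, resnum, icode, side, note."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chain": str})
    missing = [c for c in REFERENCE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    df = df[REFERENCE_COLUMNS].copy()
    df["icode"] = _normalise_icode(df["icode"])
    df["resnum"] = df["resnum"].astype(int)
    df["note"] = df["note"].fillna("")
    bad = set(df["side"]) - {"receptor", "peptide"}
    if bad:
        raise ValueError(f"{path}: invalid side values {sorted(bad)}")
    if df.duplicated(subset=["chain", "resnum", "icode"]).any():
        raise ValueError(f"{path}: duplicate hotspot keys")
    return HotspotReference(df.reset_index(drop=True))


def flag_hotspots(table: pd.DataFrame, cutoff: float = 0.95) -> dict[str, set[ResidueKey]]:
    """Per-model sets of residues flagged as hotspots (ddg >= cutoff).

    Every model present in the table gets an entry, possibly empty.
    """
    flags: dict[str, set[ResidueKey]] = {}
    for row in table.itertuples():
        flags.setdefault(row.model_id, set())
        if row.ddg >= cutoff:
            flags[row.model_id].add((row.chain, int(row.resnum), row.icode))
    return flags


def hit_rates(
    flags_by_model: dict[str, set[ResidueKey]],
    universe: set[ResidueKey],
) -> pd.DataFrame:
    """Per-residue hit counts and rates over a model ensemble.

    Residues in ``universe`` never flagged get count 0; flagged residues
    outside the universe are included as well (the universe only pads).
    """
    if not flags_by_model:
        raise ValueError("need at least one model")
    n_models = len(flags_by_model)
    counts: dict[ResidueKey, int] = {key: 0 for key in universe}
    for flagged in flags_by_model.values():
        for key in flagged:
            counts[key] = counts.get(key, 0) + 1
    rows = [
        {
            "chain": k[0],
            "resnum": k[1],
            "icode": k[2],
            "hit_count": c,
            "n_models": n_models,
            "hit_rate": c / n_models,
        }
        for k, c in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["chain", "resnum", "icode", "hit_count", "n_models", "hit_rate"])


def recovery_histogram(
    flags_by_model: dict[str, set[ResidueKey]],
    reference: HotspotReference,
    side: str,
    baseline_flags: set[ResidueKey] | None = None,
) -> tuple[pd.Series, int | None]:
    """Histogram of per-model reference-hotspot recovery counts.

    For each model, the number of reference hotspots (on the chosen side)
    among its flags; returned as a Series indexed 0..n_reference with the
    number of models per recovery count.  ``baseline_flags`` (e.g. the
    flags obtained on the crystal structure) yields the baseline recovery
    count reported alongside — the "stars" of an ensemble histogram.
    """
    ref_keys = reference.keys(side)
    if not ref_keys:
        raise ValueError(f"reference hotspot list has no {side} entries")
    counts = [len(flags & ref_keys) for flags in flags_by_model.values()]
    hist = pd.Series(0, index=range(len(ref_keys) + 1), name="n_models")
    for c in counts:
        hist[c] += 1
    baseline = len(baseline_flags & ref_keys) if baseline_flags is not None else None
    return hist, baseline


def annotate_structure(
    structure: ComplexStructure,
    rates: pd.DataFrame,
    mode: str = "count",
) -> ComplexStructure:
    """Write per-residue hit counts or rates into the B-factor column.

    Returns a copy of the structure whose atoms carry the residue's value
    (``mode='count'`` or ``'rate'``); residues absent from ``rates`` get 0.
    The written structure can be coloured by B-factor in any viewer.
    """
    if mode not in ("count", "rate"):
        raise ValueError(f"mode must be 'count' or 'rate', got {mode!r}")
    column = "hit_count" if mode == "count" else "hit_rate"
    values = {
        (r.chain, int(r.resnum), r.icode): float(getattr(r, column))
        for r in rates.itertuples()
    }
    annotated = structure.copy()
    for res in annotated.residues:
        value = values.get(res.key, 0.0)
        for atom in res.atoms:
            atom.bfactor = value
    return annotated
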