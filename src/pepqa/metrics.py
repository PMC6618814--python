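"""The metric bundle and the one-model assessment pipeline."""

from __future__ import annotations

import math
from dataclasses import dataclass

from .contacts import contacts, count_clashes, fnat
from .hbonds import detect_interface_hbonds, fnat_hb
from .rmsd import interface_rmsd, ligand_rmsd
from .structure import ComplexStructure, build_correspondence

__all__ = ["MetricBundle", "assess_model"]


@dataclass
class MetricBundle:
    """All quality measures for one model against one reference.

    ``fnat_hb`` and ``s_rmsd`` may be NaN when undefined (no native
    hydrogen bonds; no paired interface side-chain atoms).
    """

    fnat: float
    fnat_hb: float
    l_rmsd: float
    i_rmsd: float
    s_rmsd: float
    clashes: int
    n_native_contacts: int
    n_native_hbonds: int
    model_id: str = ""

    def __post_init__(self) -> None:
        for name in ("l_rmsd", "i_rmsd", "s_rmsd"):
            v = getattr(self, name)
            if v is not None and not math.isnan(v) and v < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("fnat", "fnat_hb"):
            v = getattr(self, name)
            if v is not None and not math.isnan(v) and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


def assess_model(
    reference: ComplexStructure,
    model: ComplexStructure,
    chain_map: dict[str, str] | None = None,
    interface_cutoff: float = 8.0,
    contact_cutoff: float = 4.0,
    clash_cutoff: float = 3.0,
    hb_match: str = "atom",
    model_id: str = "",
) -> MetricBundle:
    """Compute the full metric bundle for one model.

    The native contact set, hydrogen-bond set and interface are all
    derived from the reference; the model is measured against them through
    the residue/atom correspondence.
    """
    cmap = build_correspondence(reference, model, chain_map)

    ref_contacts = contacts(reference, cutoff=contact_cutoff)
    mod_contacts = contacts(model, cutoff=contact_cutoff)
    f = fnat(ref_contacts, mod_contacts, cmap)

    ref_hb = detect_interface_hbonds(reference)
    mod_hb = detect_interface_hbonds(model)
    fhb = fnat_hb(ref_hb, mod_hb, cmap, match=hb_match)

    return MetricBundle(
        fnat=f,
        fnat_hb=fhb,
        l_rmsd=ligand_rmsd(reference, model, cmap),
        i_rmsd=interface_rmsd(reference, model, cmap, "backbone", interface_cutoff),
        s_rmsd=interface_rmsd(reference, model, cmap, "sidechain", interface_cutoff),
        clashes=count_clashes(model, cutoff=clash_cutoff),
        n_native_contacts=len(ref_contacts),
        n_native_hbonds=len(ref_hb),
        model_id=model_id,
    )
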