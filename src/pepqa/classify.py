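"""CAPRI quality classification and the side-chain-aware refinement.

The standard peptide-docking classes, evaluated better-class-first:

========== =================================================================
High       fnat >= 0.8  and (L-RMSD <= 1.0 or I-RMSD <= 0.5)
Medium     fnat in [0.5, 0.8) and (L-RMSD <= 2.0 or I-RMSD <= 1.0), or
           fnat >= 0.8  and  L-RMSD > 1.0 and I-RMSD > 0.5
Acceptable fnat in [0.2, 0.5) and (L-RMSD <= 4.0 or I-RMSD <= 2.0), or
           fnat >= 0.5  and  L-RMSD > 2.0 and I-RMSD > 1.0
Incorrect  the rest
========== =================================================================

Boundary fnat values (0.8, 0.5, 0.2) belong to the higher class; RMSD
thresholds are inclusive.

The refined scheme loosens each class's backbone RMSD thresholds by a
fixed amount but awards the class only when the interface side-chain RMSD
(S-RMSD) stays under a per-class cap, so that only models with
well-modelled side chains benefit.  It never demotes a model below its
standard class.  The default loosening and caps are this package's
defaults, exposed as configuration — they are a parametric scheme, not
community-agreed constants.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import MetricBundle

__all__ = [
    "QualityClass",
    "RefinedScheme",
    "classify_capri",
    "classify_refined",
    "metric_correlations",
    "CLASS_ORDER",
]

#: Quality labels from best to worst.
CLASS_ORDER = ("High", "Medium", "Acceptable", "Incorrect")
_RANK = {label: i for i, label in enumerate(CLASS_ORDER)}


@dataclass(frozen=True)
class QualityClass:
    label: str
    rule_fired: str

    def __post_init__(self) -> None:
        if self.label not in CLASS_ORDER:
            raise ValueError(f"unknown quality label {self.label!r}")

    def better_than(self, other: "QualityClass") -> bool:
        return _RANK[self.label] < _RANK[other.label]


@dataclass
class RefinedScheme:
    """Parameters of the S-RMSD-augmented classification."""

    backbone_loosening: float = 0.5
    s_rmsd_caps: dict[str, float] = field(
        default_factory=lambda: {"High": 0.5, "Medium": 1.0, "Acceptable": 2.0}
    )

    def __post_init__(self) -> None:
        if self.backbone_loosening < 0:
            raise ValueError("backbone_loosening must be >= 0")
        if any(v <= 0 for v in self.s_rmsd_caps.values()):
            raise ValueError("s_rmsd_caps must be positive")


def _clauses(loosen: float) -> list[tuple[str, str, callable]]:
    """Ordered classification clauses with L/I thresholds loosened by ``loosen``."""
    return [
        ("High", "high", lambda f, l, i: f >= 0.8 and (l <= 1.0 + loosen or i <= 0.5 + loosen)),
        (
            "Medium",
            "medium_fnat_band",
            lambda f, l, i: 0.5 <= f < 0.8 and (l <= 2.0 + loosen or i <= 1.0 + loosen),
        ),
        (
            "Medium",
            "medium_high_fnat",
            lambda f, l, i: f >= 0.8 and l > 1.0 + loosen and i > 0.5 + loosen,
        ),
        (
            "Acceptable",
            "acceptable_fnat_band",
            lambda f, l, i: 0.2 <= f < 0.5 and (l <= 4.0 + loosen or i <= 2.0 + loosen),
        ),
        (
            "Acceptable",
            "acceptable_high_fnat",
            lambda f, l, i: f >= 0.5 and l > 2.0 + loosen and i > 1.0 + loosen,
        ),
    ]


def _classify(fnat: float, l_rmsd: float, i_rmsd: float, loosen: float) -> QualityClass:
    for label, rule, predicate in _clauses(loosen):
        if predicate(fnat, l_rmsd, i_rmsd):
            return QualityClass(label, rule)
    return QualityClass("Incorrect", "rest")


def classify_capri(m: MetricBundle) -> QualityClass:
    """Assign the standard quality class to one model's metrics."""
    for value, name in ((m.fnat, "fnat"), (m.l_rmsd, "l_rmsd"), (m.i_rmsd, "i_rmsd")):
        if value is None or (isinstance(value, float) and math.isnan(value)):
            raise ValueError(f"classification requires {name}; it is undefined for this model")
    return _classify(m.fnat, m.l_rmsd, m.i_rmsd, loosen=0.0)


def classify_refined(m: MetricBundle, scheme: RefinedScheme | None = None) -> QualityClass:
    """Classify with loosened backbone thresholds gated by S-RMSD caps.

    Falls back to :func:`classify_capri` when S-RMSD is undefined, and
    never returns a class worse than the standard one.
    """
    scheme = scheme or RefinedScheme()
    base = classify_capri(m)
    if m.s_rmsd is None or (isinstance(m.s_rmsd, float) and math.isnan(m.s_rmsd)):
        return base
    refined = QualityClass("Incorrect", "rest")
    for label, rule, predicate in _clauses(scheme.backbone_loosening):
        cap = scheme.s_rmsd_caps.get(label, float("inf"))
        if m.s_rmsd > cap:
            continue
        if predicate(m.fnat, m.l_rmsd, m.i_rmsd):
            refined = QualityClass(label, f"refined_{rule}")
            break
    return refined if refined.better_than(base) or refined.label == base.label else base


_CORRELATION_METRICS = ("fnat", "fnat_hb", "l_rmsd", "i_rmsd", "s_rmsd")


def metric_correlations(bundles: list[MetricBundle]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman rank correlations between quality metrics.

    Undefined metric values (NaN) are dropped pairwise.  Entries with
    fewer than 3 usable observations are NaN.  Returns ``(rho, pvalues)``
    DataFrames indexed by metric name.
    """
    if len(bundles) < 3:
        raise ValueError("need at least 3 models for correlation analysis")
    data = pd.DataFrame(
        {name: [getattr(b, name) for b in bundles] for name in _CORRELATION_METRICS},
        dtype=float,
    )
    n = len(_CORRELATION_METRICS)
    rho = pd.DataFrame(np.eye(n), index=_CORRELATION_METRICS, columns=_CORRELATION_METRICS)
    pval = pd.DataFrame(np.zeros((n, n)), index=_CORRELATION_METRICS, columns=_CORRELATION_METRICS)
    for a, b in itertools.combinations(_CORRELATION_METRICS, 2):
        sub = data[[a, b]].dropna()
        if len(sub) < 3 or sub[a].nunique() < 2 or sub[b].nunique() < 2:
            r, p = float("nan"), float("nan")
        else:
            r, p = stats.spearmanr(sub[a], sub[b])
        rho.loc[a, b] = rho.loc[b, a] = r
        pval.loc[a, b] = pval.loc[b, a] = p
    return rho, pval
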