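"""Homoeolog expression-triad classification.

Each gene of the amphitriploid has three homoeologous alleles: one from
the distant parent and two from the close-parent pair.  With expression
``E_far`` for the distant-parent allele and ``E_other`` for the pooled
close-parent alleles, the dosage-balanced expectation is a 1:2 ratio.
Triads are classified by the ratio ``r = E_far / E_other``:

* ``FAR_DOMINANT``   — r >= 1 (the single allele matches the pooled pair);
* ``OTHER_DOMINANT`` — r <= 1/4 (the pooled pair over-contributes);
* ``BALANCED``       — everything between the two thresholds, which
  contains the 1:2 dose point;
* ``NOT_EXPRESSED``  — total expression below the floor (1 FPKM by
  default), applied to the triad total so monoallelic genes are kept.

Both dominance thresholds are inclusive; ``E_other = 0`` with an
expressed total gives r = +inf, hence FAR_DOMINANT.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BALANCED",
    "FAR_DOMINANT",
    "OTHER_DOMINANT",
    "NOT_EXPRESSED",
    "classify_triad",
    "classify_table",
    "triad_proportions",
    "pathway_panel_matrix",
]

BALANCED = "BALANCED"
FAR_DOMINANT = "FAR_DOMINANT"
OTHER_DOMINANT = "OTHER_DOMINANT"
NOT_EXPRESSED = "NOT_EXPRESSED"

EXPRESSED_CATEGORIES = (BALANCED, FAR_DOMINANT, OTHER_DOMINANT)


def classify_triad(e_far: float, e_other: float, floor: float = 1.0) -> str:
    """Classify one triad by its far/other expression ratio."""
    if not np.isfinite(e_far) or not np.isfinite(e_other):
        raise ValueError("expression values must be finite")
    if e_far < 0 or e_other < 0:
        raise ValueError(f"negative expression: ({e_far}, {e_other})")
    if e_far + e_other < floor:
        return NOT_EXPRESSED
    r = np.inf if e_other == 0 else e_far / e_other
    if r >= 1.0:
        return FAR_DOMINANT
    if r <= 0.25:
        return OTHER_DOMINANT
    return BALANCED


def classify_table(expr: pd.DataFrame, floor: float = 1.0) -> pd.DataFrame:
    """Vectorized classification of an expression table.

    ``expr`` needs columns ``e_far`` and ``e_other``; a ``category``
    column is added (other columns pass through).
    """
    e_far = expr["e_far"].to_numpy(dtype=float)
    e_other = expr["e_other"].to_numpy(dtype=float)
    if np.any(e_far < 0) or np.any(e_other < 0):
        raise ValueError("negative expression values")
    total = e_far + e_other
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(e_other > 0, e_far / np.where(e_other > 0, e_other, 1.0), np.inf)
    cat = np.where(
        total < floor,
        NOT_EXPRESSED,
        np.where(r >= 1.0, FAR_DOMINANT, np.where(r <= 0.25, OTHER_DOMINANT, BALANCED)),
    )
    out = expr.copy()
    out["category"] = cat
    return out


def triad_proportions(classified: pd.DataFrame) -> pd.DataFrame:
    """Per-tissue fractions of the three expressed categories.

    NOT_EXPRESSED records are excluded from the denominator; tissues with
    no expressed record are omitted with a warning.  Fractions per tissue
    sum to 1; counts are reported alongside.
    """
    rows = []
    for tissue, sub in classified.groupby("tissue"):
        expressed = sub[sub["category"] != NOT_EXPRESSED]
        if expressed.empty:
            warnings.warn(f"tissue {tissue!r} has no expressed triads; omitted")
            continue
        counts = expressed["category"].value_counts()
        n = len(expressed)
        row = {"tissue": tissue, "n_expressed": n}
        for cat in EXPRESSED_CATEGORIES:
            row[f"n_{cat.lower()}"] = int(counts.get(cat, 0))
            row[f"frac_{cat.lower()}"] = counts.get(cat, 0) / n
        rows.append(row)
    return pd.DataFrame(rows)


def pathway_panel_matrix(
    classified: pd.DataFrame, panel: Sequence[str]
) -> pd.DataFrame:
    """Extract a gene-panel expression matrix for heatmap export.

    Rows are panel genes present in the table (panel order preserved);
    columns are (tissue, allele-class) expression values.  Unknown panel
    ids are reported in a warning, not an error.
    """
    panel = list(panel)
    known = set(classified["gene_id"])
    unknown = [g for g in panel if g not in known]
    if unknown:
        warnings.warn(f"panel ids not in table: {', '.join(unknown)}")
    keep = [g for g in panel if g in known]
    if not keep:
        return pd.DataFrame()
    sub = classified[classified["gene_id"].isin(keep)]
    mat = sub.pivot_table(
        index="gene_id", columns="tissue", values=["e_far", "e_other"], sort=False
    )
    mat.columns = [f"{t}_{v}" for v, t in mat.columns]
    return mat.reindex(keep)
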