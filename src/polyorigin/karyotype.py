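"""Per-group karyotype assembly from haplotype origin calls.

A homologous group of the amphitriploid normally carries three
haplotypes: one from the distant maternal parent and two from the
close paternal-side pair.  The four karyotype categories are:

1. ``{FAR, NEAR1, NEAR2}`` — one haplotype from each parent;
2. ``{FAR, NEARx, NEARx}`` — two copies from the same close parent;
3. ``{FAR, NEARx, RECOMBINANT}`` — one recombinant haplotype switching
   between the close parents;
4. aneuploid — copy number other than three.

Groups containing an unresolved haplotype, or any other origin multiset,
are never force-classified.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .origin import NEAR1, NEAR2, OriginCall, RECOMBINANT, UNRESOLVED
from .simulate import FAR

__all__ = ["GroupKaryotype", "assemble_karyogram", "karyogram_report"]

CATEGORY_UNRESOLVED = "UNRESOLVED"


@dataclass
class GroupKaryotype:
    group_id: str
    origins: tuple[str, ...]  # sorted origin multiset
    category: int | str  # 1..4 or "UNRESOLVED"
    breakpoints: dict[str, tuple[int, ...]] = field(default_factory=dict)
    hap_ids: tuple[str, ...] = ()


def _classify(origins: Sequence[str]) -> int | str:
    counts = Counter(origins)
    if len(origins) != 3:
        return 4
    if counts[UNRESOLVED]:
        return CATEGORY_UNRESOLVED
    if counts[FAR] != 1:
        return CATEGORY_UNRESOLVED
    rest = sorted(o for o in origins if o != FAR)
    if rest == [NEAR1, NEAR2]:
        return 1
    if rest in ([NEAR1, NEAR1], [NEAR2, NEAR2]):
        return 2
    if RECOMBINANT in rest and rest.count(RECOMBINANT) == 1:
        return 3
    return CATEGORY_UNRESOLVED


def assemble_karyogram(
    calls: Iterable[OriginCall], hap_groups: Mapping[str, str]
) -> list[GroupKaryotype]:
    """Group origin calls by homologous group and classify each group."""
    by_group: dict[str, list[OriginCall]] = {}
    for call in calls:
        if call.hap_id not in hap_groups:
            raise ValueError(f"haplotype {call.hap_id} has no homologous group")
        by_group.setdefault(hap_groups[call.hap_id], []).append(call)
    out = []
    for gid in sorted(by_group):
        members = sorted(by_group[gid], key=lambda c: c.hap_id)
        origins = tuple(sorted(c.origin for c in members))
        out.append(
            GroupKaryotype(
                group_id=gid,
                origins=origins,
                category=_classify(origins),
                breakpoints={
                    c.hap_id: c.breakpoints for c in members if c.breakpoints
                },
                hap_ids=tuple(c.hap_id for c in members),
            )
        )
    return out


def karyogram_report(karyotypes: Sequence[GroupKaryotype]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tabulate karyotypes and summarize category counts.

    Returns ``(table, summary)``: one row per group, and category counts
    that reconcile with the number of input groups.
    """
    table = pd.DataFrame(
        {
            "group_id": [k.group_id for k in karyotypes],
            "n_haplotypes": [len(k.hap_ids) for k in karyotypes],
            "origins": ["+".join(k.origins) for k in karyotypes],
            "category": [k.category for k in karyotypes],
            "breakpoints": [
                ";".join(
                    f"{h}:{','.join(map(str, bps))}"
                    for h, bps in sorted(k.breakpoints.items())
                )
                for k in karyotypes
            ],
        }
    )
    summary = (
        table.groupby("category", sort=False)
        .size()
        .rename("n_groups")
        .reset_index()
        .sort_values("category", key=lambda s: s.astype(str))
        .reset_index(drop=True)
    )
    assert summary["n_groups"].sum() == len(table)
    return table, summary
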