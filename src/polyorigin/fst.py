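"""Fst scans, hotspot extraction, haplogroup concordance and IBS.

The fixation index between the two phenotype groups is computed with the
Weir & Cockerham (1984) estimator, the two-level (population /
individual / within-individual) variance-component form for diploid
genotypes that VCFtools implements.  Per site the components are

    a  — among-population variance,
    b  — among-individual-within-population variance,
    c  — within-individual variance,

and the estimate is ``a / (a + b + c)``.  Windowed values combine sites
by ratio of sums ``sum(a) / sum(a+b+c)`` (again the cited tool's
convention), and negative per-site estimates are retained in the sums.

Hotspots are maximal runs of windows with Fst at or above a threshold
(0.3 in the study), allowing a configurable number of sub-threshold
windows inside a run.  Within a hotspot, individuals are split into two
haplogroups by 2-medoids clustering on identity-by-state distance, and
concordance with the phenotype partition is scored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .windows import assign_windows, make_windows

__all__ = [
    "SiteComponents",
    "HotspotRegion",
    "site_fst",
    "site_fst_scan",
    "windowed_fst",
    "find_hotspots",
    "hotspot_haplogroups",
    "ibs_matrix",
]


@dataclass
class SiteComponents:
    a: float
    b: float
    c: float

    @property
    def estimate(self) -> float:
        denom = self.a + self.b + self.c
        return np.nan if denom == 0 else self.a / denom


@dataclass
class HotspotRegion:
    start: int
    end: int
    mean_fst: float
    window_indices: tuple[int, ...]
    genes: tuple[str, ...] = ()
    haplogroups: dict[str, int] = field(default_factory=dict)


def _pop_stats(genotypes: np.ndarray) -> tuple[int, float, float]:
    """(n individuals, alt-allele frequency, observed het frequency)."""
    g = genotypes[genotypes >= 0]
    n = len(g)
    if n == 0:
        return 0, np.nan, np.nan
    p = g.sum() / (2 * n)
    h = np.mean(g == 1)
    return n, p, h


def site_fst(g1: np.ndarray, g2: np.ndarray) -> SiteComponents:
    """Weir–Cockerham components at one biallelic site, two populations.

    ``g1``/``g2`` are diploid genotypes coded 0/1/2 (alt-allele dosage),
    -1 for missing.  Monomorphic sites (after removing missing calls)
    and sites with fewer than two individuals in either group raise;
    callers scanning many sites should pre-filter (see
    :func:`site_fst_scan`).
    """
    n1, p1, h1 = _pop_stats(np.asarray(g1))
    n2, p2, h2 = _pop_stats(np.asarray(g2))
    if n1 < 2 or n2 < 2:
        raise ValueError("need >=2 non-missing diploid individuals per group")
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    if pbar in (0.0, 1.0):
        raise ValueError("monomorphic site: Fst undefined")
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2
        - (1.0 / (nbar - 1))
        * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar)
        - ((r - 1) / r) * s2
        - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2.0
    return SiteComponents(a=float(a), b=float(b), c=float(c))


def site_fst_scan(
    genotypes: np.ndarray,
    phenotypes: Sequence[str],
    positions: np.ndarray,
    case_label: str = "case",
) -> pd.DataFrame:
    """Per-site components over a genotype matrix (individuals x sites).

    Monomorphic and under-sampled sites are excluded; the returned frame
    has columns pos, a, b, c, fst plus the count of excluded sites in
    ``attrs["n_excluded"]``.
    """
    phenotypes = np.asarray(phenotypes)
    is_case = phenotypes == case_label
    rows = []
    n_excluded = 0
    for j in range(genotypes.shape[1]):
        col = genotypes[:, j]
        try:
            comp = site_fst(col[is_case], col[~is_case])
        except ValueError:
            n_excluded += 1
            continue
        rows.append((int(positions[j]), comp.a, comp.b, comp.c, comp.estimate))
    out = pd.DataFrame(rows, columns=["pos", "a", "b", "c", "fst"])
    out.attrs["n_excluded"] = n_excluded
    return out


def windowed_fst(
    sites: pd.DataFrame,
    span: int,
    window_size: int,
    min_sites: int = 5,
) -> pd.DataFrame:
    """Ratio-of-sums windowed Fst: sum(a) / sum(a+b+c) per window.

    Windows with fewer than ``min_sites`` analyzable sites are flagged
    ``low_confidence`` and get NaN when empty.  The estimate is invariant
    to the order of sites within a window.
    """
    wins = make_windows(span, window_size)
    idx = assign_windows(sites["pos"].to_numpy(), wins)
    ok = idx >= 0
    a = np.bincount(idx[ok], weights=sites["a"].to_numpy()[ok], minlength=len(wins))
    denom = np.bincount(
        idx[ok],
        weights=(sites["a"] + sites["b"] + sites["c"]).to_numpy()[ok],
        minlength=len(wins),
    )
    counts = np.bincount(idx[ok], minlength=len(wins))
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(denom != 0, a / np.where(denom != 0, denom, 1.0), np.nan)
    return pd.DataFrame(
        {
            "start": wins[:, 0],
            "end": wins[:, 1],
            "fst": fst,
            "n_sites": counts,
            "low_confidence": counts < min_sites,
        }
    )


def find_hotspots(
    windows: pd.DataFrame,
    threshold: float = 0.3,
    merge_gap: int = 1,
) -> list[HotspotRegion]:
    """Maximal runs of windows with Fst >= threshold.

    Up to ``merge_gap`` consecutive sub-threshold windows inside a run
    are tolerated (they join the region but do not count toward its mean
    Fst).  Extraction is idempotent and monotone in the threshold.
    """
    fst = windows["fst"].to_numpy()
    hot = np.flatnonzero(np.nan_to_num(fst, nan=-np.inf) >= threshold)
    if len(hot) == 0:
        return []
    regions = []
    run = [hot[0]]
    for i in hot[1:]:
        if i - run[-1] - 1 <= merge_gap:
            run.append(i)
        else:
            regions.append(run)
            run = [i]
    regions.append(run)
    out = []
    for run in regions:
        members = tuple(range(run[0], run[-1] + 1))
        qual = [i for i in members if np.nan_to_num(fst[i], nan=-np.inf) >= threshold]
        out.append(
            HotspotRegion(
                start=int(windows["start"].iloc[run[0]]),
                end=int(windows["end"].iloc[run[-1]]),
                mean_fst=float(np.mean(fst[qual])),
                window_indices=members,
            )
        )
    return out


# ---------------------------------------------------------------------------
# identity by state and haplogroups


def ibs_matrix(genotypes: np.ndarray) -> np.ndarray:
    """Pairwise proportion of identical unphased genotypes.

    ``genotypes``: (individuals x sites), -1 for missing.  Entry (i, j)
    is computed over sites non-missing in both; a pair sharing no such
    site gets NaN with a warning.  The matrix is symmetric with unit
    diagonal.
    """
    g = np.asarray(genotypes)
    n = g.shape[0]
    if n < 2:
        raise ValueError("need at least two individuals")
    valid = g >= 0
    out = np.ones((n, n))
    warned = False
    for i in range(n):
        both = valid[i] & valid[i + 1:]
        same = (g[i] == g[i + 1:]) & both
        shared = both.sum(axis=1)
        with np.errstate(invalid="ignore"):
            vals = np.where(shared > 0, same.sum(axis=1) / np.maximum(shared, 1), np.nan)
        if np.any(shared == 0) and not warned:
            warnings.warn("individual pair(s) with zero shared sites: NaN entries")
            warned = True
        out[i, i + 1:] = vals
        out[i + 1:, i] = vals
    return out


def _two_medoids(dist: np.ndarray, max_iter: int = 100) -> np.ndarray:
    """Deterministic 2-medoids on a distance matrix; ties to lowest index."""
    n = dist.shape[0]
    # start from the most distant pair (lexicographically first on ties)
    flat = np.round(dist, 12)
    best = np.unravel_index(np.argmax(flat), flat.shape)
    medoids = sorted(best)
    if medoids[0] == medoids[1]:  # all-zero distances
        medoids = [0, 1]
    for _ in range(max_iter):
        d = dist[:, medoids]
        labels = np.where(d[:, 0] <= d[:, 1], 0, 1)
        new = []
        for k in (0, 1):
            members = np.flatnonzero(labels == k)
            if len(members) == 0:
                new.append(medoids[k])
                continue
            cost = dist[np.ix_(members, members)].sum(axis=1)
            new.append(int(members[np.argmin(np.round(cost, 12))]))
        if new == medoids:
            break
        medoids = new
    d = dist[:, medoids]
    return np.where(d[:, 0] <= d[:, 1], 0, 1)


def hotspot_haplogroups(
    genotypes: np.ndarray,
    phenotypes: Sequence[str],
) -> tuple[np.ndarray, float]:
    """Split individuals into two haplogroups within a region and score
    concordance with phenotype.

    ``genotypes``: (individuals x sites) restricted to the region.
    Individuals are clustered by 2-medoids on IBS distance (1 - IBS);
    concordance is the fraction of individuals whose phenotype equals the
    majority phenotype of their haplogroup.  In a trait-linked hotspot
    the two haplogroups track the two phenotypes (concordance 1 in the
    noiseless case); in a control region concordance stays near the
    majority-class baseline.
    """
    g = np.asarray(genotypes)
    phenotypes = np.asarray(phenotypes)
    if g.shape[0] != len(phenotypes):
        raise ValueError("genotype rows and phenotype labels differ in length")
    poly = np.array([len(np.unique(col[col >= 0])) > 1 for col in g.T])
    if poly.sum() < 2:
        raise ValueError("region has fewer than 2 polymorphic sites")
    dist = 1.0 - ibs_matrix(g[:, poly])
    labels = _two_medoids(dist)
    conc = 0
    for k in (0, 1):
        members = phenotypes[labels == k]
        if len(members) == 0:
            continue
        _, counts = np.unique(members, return_counts=True)
        conc += counts.max()
    return labels, conc / len(phenotypes)
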