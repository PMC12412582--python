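"""Parental-origin assignment of offspring haplotypes.

Two evidence layers, mirroring how origin is read off in allopolyploid
assemblies:

* **Read depth.**  Short reads from each parent are mapped to the
  haplotype-resolved assembly; the distant parent's reads pile up only on
  the haplotypes it contributed, so the far-parent share of normalized
  window depth separates FAR from non-FAR haplotypes.
* **Diagnostic SNPs.**  Sites where the two close parents are homozygous
  for different alleles score a haplotype +1 when it carries the NEAR2
  allele and -1 for the NEAR1 allele.  Window means near +1 or -1 assign
  the haplotype to one close parent; a switch of sign along the haplotype
  marks an inter-parental recombination breakpoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .simulate import FAR, NEAR1, NEAR2, RECOMBINANT, PARENT_SAMPLES
from .windows import assign_windows, make_windows

__all__ = [
    "UNRESOLVED",
    "NOT_FAR",
    "WindowTrack",
    "DiagnosticSNPSet",
    "OriginCall",
    "normalize_depth",
    "classify_far_haplotype",
    "extract_diagnostic_snps",
    "diagnostic_snps_from_variants",
    "far_depth_fractions",
    "score_sites",
    "window_scores",
    "call_origin",
    "type_origins",
    "calls_to_frame",
]

UNRESOLVED = "UNRESOLVED"
NOT_FAR = "NOT_FAR"
AMBIG = 0  # internal window label; NEAR1 = -1, NEAR2 = +1


@dataclass
class WindowTrack:
    """Per-window numeric track on one haplotype.

    ``values`` hold normalized depth (>= 0) or mean SNP score (in
    [-1, 1], NaN where a window has no informative site); ``n_sites``
    and ``low_confidence`` are populated for score tracks.
    """

    hap_id: str
    windows: np.ndarray  # (n, 2) start/end
    values: np.ndarray
    n_sites: np.ndarray | None = None
    low_confidence: np.ndarray | None = None

    def __post_init__(self):
        if len(self.windows) != len(self.values):
            raise ValueError("windows and values length mismatch")
        if len(self.windows) == 0:
            raise ValueError(f"empty track for {self.hap_id}")


@dataclass
class DiagnosticSNPSet:
    """Differential homozygous sites between the two close parents.

    ``sites`` maps group id -> DataFrame(pos, allele_near1, allele_near2);
    ``dropped`` counts excluded input records by reason.
    """

    sites: dict[str, pd.DataFrame]
    dropped: dict[str, int] = field(default_factory=dict)

    def n_sites(self) -> int:
        return sum(len(v) for v in self.sites.values())


@dataclass
class OriginCall:
    hap_id: str
    origin: str  # FAR / NEAR1 / NEAR2 / RECOMBINANT / UNRESOLVED
    segments: list[tuple[int, int, str]] = field(default_factory=list)
    breakpoints: tuple[int, ...] = ()
    evidence: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# depth layer


def normalize_depth(
    raw: pd.DataFrame, reference_coverage: float = 1.0
) -> pd.DataFrame:
    """Scale each parental sample's window depths to a common coverage.

    ``raw`` is a long table (hap_id, sample, start, end, depth).  Each
    sample's depths are divided by that sample's genome-wide mean and
    multiplied by ``reference_coverage``, which makes samples of
    different sequencing yield comparable.
    """
    out = raw.copy()
    means = out.groupby("sample")["depth"].mean()
    zero = means[means <= 0]
    if len(zero):
        raise ValueError(
            f"sample(s) with zero total depth: {', '.join(zero.index)}"
        )
    out["depth"] = (
        out["depth"] / out["sample"].map(means) * reference_coverage
    )
    return out


def classify_far_haplotype(
    depth: pd.DataFrame,
    hap_id: str,
    depth_fraction_threshold: float = 0.8,
    far_sample: str = FAR,
) -> str:
    """FAR / NOT_FAR / UNRESOLVED from the far-parent depth share.

    The far sample's share of total normalized depth, averaged over
    windows, decides the call: >= threshold -> FAR, <= 1 - threshold ->
    NOT_FAR, anything else UNRESOLVED.  The share is invariant to a
    uniform rescaling of all tracks.
    """
    sub = depth[depth["hap_id"] == hap_id]
    if sub.empty:
        raise ValueError(f"no depth windows for haplotype {hap_id}")
    wide = sub.pivot_table(
        index=["start", "end"], columns="sample", values="depth"
    )
    total = wide.sum(axis=1)
    nonzero = total > 0
    if not nonzero.any():
        warnings.warn(f"all-sample zero depth on {hap_id}; unresolved")
        return UNRESOLVED
    frac = (wide.loc[nonzero, far_sample] / total[nonzero]).mean()
    if frac >= depth_fraction_threshold:
        return FAR
    if frac <= 1.0 - depth_fraction_threshold:
        return NOT_FAR
    return UNRESOLVED


def far_depth_fractions(depth: pd.DataFrame, far_sample: str = FAR) -> pd.Series:
    """Per-haplotype mean far-sample depth share (one pass, all haplotypes)."""
    wide = depth.pivot_table(
        index=["hap_id", "start"], columns="sample", values="depth"
    )
    total = wide.sum(axis=1)
    frac = (wide[far_sample] / total)[total > 0]
    return frac.groupby(level="hap_id").mean()


# ---------------------------------------------------------------------------
# diagnostic-SNP layer


def extract_diagnostic_snps(
    records: Iterable[tuple],
) -> DiagnosticSNPSet:
    """Filter parental genotype records down to diagnostic sites.

    ``records`` yields ``(chrom, pos, alleles, gt_near1, gt_near2)``:
    ``alleles`` is the record's full allele tuple (REF first) and each
    ``gt_*`` is that parent's genotype as a tuple of allele strings
    (e.g. ``("A", "A")``), with ``None`` for missing calls.  A site is
    retained exactly when the record is a biallelic SNP and both close
    parents are homozygous for different alleles; everything else is
    dropped with a per-reason count.

    Use :func:`polyorigin.io.iter_vcf_parent_genotypes` to adapt a VCF.
    """
    dropped = {
        "multiallelic": 0,
        "not_snp": 0,
        "missing": 0,
        "heterozygous": 0,
        "identical": 0,
    }
    rows: dict[str, list[tuple[int, str, str]]] = {}
    for chrom, pos, alleles, gt1, gt2 in records:
        if len(alleles) > 2:
            dropped["multiallelic"] += 1
            continue
        if any(len(a) != 1 for a in alleles):
            dropped["not_snp"] += 1
            continue
        if any(a is None for a in gt1) or any(a is None for a in gt2):
            dropped["missing"] += 1
            continue
        if len(set(gt1)) != 1 or len(set(gt2)) != 1:
            dropped["heterozygous"] += 1
            continue
        a1, a2 = gt1[0], gt2[0]
        if a1 == a2:
            dropped["identical"] += 1
            continue
        rows.setdefault(chrom, []).append((pos, a1, a2))
    sites = {
        chrom: pd.DataFrame(v, columns=["pos", "allele_near1", "allele_near2"])
        .sort_values("pos")
        .reset_index(drop=True)
        for chrom, v in rows.items()
    }
    return DiagnosticSNPSet(sites=sites, dropped=dropped)


def diagnostic_snps_from_variants(variants: pd.DataFrame) -> DiagnosticSNPSet:
    """Vectorized diagnostic-site filter over a parental variant table.

    ``variants`` has columns chrom, pos, ref, far, near1, near2 holding
    single-letter homozygous alleles (NaN for missing).  Applies the same
    retention rule as :func:`extract_diagnostic_snps` — biallelic SNP,
    close parents homozygous for different alleles — in one pass; the
    tests assert the two routes agree.
    """
    v = variants
    ref, far = v["ref"], v["far"]
    n1, n2 = v["near1"], v["near2"]
    missing = ref.isna() | far.isna() | n1.isna() | n2.isna()
    n_alleles = (
        1
        + (far != ref).astype(int)
        + ((n1 != ref) & (n1 != far)).astype(int)
        + ((n2 != ref) & (n2 != far) & (n2 != n1)).astype(int)
    )
    multi = ~missing & (n_alleles > 2)
    not_snp = ~missing & ~multi & (
        (ref.str.len() != 1) | (far.str.len() != 1)
        | (n1.str.len() != 1) | (n2.str.len() != 1)
    )
    identical = ~missing & ~multi & ~not_snp & (n1 == n2)
    keep = ~missing & ~multi & ~not_snp & ~identical
    dropped = {
        "multiallelic": int(multi.sum()),
        "not_snp": int(not_snp.sum()),
        "missing": int(missing.sum()),
        "heterozygous": 0,
        "identical": int(identical.sum()),
    }
    kept = v[keep]
    sites = {
        chrom: sub[["pos", "near1", "near2"]]
        .rename(columns={"near1": "allele_near1", "near2": "allele_near2"})
        .sort_values("pos")
        .reset_index(drop=True)
        for chrom, sub in kept.groupby("chrom")
    }
    return DiagnosticSNPSet(sites=sites, dropped=dropped)


def score_sites(
    alleles: pd.DataFrame, snps: pd.DataFrame
) -> pd.DataFrame:
    """Score a haplotype's alleles at diagnostic sites as +/-1.

    +1 when the allele matches the NEAR2 parent, -1 for NEAR1; sites with
    a missing or third allele get NaN and are excluded from window means
    (rather than scored 0, which would dilute |mean| toward the ambiguous
    zone).  ``alleles`` is DataFrame(pos, allele); ``snps`` one group's
    table from :class:`DiagnosticSNPSet`.
    """
    merged = snps.merge(alleles, on="pos", how="left")
    score = np.full(len(merged), np.nan)
    score[merged["allele"] == merged["allele_near2"]] = 1.0
    score[merged["allele"] == merged["allele_near1"]] = -1.0
    return pd.DataFrame({"pos": merged["pos"], "score": score})


def window_scores(
    scores: pd.DataFrame,
    span: int,
    window_size: int,
    hap_id: str = "",
    min_sites: int = 10,
) -> WindowTrack:
    """Mean +/-1 score per window; sparse windows are flagged.

    The site-weighted mean of window means equals the global mean of the
    non-excluded site scores, an identity the tests hold to 1e-12.
    """
    wins = make_windows(span, window_size)
    pos = scores["pos"].to_numpy()
    val = scores["score"].to_numpy(dtype=float)
    ok = ~np.isnan(val)
    idx = assign_windows(pos[ok], wins)
    val = val[ok][idx >= 0]
    idx = idx[idx >= 0]
    sums = np.bincount(idx, weights=val, minlength=len(wins))
    counts = np.bincount(idx, minlength=len(wins))
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return WindowTrack(
        hap_id=hap_id,
        windows=wins,
        values=means,
        n_sites=counts,
        low_confidence=counts < min_sites,
    )


# ---------------------------------------------------------------------------
# segmentation


def _label_windows(track: WindowTrack, score_threshold: float) -> np.ndarray:
    v = track.values
    lab = np.zeros(len(v), dtype=np.int8)
    with np.errstate(invalid="ignore"):
        lab[v >= score_threshold] = 1
        lab[v <= -score_threshold] = -1
    return lab


def _runs(labels: np.ndarray) -> list[list]:
    """Maximal runs of labeled windows, ambiguous ones attached greedily.

    Returns mutable [label, n_labeled, first_idx, last_idx] runs over the
    full window index range: same-label runs separated only by ambiguous
    windows are merged; ambiguous windows between two different-label runs
    go to the longer flanking run (left on ties); leading/trailing
    ambiguous windows join the nearest run.
    """
    labeled = np.flatnonzero(labels != 0)
    if len(labeled) == 0:
        return []
    runs: list[list] = []
    for i in labeled:
        if runs and runs[-1][0] == labels[i]:
            runs[-1][1] += 1
            runs[-1][3] = i
        else:
            runs.append([int(labels[i]), 1, int(i), int(i)])
    # attach ambiguous windows
    runs[0][2] = 0
    runs[-1][3] = len(labels) - 1
    for left, right in zip(runs, runs[1:]):
        gap_lo, gap_hi = left[3] + 1, right[2] - 1
        if gap_lo > gap_hi:
            continue
        # the whole gap goes to one side so segments stay contiguous
        if left[1] >= right[1]:  # longer flank wins; tie -> left
            left[3] = gap_hi
        else:
            right[2] = gap_lo
    return runs


def call_origin(
    track: WindowTrack,
    score_threshold: float = 0.8,
    min_segment_windows: int = 2,
) -> OriginCall:
    """Segment a score track into close-parent origins.

    Windows are labeled NEAR2 (mean >= +threshold), NEAR1 (<= -threshold)
    or ambiguous; ambiguous windows are absorbed into flanking runs.
    Runs shorter than ``min_segment_windows`` labeled windows are treated
    as noise and absorbed into their larger neighbor, so an isolated
    discordant window cannot spawn a breakpoint.  One surviving segment
    gives a plain NEAR1/NEAR2 call; two or more alternating segments give
    RECOMBINANT with breakpoints at the boundary between adjacent
    segments' windows.
    """
    labels = _label_windows(track, score_threshold)
    runs = _runs(labels)
    with np.errstate(invalid="ignore"):
        mean_abs = float(np.nanmean(np.abs(track.values))) if np.any(
            ~np.isnan(track.values)
        ) else float("nan")
    evidence = {"mean_abs_score": mean_abs}
    if not runs:
        return OriginCall(track.hap_id, UNRESOLVED, evidence=evidence)
    # absorb sub-minimum runs into their stronger neighbor
    runs = [r for r in runs]
    while len(runs) > 1 and min(r[1] for r in runs) < min_segment_windows:
        k = min(range(len(runs)), key=lambda i: (runs[i][1], i))
        left = runs[k - 1] if k > 0 else None
        right = runs[k + 1] if k + 1 < len(runs) else None
        # absorbed windows extend the neighbor's span but do not add to
        # its labeled-window count (they carried the discordant label)
        if right is None or (left is not None and left[1] >= right[1]):
            left[3] = runs[k][3]
        else:
            right[2] = runs[k][2]
        del runs[k]
        # merge neighbors that now share a label
        merged: list[list] = []
        for r in runs:
            if merged and merged[-1][0] == r[0]:
                merged[-1][1] += r[1]
                merged[-1][3] = r[3]
            else:
                merged.append(r)
        runs = merged
    name = {1: NEAR2, -1: NEAR1}
    wins = track.windows
    segments = [
        (int(wins[r[2], 0]), int(wins[r[3], 1]), name[r[0]]) for r in runs
    ]
    if len(runs) == 1:
        if runs[0][1] < min_segment_windows:
            return OriginCall(
                track.hap_id, UNRESOLVED, segments=[], evidence=evidence
            )
        return OriginCall(
            track.hap_id, name[runs[0][0]], segments=segments, evidence=evidence
        )
    # breakpoint = midpoint between the last window of one segment and the
    # first of the next; contiguous windows make that the shared boundary
    breakpoints = tuple(
        int((wins[a[3], 1] + wins[b[2], 0]) // 2) for a, b in zip(runs, runs[1:])
    )
    return OriginCall(
        track.hap_id,
        RECOMBINANT,
        segments=segments,
        breakpoints=breakpoints,
        evidence=evidence,
    )


# ---------------------------------------------------------------------------
# orchestration


def type_origins(
    depth: pd.DataFrame,
    hap_alleles: Mapping[str, pd.DataFrame],
    snps: DiagnosticSNPSet,
    hap_groups: Mapping[str, str],
    spans: Mapping[str, int],
    score_window: int = 20_000,
    depth_fraction_threshold: float = 0.8,
    score_threshold: float = 0.8,
    min_segment_windows: int = 2,
    min_sites: int = 10,
) -> list[OriginCall]:
    """Full origin typing: depth gate first, then SNP-score segmentation.

    ``hap_alleles`` maps hap_id -> DataFrame(pos, allele) at diagnostic
    sites; ``spans`` maps hap_id -> haplotype length; ``hap_groups`` maps
    hap_id -> homologous group.
    """
    calls: list[OriginCall] = []
    mean_depths = depth.groupby(["hap_id", "sample"])["depth"].mean()
    fractions = far_depth_fractions(depth)
    for hap_id, gid in hap_groups.items():
        frac = float(fractions.get(hap_id, np.nan))
        if np.isnan(frac):
            warnings.warn(f"all-sample zero depth on {hap_id}; unresolved")
            gate = UNRESOLVED
        elif frac >= depth_fraction_threshold:
            gate = FAR
        elif frac <= 1.0 - depth_fraction_threshold:
            gate = NOT_FAR
        else:
            gate = UNRESOLVED
        evidence = {
            f"depth_{s.lower()}": float(mean_depths.get((hap_id, s), np.nan))
            for s in PARENT_SAMPLES
        }
        evidence["far_fraction"] = frac
        if gate == FAR:
            calls.append(
                OriginCall(
                    hap_id,
                    FAR,
                    segments=[(0, spans[hap_id], FAR)],
                    evidence=evidence,
                )
            )
            continue
        if gate == UNRESOLVED:
            calls.append(OriginCall(hap_id, UNRESOLVED, evidence=evidence))
            continue
        sites = snps.sites.get(gid)
        if sites is None or sites.empty:
            calls.append(OriginCall(hap_id, UNRESOLVED, evidence=evidence))
            continue
        scores = score_sites(hap_alleles[hap_id], sites)
        track = window_scores(
            scores, spans[hap_id], score_window, hap_id=hap_id, min_sites=min_sites
        )
        call = call_origin(track, score_threshold, min_segment_windows)
        call.evidence.update(evidence)
        calls.append(call)
    return calls


def calls_to_frame(calls: Iterable[OriginCall]) -> pd.DataFrame:
    """Tabular export of origin calls (one row per haplotype)."""
    rows = []
    for c in calls:
        rows.append(
            {
                "hap_id": c.hap_id,
                "origin": c.origin,
                "n_segments": len(c.segments),
                "segments": ";".join(f"{s}-{e}:{o}" for s, e, o in c.segments),
                "breakpoints": ",".join(str(b) for b in c.breakpoints),
                **{k: v for k, v in c.evidence.items()},
            }
        )
    return pd.DataFrame(rows)
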