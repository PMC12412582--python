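"""Synthetic amphitriploid genomes with planted ground truth.

The generator emulates the genomic structure of a three-parent
amphitriploid: one distantly related maternal parent ("FAR") and two
closely related paternal-side parents ("NEAR1", "NEAR2").  The offspring
carries, per homologous group, haplotypes drawn from four karyotype
categories:

1. one haplotype from each parent ``{FAR, NEAR1, NEAR2}``;
2. one FAR haplotype and two copies from the same near parent;
3. one FAR haplotype, one near haplotype, and a recombinant haplotype
   whose origin switches between the two near parents at planted
   breakpoints;
4. aneuploid groups with a copy number other than three.

Downstream observables are simulated directly rather than via reads:
window read-depth per parental sample (negative-binomial counts with a
cross-mapping floor), offspring alleles at diagnostic sites (with a
configurable allele-error rate), allele-expression triads with planted
category proportions, case/control population genotypes with one planted
differentiated block, and clonal genotype sets with planted within/between
clone identity.  Every simulated entity has exactly one ground-truth
record in the accompanying :class:`TruthSet`.

Sequences are i.i.d. substitutions on a random ancestral sequence; there
are no indels (downstream genotyping uses SNPs only).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .windows import make_windows

__all__ = [
    "FAR",
    "NEAR1",
    "NEAR2",
    "RECOMBINANT",
    "BASES",
    "GroupPlan",
    "FstBlock",
    "SimConfig",
    "Haplotype",
    "ParentGenomes",
    "TruthSet",
    "PopulationSim",
    "CloneSim",
    "default_karyotype_plan",
    "group_names",
    "simulate_parents",
    "simulate_offspring",
    "simulate_depth",
    "simulate_snp_observations",
    "simulate_expression",
    "simulate_populations",
    "simulate_clones",
]

FAR = "FAR"
NEAR1 = "NEAR1"
NEAR2 = "NEAR2"
RECOMBINANT = "RECOMBINANT"

PARENT_SAMPLES = (FAR, NEAR1, NEAR2)

#: base code -> letter (sequences are stored as uint8 codes 0..3)
BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# stage tags used to derive independent child RNG streams from one seed
_ST_PARENTS, _ST_DEPTH, _ST_SNPOBS, _ST_EXPR, _ST_POP, _ST_CLONE = range(6)


def _rng(seed: int, stage: int, index: int = 0) -> np.random.Generator:
    return np.random.default_rng([seed, stage, index])


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class GroupPlan:
    """Planned karyotype for one homologous group.

    ``category`` follows the four-way classification above.  For category
    3, ``breakpoints`` are the recombination positions (bp, 0-based) of the
    recombinant haplotype; segments alternate starting from NEAR1.  For
    category 4, ``copy_number`` gives the aneuploid copy count.  ``origins``
    may override the default origin list for the category.
    """

    category: int
    breakpoints: tuple[int, ...] = ()
    copy_number: int | None = None
    origins: tuple[str, ...] | None = None

    def origin_list(self) -> tuple[str, ...]:
        if self.origins is not None:
            return self.origins
        if self.category == 1:
            return (FAR, NEAR1, NEAR2)
        if self.category == 2:
            return (FAR, NEAR2, NEAR2)
        if self.category == 3:
            return (FAR, NEAR2, RECOMBINANT)
        if self.category == 4:
            n = self.copy_number if self.copy_number is not None else 4
            if n == 2:
                return (FAR, NEAR2)
            return (FAR, NEAR1) + (NEAR2,) * (n - 2)
        raise ValueError(f"unknown karyotype category {self.category}")


@dataclass(frozen=True)
class FstBlock:
    """Planted differentiated interval on the population chromosome."""

    start: int = 200_000
    end: int = 300_000
    freq_case: float = 1.0
    freq_control: float = 0.0


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the generator, with desk-scale defaults.

    Window sizes keep the 1:2 depth-window:score-window ratio of the
    full-genome analysis (10 Mb / 20 Mb there; 10 kb / 20 kb here on
    500 kb groups).
    """

    seed: int = 0
    n_groups: int = 25
    group_length: int = 500_000
    divergence_far: float = 0.010
    divergence_near: float = 0.003
    depth_mean: float = 30.0
    depth_noise: float = 0.1  # NB overdispersion alpha; 0 = noiseless
    cross_map_floor: float = 0.02  # epsilon: cross-parent mapping fraction
    near_cross: float = 0.5  # near-parent reads on the other near haplotype
    allele_error: float = 0.01
    depth_window: int = 10_000
    score_window: int = 20_000
    karyotype_plan: Mapping[str, GroupPlan] | None = None
    # expression
    n_genes: int = 5_000
    tissues: tuple[str, ...] = ("head_kidney",)
    triad_props: tuple[float, float, float] = (0.60, 0.17, 0.23)
    expression_floor: float = 1.0
    # populations
    n_case: int = 30
    n_control: int = 30
    pop_chrom: str = "popchr"
    pop_chrom_length: int = 500_000
    pop_n_sites: int = 500
    fst_block: FstBlock = field(default_factory=FstBlock)
    # clones
    n_clones: int = 3
    n_per_clone: int = 10
    clone_n_sites: int = 20_000
    identity_within: float = 0.982
    identity_between: float = 0.730

    def __post_init__(self):
        for name in (
            "divergence_far",
            "divergence_near",
            "cross_map_floor",
            "near_cross",
            "allele_error",
            "identity_within",
            "identity_between",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.divergence_far <= self.divergence_near:
            raise ValueError(
                "divergence_far must exceed divergence_near "
                f"({self.divergence_far} <= {self.divergence_near})"
            )
        if abs(sum(self.triad_props) - 1.0) > 1e-9:
            raise ValueError(f"triad_props must sum to 1, got {self.triad_props}")
        if min(self.triad_props) < 0:
            raise ValueError("triad_props must be non-negative")
        if self.depth_mean <= 0:
            raise ValueError(f"depth_mean must be positive, got {self.depth_mean}")
        if self.group_length <= 0:
            raise ValueError(f"group_length must be positive, got {self.group_length}")
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("need at least 2 individuals per group (Fst undefined)")
        blk = self.fst_block
        if not (0 <= blk.start < blk.end <= self.pop_chrom_length):
            raise ValueError(f"fst_block {blk} outside [0, {self.pop_chrom_length})")
        plan = self.karyotype_plan
        if plan is not None:
            for gid, gp in plan.items():
                for bp in gp.breakpoints:
                    if not 0 < bp < self.group_length:
                        raise ValueError(
                            f"breakpoint {bp} of group {gid} not strictly inside "
                            f"(0, {self.group_length})"
                        )

    def plan(self) -> dict[str, GroupPlan]:
        if self.karyotype_plan is not None:
            return dict(self.karyotype_plan)
        return default_karyotype_plan(self.n_groups, self.group_length)


def group_names(n: int) -> list[str]:
    """Homologous-group ids: chromosome number + alternating subgenome."""
    return [f"{i // 2 + 1:02d}{'AB'[i % 2]}" for i in range(n)]


def default_karyotype_plan(n_groups: int, group_length: int) -> dict[str, GroupPlan]:
    """Deterministic plan mirroring the study's karyogram structure.

    Mostly category-1 groups; a handful of category-2 groups; four
    recombinant (category 3) groups, one of them with two breakpoints;
    and two aneuploid (category 4) groups with copy numbers 2 and 4.
    """
    names = group_names(n_groups)
    L = group_length
    plan: dict[str, GroupPlan] = {}
    cat2 = {1, 5, 11, 17, 23}
    cat3 = {4: (round(0.5 * L),), 10: (round(0.3 * L),), 16: (round(0.62 * L),),
            22: (round(0.33 * L), round(0.66 * L))}
    cat4 = {7: 2, 19: 4}
    for i, name in enumerate(names):
        if i in cat3:
            plan[name] = GroupPlan(3, breakpoints=cat3[i])
        elif i in cat4:
            plan[name] = GroupPlan(4, copy_number=cat4[i])
        elif i in cat2:
            plan[name] = GroupPlan(2)
        else:
            plan[name] = GroupPlan(1)
    return plan


# ---------------------------------------------------------------------------
# containers


@dataclass
class Haplotype:
    hap_id: str
    group_id: str
    seq: np.ndarray  # uint8 codes 0..3

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ParentGenomes:
    """Per-group sequences of the three parents plus the variant table.

    ``variants`` has one row per position where the three parental alleles
    are not all identical: columns ``chrom, pos, ref, far, near1, near2``
    with 0-based ``pos`` and single-letter alleles (``ref`` is the
    ancestral allele, which equals the NEAR1 allele under the sequence
    model used here).
    """

    groups: dict[str, dict[str, np.ndarray]]
    variants: pd.DataFrame

    def group_length(self, gid: str) -> int:
        return len(self.groups[gid][FAR])

    def genotype_records(self):
        """Yield (chrom, pos, alleles, near1 gt, near2 gt) records, the
        input shape of the diagnostic-SNP filter, without a VCF detour."""
        for r in self.variants.itertuples(index=False):
            alleles = [r.ref]
            for a in (r.far, r.near1, r.near2):
                if a not in alleles:
                    alleles.append(a)
            yield (
                r.chrom,
                r.pos,
                tuple(alleles),
                (r.near1, r.near1),
                (r.near2, r.near2),
            )

    def diagnostic_truth(self, gid: str) -> pd.DataFrame:
        """Sites where the two near parents carry different alleles."""
        v = self.variants
        sub = v[(v["chrom"] == gid) & (v["near1"] != v["near2"])]
        return sub[["pos", "near1", "near2"]].reset_index(drop=True)


@dataclass
class TruthSet:
    """Ground truth for every simulated entity."""

    origins: dict[str, str] = field(default_factory=dict)
    segments: dict[str, list[tuple[int, int, str]]] = field(default_factory=dict)
    breakpoints: dict[str, tuple[int, ...]] = field(default_factory=dict)
    categories: dict[str, int] = field(default_factory=dict)
    triad_categories: dict[str, str] = field(default_factory=dict)
    hotspot: tuple[str, int, int] | None = None
    haplogroups: dict[str, str] = field(default_factory=dict)
    identity_targets: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=1, sort_keys=True, default=list)

    @classmethod
    def from_json(cls, text: str) -> "TruthSet":
        d = json.loads(text)
        d["segments"] = {
            k: [tuple(s) for s in v] for k, v in d.get("segments", {}).items()
        }
        d["breakpoints"] = {
            k: tuple(v) for k, v in d.get("breakpoints", {}).items()
        }
        if d.get("hotspot") is not None:
            d["hotspot"] = tuple(d["hotspot"])
        return cls(**d)


@dataclass
class PopulationSim:
    """Case/control genotypes on one chromosome with a planted block."""

    chrom: str
    positions: np.ndarray
    genotypes: np.ndarray  # (n_individuals, n_sites) int8 in {0,1,2}
    individuals: list[str]
    phenotypes: list[str]  # "case" / "control" per individual
    block: FstBlock


@dataclass
class CloneSim:
    """Genotypes of clonal lineages for identity-by-state analysis."""

    genotypes: np.ndarray  # (n_individuals, n_sites) int8 in {0,1,2}
    individuals: list[str]
    clone_of: list[str]


# ---------------------------------------------------------------------------
# sequence-level simulation


def _mutate(seq: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site with probability ``p`` to a different base."""
    out = seq.copy()
    if p <= 0:
        return out
    mask = rng.random(len(seq)) < p
    k = int(mask.sum())
    if k:
        out[mask] = (out[mask] + rng.integers(1, 4, size=k, dtype=np.uint8)) % 4
    return out


def simulate_parents(config: SimConfig) -> ParentGenomes:
    """Draw the three parental genomes over all homologous groups.

    NEAR1 is the close-parent ancestor; NEAR2 diverges from it at rate
    ``divergence_near`` and FAR at rate ``divergence_far``, so the
    realized count of near1/near2 differential sites per group is
    Binomial(group_length, divergence_near).
    """
    names = group_names(config.n_groups)
    groups: dict[str, dict[str, np.ndarray]] = {}
    rows = []
    letters = BASES.view("S1").astype("U1")
    for gi, gid in enumerate(names):
        rng = _rng(config.seed, _ST_PARENTS, gi)
        anc = rng.integers(0, 4, size=config.group_length, dtype=np.uint8)
        far = _mutate(anc, config.divergence_far, rng)
        near1 = anc
        near2 = _mutate(anc, config.divergence_near, rng)
        groups[gid] = {FAR: far, NEAR1: near1, NEAR2: near2}
        var = np.flatnonzero((far != anc) | (near2 != anc))
        rows.append(
            pd.DataFrame(
                {
                    "chrom": gid,
                    "pos": var,
                    "ref": letters[anc[var]],
                    "far": letters[far[var]],
                    "near1": letters[near1[var]],
                    "near2": letters[near2[var]],
                }
            )
        )
    variants = pd.concat(rows, ignore_index=True)
    return ParentGenomes(groups=groups, variants=variants)


def _recombinant_seq(
    g: dict[str, np.ndarray], breakpoints: Sequence[int]
) -> tuple[np.ndarray, list[tuple[int, int, str]]]:
    L = len(g[NEAR1])
    bounds = [0, *breakpoints, L]
    seq = np.empty(L, dtype=np.uint8)
    segs = []
    for k in range(len(bounds) - 1):
        origin = NEAR1 if k % 2 == 0 else NEAR2
        s, e = bounds[k], bounds[k + 1]
        seq[s:e] = g[origin][s:e]
        segs.append((s, e, origin))
    return seq, segs


def simulate_offspring(
    parents: ParentGenomes, config: SimConfig
) -> tuple[list[Haplotype], TruthSet]:
    """Assemble the planted triploid offspring from the karyotype plan."""
    plan = config.plan()
    missing = set(parents.groups) - set(plan)
    if missing:
        raise ValueError(f"karyotype plan misses groups: {sorted(missing)}")
    haplotypes: list[Haplotype] = []
    truth = TruthSet()
    for gid in parents.groups:
        gp = plan[gid]
        g = parents.groups[gid]
        L = len(g[FAR])
        for bp in gp.breakpoints:
            if not 0 < bp < L:
                raise ValueError(
                    f"breakpoint {bp} outside span (0, {L}) of group {gid}"
                )
        origins = gp.origin_list()
        truth.categories[gid] = gp.category
        for h, origin in enumerate(origins, start=1):
            hap_id = f"{gid}_h{h}"
            if origin == RECOMBINANT:
                seq, segs = _recombinant_seq(g, gp.breakpoints)
                truth.segments[hap_id] = segs
                truth.breakpoints[hap_id] = tuple(gp.breakpoints)
            else:
                seq = g[origin].copy()
                truth.segments[hap_id] = [(0, L, origin)]
                truth.breakpoints[hap_id] = ()
            truth.origins[hap_id] = origin
            haplotypes.append(Haplotype(hap_id, gid, seq))
    return haplotypes, truth


# ---------------------------------------------------------------------------
# observation models


def _expected_depth(origin: str, sample: str, config: SimConfig) -> float:
    m = config.depth_mean
    if origin == FAR:
        return m if sample == FAR else config.cross_map_floor * m
    if sample == FAR:
        return config.cross_map_floor * m
    return m if sample == origin else config.near_cross * m


def _nb_sample(mean: np.ndarray, alpha: float, rng: np.random.Generator) -> np.ndarray:
    """Negative binomial with var = m + alpha m^2; alpha=0 is noiseless."""
    if alpha <= 0:
        return mean.astype(float)
    size = 1.0 / alpha
    p = size / (size + mean)
    return rng.negative_binomial(size, p).astype(float)


def simulate_depth(
    offspring: Sequence[Haplotype], truth: TruthSet, config: SimConfig
) -> pd.DataFrame:
    """Window depth of each parental read set on each offspring haplotype.

    Depth is drawn per window around an expected mean of ``depth_mean``
    when the sample's parent contributed the window's segment, scaled by
    ``near_cross`` for the sister near parent and by the cross-mapping
    floor ``cross_map_floor`` across the far/near divide.  Windows that
    straddle a recombination breakpoint get a length-weighted mean.

    Returns a long table: hap_id, sample, start, end, depth.
    """
    if config.depth_mean <= 0:
        raise ValueError("depth_mean must be positive")
    recs = []
    for hi, hap in enumerate(offspring):
        rng = _rng(config.seed, _ST_DEPTH, hi)
        wins = make_windows(len(hap), config.depth_window)
        segs = truth.segments[hap.hap_id]
        for sample in PARENT_SAMPLES:
            mu = np.zeros(len(wins))
            for s, e, origin in segs:
                ov = np.clip(
                    np.minimum(wins[:, 1], e) - np.maximum(wins[:, 0], s), 0, None
                )
                mu += ov * _expected_depth(origin, sample, config)
            mu /= wins[:, 1] - wins[:, 0]
            depth = _nb_sample(mu, config.depth_noise, rng)
            recs.append(
                pd.DataFrame(
                    {
                        "hap_id": hap.hap_id,
                        "sample": sample,
                        "start": wins[:, 0],
                        "end": wins[:, 1],
                        "depth": depth,
                    }
                )
            )
    return pd.concat(recs, ignore_index=True)


def simulate_snp_observations(
    parents: ParentGenomes,
    offspring: Sequence[Haplotype],
    config: SimConfig,
) -> dict[str, pd.DataFrame]:
    """Observed offspring alleles at the near1/near2 differential sites.

    Each allele is miscalled with probability ``allele_error`` (replaced
    by a uniformly random different base), emulating assembly/genotyping
    noise.  Returns hap_id -> DataFrame(pos, allele).
    """
    letters = BASES.view("S1").astype("U1")
    diag = {gid: parents.diagnostic_truth(gid) for gid in parents.groups}
    out: dict[str, pd.DataFrame] = {}
    for hi, hap in enumerate(offspring):
        rng = _rng(config.seed, _ST_SNPOBS, hi)
        sites = diag[hap.group_id]
        pos = sites["pos"].to_numpy()
        alleles = hap.seq[pos]
        if config.allele_error > 0 and len(pos):
            mask = rng.random(len(pos)) < config.allele_error
            k = int(mask.sum())
            if k:
                alleles = alleles.copy()
                alleles[mask] = (
                    alleles[mask] + rng.integers(1, 4, size=k, dtype=np.uint8)
                ) % 4
        out[hap.hap_id] = pd.DataFrame({"pos": pos, "allele": letters[alleles]})
    return out


# ---------------------------------------------------------------------------
# expression triads

_TRIAD_CATS = ("BALANCED", "FAR_DOMINANT", "OTHER_DOMINANT")
# interior log-ratio ranges per category; margins keep multiplicative noise
# away from the 1:1 and 1:4 classification boundaries
_RATIO_RANGES = {
    "BALANCED": (0.30, 0.85),
    "FAR_DOMINANT": (1.0, 6.0),
    "OTHER_DOMINANT": (0.03, 0.25),
}


def simulate_expression(
    config: SimConfig, truth: TruthSet | None = None
) -> pd.DataFrame:
    """Per-gene triad expression with planted category proportions.

    For each gene a category is drawn from ``triad_props`` (balanced,
    far-dominant, other-dominant); the far/other expression ratio is then
    drawn log-uniformly inside that category's region and the total
    expression from a shifted log-normal that never falls below the
    expression floor.  Gene categories are shared across tissues.
    """
    props = np.asarray(config.triad_props, dtype=float)
    if config.expression_floor <= 0:
        raise ValueError("expression floor must be positive")
    rng = _rng(config.seed, _ST_EXPR)
    cats = rng.choice(len(_TRIAD_CATS), size=config.n_genes, p=props)
    gene_ids = [f"gene{g:05d}" for g in range(config.n_genes)]
    rows = []
    for tissue in config.tissues:
        lo = np.array([_RATIO_RANGES[_TRIAD_CATS[c]][0] for c in cats])
        hi = np.array([_RATIO_RANGES[_TRIAD_CATS[c]][1] for c in cats])
        r = np.exp(rng.uniform(np.log(lo), np.log(hi)))
        total = config.expression_floor + rng.lognormal(2.5, 1.0, size=config.n_genes)
        e_far = total * r / (1.0 + r)
        e_other = total / (1.0 + r)
        rows.append(
            pd.DataFrame(
                {
                    "gene_id": gene_ids,
                    "tissue": tissue,
                    "e_far": e_far,
                    "e_other": e_other,
                }
            )
        )
    if truth is not None:
        for g, c in zip(gene_ids, cats):
            truth.triad_categories[g] = _TRIAD_CATS[c]
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# populations and clones


def simulate_populations(
    config: SimConfig, truth: TruthSet | None = None
) -> PopulationSim:
    """Case/control genotypes with one planted differentiated block.

    Outside the block both groups share the same site allele frequency
    (uniform on [0.05, 0.95]); inside it the groups are driven to the
    planted frequencies (a fixed difference by default).
    """
    rng = _rng(config.seed, _ST_POP)
    pos = np.sort(
        rng.choice(config.pop_chrom_length, size=config.pop_n_sites, replace=False)
    )
    p_bg = rng.uniform(0.05, 0.95, size=config.pop_n_sites)
    blk = config.fst_block
    in_block = (pos >= blk.start) & (pos < blk.end)
    p_case = np.where(in_block, blk.freq_case, p_bg)
    p_ctrl = np.where(in_block, blk.freq_control, p_bg)
    n1, n2 = config.n_case, config.n_control
    g_case = rng.binomial(2, p_case, size=(n1, config.pop_n_sites))
    g_ctrl = rng.binomial(2, p_ctrl, size=(n2, config.pop_n_sites))
    genotypes = np.vstack([g_case, g_ctrl]).astype(np.int8)
    individuals = [f"case{i:03d}" for i in range(n1)] + [
        f"ctrl{i:03d}" for i in range(n2)
    ]
    phenotypes = ["case"] * n1 + ["control"] * n2
    if truth is not None:
        truth.hotspot = (config.pop_chrom, int(blk.start), int(blk.end))
        truth.haplogroups = dict(zip(individuals, phenotypes))
    return PopulationSim(
        chrom=config.pop_chrom,
        positions=pos,
        genotypes=genotypes,
        individuals=individuals,
        phenotypes=phenotypes,
        block=blk,
    )


def clone_design(identity_within: float, identity_between: float) -> tuple[float, float]:
    """Solve the per-site flip rate and conserved-site fraction.

    A member genotype flips from its clone founder with probability ``d``
    (to one of the two other genotype states uniformly).  Two members of
    one clone are then identical at a site with probability
    ``P_same = (1-d)^2 + d^2/2``; members of clones whose founders differ
    at the site agree with probability ``P_diff = d(1-d) + d^2/4``.
    Making a fraction ``q`` of sites founder-conserved yields between-clone
    identity ``q P_same + (1-q) P_diff``; both targets have closed-form
    solutions used here.
    """
    w, b = identity_within, identity_between
    if not 0 < b < w <= 1:
        raise ValueError("need 0 < identity_between < identity_within <= 1")
    # (1-d)^2 + d^2/2 = w  ->  1.5 d^2 - 2 d + (1 - w) = 0
    d = (2.0 - np.sqrt(4.0 - 6.0 * (1.0 - w))) / 3.0
    p_diff = d * (1.0 - d) + d * d / 4.0
    q = (b - p_diff) / (w - p_diff)
    if not 0 <= q <= 1:
        raise ValueError("identity targets not realizable")
    return d, q


def simulate_clones(config: SimConfig, truth: TruthSet | None = None) -> CloneSim:
    """Clonal lineages with planted within/between identity.

    Supports up to three clones with exact pairwise targets: founders are
    identical at a conserved fraction of sites and pairwise-distinct
    elsewhere (three genotype states allow three mutually distinct
    founders).
    """
    if config.n_clones > 3:
        raise ValueError("pairwise identity targets only realizable for <=3 clones")
    d, q = clone_design(config.identity_within, config.identity_between)
    rng = _rng(config.seed, _ST_CLONE)
    n_sites = config.clone_n_sites
    base = rng.integers(0, 3, size=n_sites, dtype=np.int8)
    conserved = rng.random(n_sites) < q
    founders = []
    for k in range(config.n_clones):
        f = (base + k) % 3
        f[conserved] = base[conserved]
        founders.append(f.astype(np.int8))
    genotypes = []
    individuals = []
    clone_of = []
    for k, founder in enumerate(founders):
        for j in range(config.n_per_clone):
            g = founder.copy()
            mask = rng.random(n_sites) < d
            nflip = int(mask.sum())
            if nflip:
                g[mask] = (g[mask] + rng.integers(1, 3, size=nflip, dtype=np.int8)) % 3
            genotypes.append(g)
            individuals.append(f"clone{k + 1}_i{j:02d}")
            clone_of.append(f"clone{k + 1}")
    if truth is not None:
        truth.identity_targets = {
            "within": config.identity_within,
            "between": config.identity_between,
        }
    return CloneSim(
        genotypes=np.vstack(genotypes),
        individuals=individuals,
        clone_of=clone_of,
    )
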