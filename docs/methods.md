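# Methods

## The inference problem

An amphitriploid genome assembled to haplotype resolution contains, per
homologous group, two to four haplotype copies whose parental origin is
unknown. Three parental samples are available: one distantly related
maternal parent ("FAR") and two closely related paternal-side parents
("NEAR1", "NEAR2"). The package assigns each haplotype to a parent,
finds recombination breakpoints between the two near parents, and runs
the downstream analyses that depend on those assignments (karyotype
categories, homoeolog expression triads, case/control Fst scans,
identity-by-state clonality).

## Origin typing

**Depth layer.** Each parental sample's window depths are normalized by
that sample's genome-wide mean and scaled to a common reference
coverage, making samples of different yield comparable. The far-parent
share of total normalized depth, averaged over windows, is compared to a
threshold (default 0.8): share ≥ 0.8 → FAR, ≤ 0.2 → NOT-FAR, otherwise
UNRESOLVED. The share is invariant to uniform rescaling, so the
reference constant is cosmetic. Depth cannot separate the two near
parents — their reads cross-map onto each other's haplotypes — which is
exactly why the second layer exists.

**Diagnostic-SNP layer.** Diagnostic sites are the positions where both
near parents are homozygous for different alleles; multiallelic records,
indels, heterozygous and missing calls are dropped with per-reason
counts. A NOT-FAR haplotype scores +1 at a site where it carries the
NEAR2 allele and −1 for NEAR1; a third allele or a missing call is
excluded from window means rather than scored 0, so errors cannot drag
|mean| toward the ambiguous zone. Window means (default window twice the
depth window) are labeled NEAR2 (≥ +0.8), NEAR1 (≤ −0.8) or ambiguous.

**Segmentation.** Maximal runs of same-label windows form candidate
segments; ambiguous windows between two runs are absorbed into the
longer flank (left on ties), leading/trailing ones into the nearest run.
Runs with fewer labeled windows than `min_segment_windows` (default 2)
are treated as noise and absorbed into the larger neighbor, so one
discordant window cannot spawn a breakpoint. One surviving segment gives
a plain NEAR1/NEAR2 call; two or more alternating segments give
RECOMBINANT with breakpoints at the boundary between adjacent segments'
windows — breakpoint resolution is therefore one score window. A track
with no labeled window, or a single run shorter than the minimum, is
UNRESOLVED; so is a haplotype whose depth share sits between the two
gates.

**Thresholds.** The 0.8 depth-share and 0.8 score thresholds
operationalize the qualitative separation the method relies on (depth
share near 1 vs near 0; window means near ±1); both are exposed in
configuration, and results at desk scale are insensitive to them over a
wide range because the noiseless gap between classes is large.

## Karyotype categories

Exactly three haplotypes with one FAR: {FAR, NEAR1, NEAR2} is category
1; a doubled near parent is category 2; a trio containing exactly one
recombinant plus one pure near haplotype is category 3; any copy number
other than three is category 4 (aneuploid). Both mirror forms of
categories 2 and 3 (NEAR1 doubled, or a recombinant accompanying NEAR1)
are accepted by symmetry — the biology does not single out one near
parent. Groups with an UNRESOLVED member, no FAR, two FARs, or two
recombinants are reported UNRESOLVED, never force-classified.

## Expression triads

With `r = E_far / E_other` (pooled close-parent alleles), the category
regions are: FAR_DOMINANT at r ≥ 1, OTHER_DOMINANT at r ≤ 1/4, BALANCED
on the open interval between them (which contains the dosage point
r = 1/2); both dominance thresholds are inclusive. Balanced is defined
by exclusion because only the two dominance thresholds are sharp. The
1 FPKM expression floor applies to the triad **total**: applying it per
allele would silently drop monoallelic genes, and E_other = 0 with an
expressed total is FAR_DOMINANT (r = +∞). The classifier is total,
deterministic and scale-invariant above the floor; per-tissue
proportions exclude NOT_EXPRESSED records from the denominator.

## Fst, hotspots, haplogroups, IBS

Per-site differentiation uses the Weir–Cockerham (1984) estimator in its
two-level diploid form (components a, b, c; estimate a/(a+b+c)),
matching the convention of the standard VCF tooling. Monomorphic and
under-sampled sites are excluded and counted. Windowed values combine
sites by ratio of sums Σa/Σ(a+b+c) — not the mean of per-site estimates
— and negative per-site components are retained in the sums; windows
with fewer than `min_sites` (default 5) sites are flagged. The test
suite checks the estimator against an independent transcription (a
numeric nested ANOVA on per-allele indicators) to 1e-12, on random
instances and by exhaustive enumeration at small n.

Hotspots are maximal runs of windows at or above the threshold (default
0.3), tolerating up to `merge_gap` (default 1) sub-threshold windows
inside a run; gap windows join the region's span but not its mean Fst.
Extraction is idempotent and monotone in the threshold.

Within a region, individuals are split into two haplogroups by
2-medoids clustering on IBS distance (1 − proportion of identical
unphased genotypes over shared non-missing sites). The clustering is
deterministic: medoids start at the most distant pair and ties break to
the lowest index, with distances rounded at 1e-12 before comparison so
float noise cannot flip a tie. Concordance is the fraction of
individuals whose phenotype matches the majority phenotype of their
haplogroup; a control region's concordance is compared against a
permutation baseline rather than an absolute value.

## The synthetic-data generator

The generator emulates the study design, not the sequencing process:

* **Sequences** — i.i.d. substitutions on a random ancestral sequence;
  NEAR1 is the close-parent ancestor, NEAR2 diverges at 0.3% per site
  and FAR at 1.0%, preserving the far/near hierarchy. No indels
  (genotyping uses SNPs only), no mutation-rate heterogeneity, no
  structural variation.
* **Karyotypes** — a deterministic default plan over 25 groups: 14
  category-1, 5 category-2, 4 recombinant groups (one with two
  breakpoints) and 2 aneuploids (copy numbers 2 and 4), echoing the
  structure of a real amphitriploid karyogram.
* **Depth** — negative-binomial window counts with variance
  m + α·m² (α = 0.1 by default; α = 0 is the noiseless limit used in
  exact-recovery tests) around 30× for the contributing parent, a 2%
  cross-mapping floor across the far/near divide, and 50% cross-mapping
  between the two near parents (they are close enough that both map).
  Real cross-mapping depends on mapping stringency; the floor is a free
  parameter.
* **SNP observations** — offspring alleles at diagnostic sites miscalled
  at 1% to a random other base, emulating assembly/genotyping error.
* **Triads** — categories drawn from a planted mixture (default
  0.60/0.17/0.23 balanced/far/other, the kind of split reported for
  hematopoietic tissues in amphitriploids); ratios drawn log-uniformly
  inside each category with a margin to the boundaries so noise cannot
  cross them; totals from a shifted log-normal that never falls below
  the floor. Only expressed genes are emitted.
* **Populations** — 30 + 30 individuals, 500 sites on a 500 kb
  chromosome, shared background frequencies (uniform 0.05–0.95) and a
  planted fixed-difference block at 200–300 kb. A fixed difference makes
  the in-block windowed Fst exactly 1 and the haplogroup split exact;
  weaker planted differences are configurable.
* **Clones** — up to three clonal lineages; a closed-form design (flip
  rate d and conserved-site fraction q) hits the planted within-clone
  (98.2%) and between-clone (73.0%) identities in expectation. With
  three genotype states, three mutually distinct founders exist at
  non-conserved sites; more than three clones cannot satisfy all
  pairwise targets and are rejected.

Passing tests on these data demonstrate that the decision rules,
segmentation, estimators and bookkeeping are correct under the stated
noise models; they do not demonstrate robustness to alignment artifacts,
reference bias, copy-number variation of the parents or expression
quantification error, none of which the generator produces.

## Scale, coordinates, determinism

Desk scale is 25 groups × 500 kb with 10 kb depth and 20 kb score
windows — the same 1:2 depth:score window ratio as a full-genome run at
10/20 Mb; the acceptance script uses 40 replicate seeds for the
breakpoint sweep and the test suite 100. All internal coordinates are
0-based half-open; VCF is the only 1-based surface, converted exactly at
the parse/write boundary. Window tiling keeps a final partial window
when it covers at least half the nominal size, otherwise merges it into
the previous window. A single top-level seed drives every stage through
deterministically derived child streams, so a rerun with the same
configuration reproduces byte-identical outputs (checked via SHA-256
manifests).

## Known limitations

* Breakpoint positions are resolved only to one score window; there is
  no sub-window refinement from individual sites.
* A haplotype whose depth gate and SNP scores disagree (e.g. FAR by
  depth but scoreable against the near parents) is left UNRESOLVED
  rather than adjudicated.
* The Fst scan assumes two phenotype groups and diploid-coded genotypes;
  haploid coding is rejected rather than converted.
* 2-medoids assumes exactly two haplogroups in a region; regions with
  more structure would need a different clustering.
* The generator's identity-by-state design supports at most three
  clones with exact pairwise targets.
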