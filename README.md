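# polyorigin

Parental-origin typing and downstream population genomics for
**three-parent allopolyploid genomes**.

Some synthetic polyploids carry chromosome sets from three parental
species at once — for example an amphitriploid carp that inherits one
genome set from a distantly related maternal species and two sets from a
pair of closely related paternal-side species. Working with such a
genome requires answering, for every assembled haplotype: *which parent
contributed it, and did any haplotype recombine between the two close
parents?* `polyorigin` implements that analysis as a tested, reusable
library:

* **Origin typing** — two evidence layers per haplotype:
  * *read depth*: each parent's short reads are mapped to the
    haplotype-resolved assembly; the far parent's share of normalized
    window depth separates its haplotypes from the rest (a share ≥ 0.8
    averaged over windows calls FAR, ≤ 0.2 calls NOT-FAR);
  * *diagnostic SNPs*: at sites where the two close parents are
    homozygous for different alleles, a haplotype scores **+1** when it
    carries the second parent's allele and **−1** for the first; window
    means near ±1 assign the haplotype, and a sign switch along the
    chromosome marks an inter-parental **recombination breakpoint**.
* **Karyotyping** — per homologous group, origin calls combine into one
  of four categories: one haplotype per parent; a doubled close parent;
  a trio containing a recombinant; or an aneuploid group (copy number
  ≠ 3).
* **Expression triads** — per gene, the distant-parent allele (E_far)
  vs the pooled close-parent alleles (E_other); with r = E_far/E_other,
  triads are far-dominant at r ≥ 1, other-dominant at r ≤ 1/4, balanced
  in between (the 1:2 dose point), not-expressed below 1 FPKM total.
* **Fst hotspot scan** — per-site Weir–Cockerham (1984) components
  (a, b, c) between two phenotype groups, windowed by ratio of sums
  Σa/Σ(a+b+c), hotspot regions at Fst ≥ 0.3, and 2-medoids haplogroup /
  phenotype concordance inside each hotspot.
* **Clonality** — pairwise identity-by-state matrices over unphased
  genotypes.
* **Synthetic data** — a generator that emulates the full study design
  (three parental lineages with a divergence hierarchy, planted
  karyotypes with breakpoints, negative-binomial depth, noisy SNP
  observations, planted triad mixtures, case/control cohorts with one
  differentiated block, clonal lineages) together with a machine-readable
  `TruthSet`, so every stage is testable end to end without any
  sequencing data.

## Worked example

```bash
python examples/02_origin_typing.py
```

```
haplotype origin accuracy: 100.0% (75 haplotypes)
karyotype category accuracy: 100.0% (25 groups)

category counts:
 category  n_groups
        1        14
        2         5
        3         4
        4         2

recombinant haplotypes (detected vs planted breakpoints):
  03A_h3: (260000,) vs (250000,)
  06A_h3: (140000,) vs (150000,)
  09A_h3: (320000,) vs (310000,)
  12A_h3: (180000, 320000) vs (165000, 330000)
```

This simulates 25 homologous groups of 500 kb at 30× negative-binomial
depth with a 1% allele-error rate, runs the depth gate and the windowed
±1 scoring, and compares against the planted truth: every haplotype
origin and group category is recovered, and each detected breakpoint
falls within one 20 kb score window of its planted position (breakpoint
resolution is one score window by construction).

The other examples cover the generator itself, triad classification
(recovering a planted 60/17/23 mixture over 5000 genes), the Fst scan
(one planted block recovered exactly, haplogroup concordance 1.0 in the
hotspot vs 0.52 in a control region) and IBS clonality (98.2% within /
73.0% between clones planted and recovered).

A thin CLI wraps the same code: `polyorigin run --seed 1 --outdir out/`
writes FASTA/VCF/bedGraph/TSV outputs for every stage plus a checksum
manifest; `polyorigin triads` and `polyorigin fst` operate on files in
the same formats.

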