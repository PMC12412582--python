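"""File formats: FASTA, VCF 4.2, bedGraph, TSV, truth JSON.

All in-memory coordinates are 0-based half-open; VCF is the only 1-based
interface and is converted exactly at the parse/write boundary.  Reading
uses the standard parsers (Biopython for FASTA, cyvcf2 for VCF); writers
emit the plain-text formats directly.
"""

from __future__ import annotations

import os
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simulate import BASES, Haplotype, ParentGenomes, PopulationSim

__all__ = [
    "write_fasta",
    "read_fasta",
    "haplotypes_to_fasta",
    "fasta_to_haplotypes",
    "write_group_map",
    "read_group_map",
    "write_depth_bedgraph",
    "read_depth_bedgraph",
    "write_parent_vcf",
    "iter_vcf_parent_genotypes",
    "write_population_vcf",
    "read_population_vcf",
    "write_tsv",
    "read_tsv",
]

_CODE = {b: i for i, b in enumerate("ACGT")}


def _seq_to_str(seq: np.ndarray) -> str:
    return BASES[seq].tobytes().decode("ascii")


def _str_to_seq(s: str) -> np.ndarray:
    arr = np.frombuffer(s.upper().encode("ascii"), dtype=np.uint8)
    out = np.empty(len(arr), dtype=np.uint8)
    for b, i in _CODE.items():
        out[arr == ord(b)] = i
    return out


def write_fasta(path: str, records: Iterable[tuple[str, np.ndarray]]) -> None:
    """Write (name, coded-sequence) pairs as FASTA."""
    seqrecs = (
        SeqRecord(Seq(_seq_to_str(seq)), id=name, description="")
        for name, seq in records
    )
    SeqIO.write(seqrecs, path, "fasta")


def read_fasta(path: str) -> dict[str, np.ndarray]:
    return {rec.id: _str_to_seq(str(rec.seq)) for rec in SeqIO.parse(path, "fasta")}


def haplotypes_to_fasta(path: str, haplotypes: Iterable[Haplotype]) -> None:
    write_fasta(path, ((h.hap_id, h.seq) for h in haplotypes))


def fasta_to_haplotypes(path: str, groups: dict[str, str]) -> list[Haplotype]:
    return [
        Haplotype(hap_id=name, group_id=groups[name], seq=seq)
        for name, seq in read_fasta(path).items()
    ]


def write_group_map(path: str, hap_groups: dict[str, str]) -> None:
    pd.DataFrame(
        {"hap_id": list(hap_groups), "group_id": list(hap_groups.values())}
    ).to_csv(path, sep="\t", index=False)


def read_group_map(path: str) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["hap_id"], df["group_id"]))


# ---------------------------------------------------------------------------
# bedGraph depth tracks


def write_depth_bedgraph(depth: pd.DataFrame, outdir: str) -> dict[str, str]:
    """One bedGraph per parental sample; chrom column holds the hap id."""
    os.makedirs(outdir, exist_ok=True)
    paths = {}
    for sample, sub in depth.groupby("sample"):
        path = os.path.join(outdir, f"depth_{sample}.bedgraph")
        sub[["hap_id", "start", "end", "depth"]].to_csv(
            path, sep="\t", index=False, header=False
        )
        paths[sample] = path
    return paths


def read_depth_bedgraph(paths: dict[str, str]) -> pd.DataFrame:
    frames = []
    for sample, path in paths.items():
        df = pd.read_csv(
            path, sep="\t", names=["hap_id", "start", "end", "depth"]
        )
        df["sample"] = sample
        frames.append(df)
    return pd.concat(frames, ignore_index=True)[
        ["hap_id", "sample", "start", "end", "depth"]
    ]


# ---------------------------------------------------------------------------
# VCF


def _vcf_header(contigs: Iterable[tuple[str, int]], samples: list[str]) -> str:
    lines = ["##fileformat=VCFv4.2", "##source=polyorigin"]
    lines += [f"##contig=<ID={c},length={l}>" for c, l in contigs]
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    return "\n".join(lines) + "\n"


def write_parent_vcf(parents: ParentGenomes, path: str) -> None:
    """Homozygous parental genotypes (samples FAR, NEAR1, NEAR2)."""
    contigs = [(gid, parents.group_length(gid)) for gid in parents.groups]
    with open(path, "w") as fh:
        fh.write(_vcf_header(contigs, ["FAR", "NEAR1", "NEAR2"]))
        v = parents.variants
        for chrom, pos, ref, far, n1, n2 in zip(
            v["chrom"], v["pos"], v["ref"], v["far"], v["near1"], v["near2"]
        ):
            alts = []
            for a in (far, n1, n2):
                if a != ref and a not in alts:
                    alts.append(a)
            idx = {ref: 0, **{a: i + 1 for i, a in enumerate(alts)}}
            gts = "\t".join(f"{idx[a]}/{idx[a]}" for a in (far, n1, n2))
            fh.write(
                f"{chrom}\t{pos + 1}\t.\t{ref}\t{','.join(alts)}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def iter_vcf_parent_genotypes(
    path: str, near1_sample: str = "NEAR1", near2_sample: str = "NEAR2"
) -> Iterator[tuple[str, int, tuple, tuple, tuple]]:
    """Adapt a VCF to (chrom, pos0, alleles, near1 gt, near2 gt) records.

    Genotype indices are resolved to allele strings; missing calls map to
    ``None`` entries so the diagnostic-SNP filter can drop them, and the
    record's full allele tuple lets it drop multiallelic sites.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    try:
        i1 = vcf.samples.index(near1_sample)
        i2 = vcf.samples.index(near2_sample)
    except ValueError as exc:
        raise ValueError(
            f"samples {near1_sample}/{near2_sample} not in {vcf.samples}"
        ) from exc
    for rec in vcf:
        alleles = [rec.REF] + list(rec.ALT)

        def resolve(idx: int) -> tuple:
            gt = rec.genotypes[idx][:-1]  # last element is the phased flag
            return tuple(None if a < 0 else alleles[a] for a in gt)

        yield rec.CHROM, rec.POS - 1, tuple(alleles), resolve(i1), resolve(i2)
    vcf.close()


def write_population_vcf(pop: PopulationSim, path: str) -> None:
    """Case/control diploid genotypes as a biallelic VCF."""
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write(
            _vcf_header(
                [(pop.chrom, int(pop.positions.max()) + 1)], list(pop.individuals)
            )
        )
        for j, pos in enumerate(pop.positions):
            gts = "\t".join(gt_str[int(g)] for g in pop.genotypes[:, j])
            fh.write(f"{pop.chrom}\t{pos + 1}\t.\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


def read_population_vcf(path: str) -> tuple[np.ndarray, np.ndarray, list[str], str]:
    """Returns (genotype dosage matrix, positions, sample names, chrom)."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    cols = []
    positions = []
    chrom = ""
    # cyvcf2 gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
    remap = np.array([0, 1, -1, 2], dtype=np.int8)
    for rec in vcf:
        chrom = rec.CHROM
        positions.append(rec.POS - 1)
        cols.append(remap[rec.gt_types])
    vcf.close()
    return (
        np.column_stack(cols).astype(np.int8),
        np.asarray(positions),
        samples,
        chrom,
    )


def write_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
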