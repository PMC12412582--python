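"""End-to-end reproducible run: simulate -> genotype -> karyotype ->
triads -> fst, with a checksum manifest.

Every stage writes its outputs as plain-text files and the downstream
stage reads them back, so the pipeline exercises the same interfaces a
user would drive with real data.  Re-running with the same configuration
reproduces identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd

from . import fst as fst_mod
from . import io as pio
from . import karyotype as karyo_mod
from . import origin as origin_mod
from . import triads as triad_mod
from .simulate import (
    SimConfig,
    TruthSet,
    simulate_clones,
    simulate_depth,
    simulate_expression,
    simulate_offspring,
    simulate_parents,
    simulate_populations,
    simulate_snp_observations,
)

log = logging.getLogger("polyorigin")

__all__ = ["RunConfig", "run_pipeline", "simulate_and_type", "file_checksums"]


@dataclass
class RunConfig:
    """Umbrella configuration: simulation plus analysis thresholds."""

    sim: SimConfig = field(default_factory=SimConfig)
    depth_fraction_threshold: float = 0.8
    score_threshold: float = 0.8
    min_segment_windows: int = 2
    min_sites: int = 10
    triad_floor: float = 1.0
    fst_threshold: float = 0.3
    fst_window: int = 10_000
    fst_min_sites: int = 5

    def __post_init__(self):
        for name in ("depth_fraction_threshold", "score_threshold"):
            v = getattr(self, name)
            if not 0.5 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0.5, 1], got {v}")
        if not 0.0 <= self.fst_threshold <= 1.0:
            raise ValueError("fst_threshold must be in [0, 1]")
        if self.triad_floor <= 0:
            raise ValueError("triad_floor must be positive")


def file_checksums(paths: dict[str, str]) -> dict[str, str]:
    out = {}
    for key, path in sorted(paths.items()):
        h = hashlib.sha256()
        with open(path, "rb") as fh:
            for chunk in iter(lambda: fh.read(1 << 20), b""):
                h.update(chunk)
        out[key] = h.hexdigest()
    return out


def simulate_and_type(config: RunConfig):
    """In-memory simulate -> origin-type -> karyotype round (no files).

    Returns ``(truth, calls, karyotypes)``; useful for parameter-recovery
    studies where the file layer would dominate runtime.
    """
    sim = config.sim
    parents = simulate_parents(sim)
    offspring, truth = simulate_offspring(parents, sim)
    hap_groups = {h.hap_id: h.group_id for h in offspring}
    depth = simulate_depth(offspring, truth, sim)
    alleles = simulate_snp_observations(parents, offspring, sim)
    normalized = origin_mod.normalize_depth(depth)
    snps = origin_mod.diagnostic_snps_from_variants(parents.variants)
    calls = origin_mod.type_origins(
        normalized,
        alleles,
        snps,
        hap_groups,
        {h.hap_id: len(h) for h in offspring},
        score_window=sim.score_window,
        depth_fraction_threshold=config.depth_fraction_threshold,
        score_threshold=config.score_threshold,
        min_segment_windows=config.min_segment_windows,
        min_sites=config.min_sites,
    )
    karyotypes = karyo_mod.assemble_karyogram(calls, hap_groups)
    return truth, calls, karyotypes


def run_pipeline(config: RunConfig, outdir: str) -> dict:
    """Run all stages into ``outdir``; returns the manifest dict."""
    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}

    def p(name: str) -> str:
        paths[name] = os.path.join(outdir, name)
        return paths[name]

    sim = config.sim
    log.info("simulating parents and offspring (seed=%d)", sim.seed)
    parents = simulate_parents(sim)
    offspring, truth = simulate_offspring(parents, sim)
    hap_groups = {h.hap_id: h.group_id for h in offspring}
    spans = {h.hap_id: len(h) for h in offspring}

    for origin_name in ("FAR", "NEAR1", "NEAR2"):
        pio.write_fasta(
            p(f"parent_{origin_name}.fasta"),
            ((gid, parents.groups[gid][origin_name]) for gid in parents.groups),
        )
    pio.haplotypes_to_fasta(p("offspring.fasta"), offspring)
    pio.write_group_map(p("groups.tsv"), hap_groups)
    pio.write_parent_vcf(parents, p("parents.vcf"))
    with open(p("truth.json"), "w") as fh:
        fh.write(truth.to_json())

    log.info("simulating depth and SNP observations")
    depth = simulate_depth(offspring, truth, sim)
    bg_paths = pio.write_depth_bedgraph(depth, os.path.join(outdir, "depth"))
    paths.update({f"depth/{k}": v for k, v in bg_paths.items()})
    hap_alleles = simulate_snp_observations(parents, offspring, sim)

    log.info("origin typing")
    depth_in = pio.read_depth_bedgraph(bg_paths)
    depth_norm = origin_mod.normalize_depth(depth_in)
    snps = origin_mod.extract_diagnostic_snps(
        pio.iter_vcf_parent_genotypes(paths["parents.vcf"])
    )
    calls = origin_mod.type_origins(
        depth_norm,
        hap_alleles,
        snps,
        hap_groups,
        spans,
        score_window=sim.score_window,
        depth_fraction_threshold=config.depth_fraction_threshold,
        score_threshold=config.score_threshold,
        min_segment_windows=config.min_segment_windows,
        min_sites=config.min_sites,
    )
    pio.write_tsv(origin_mod.calls_to_frame(calls), p("origin_calls.tsv"))

    log.info("karyotyping")
    karyotypes = karyo_mod.assemble_karyogram(calls, hap_groups)
    k_table, k_summary = karyo_mod.karyogram_report(karyotypes)
    pio.write_tsv(k_table, p("karyogram.tsv"))
    pio.write_tsv(k_summary, p("karyogram_summary.tsv"))

    log.info("triad expression")
    expr = simulate_expression(sim, truth)
    pio.write_tsv(expr, p("expression.tsv"))
    classified = triad_mod.classify_table(
        pio.read_tsv(paths["expression.tsv"]), floor=config.triad_floor
    )
    pio.write_tsv(classified, p("triads_classified.tsv"))
    pio.write_tsv(triad_mod.triad_proportions(classified), p("triad_proportions.tsv"))

    log.info("population Fst scan")
    pop = simulate_populations(sim, truth)
    pio.write_population_vcf(pop, p("population.vcf"))
    pd.DataFrame({"individual": pop.individuals, "group": pop.phenotypes}).to_csv(
        p("phenotypes.tsv"), sep="\t", index=False
    )
    genotypes, positions, samples, chrom = pio.read_population_vcf(
        paths["population.vcf"]
    )
    pheno = pd.read_csv(paths["phenotypes.tsv"], sep="\t")
    pheno_map = dict(zip(pheno["individual"], pheno["group"]))
    phenotypes = [pheno_map[s] for s in samples]
    sites = fst_mod.site_fst_scan(genotypes, phenotypes, positions)
    pio.write_tsv(sites, p("fst_sites.tsv"))
    wins = fst_mod.windowed_fst(
        sites, sim.pop_chrom_length, config.fst_window, config.fst_min_sites
    )
    pio.write_tsv(wins, p("fst_windows.tsv"))
    hotspots = fst_mod.find_hotspots(wins, threshold=config.fst_threshold)
    hot_rows = []
    for h in hotspots:
        in_region = (positions >= h.start) & (positions < h.end)
        labels, conc = fst_mod.hotspot_haplogroups(
            genotypes[:, in_region], phenotypes
        )
        hot_rows.append(
            {
                "chrom": chrom,
                "start": h.start,
                "end": h.end,
                "mean_fst": h.mean_fst,
                "concordance": conc,
            }
        )
    pio.write_tsv(pd.DataFrame(hot_rows), p("hotspots.tsv"))

    log.info("clonality IBS")
    clones = simulate_clones(sim, truth)
    ibs = fst_mod.ibs_matrix(clones.genotypes)
    pd.DataFrame(ibs, index=clones.individuals, columns=clones.individuals).to_csv(
        p("ibs_matrix.tsv"), sep="\t"
    )

    manifest = {
        "seed": sim.seed,
        "outputs": file_checksums(paths),
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
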