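"""Generator correctness: determinism, planted structure, calibration."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from polyorigin import io as pio
from polyorigin.simulate import (
    FAR,
    NEAR1,
    NEAR2,
    RECOMBINANT,
    FstBlock,
    GroupPlan,
    SimConfig,
    TruthSet,
    clone_design,
    default_karyotype_plan,
    simulate_clones,
    simulate_depth,
    simulate_expression,
    simulate_offspring,
    simulate_parents,
    simulate_populations,
)


# ---------------------------------------------------------------------------
# configuration invariants


@pytest.mark.parametrize(
    "kwargs",
    [
        {"divergence_far": 0.001, "divergence_near": 0.003},  # hierarchy broken
        {"divergence_near": -0.1},
        {"triad_props": (0.5, 0.5, 0.5)},
        {"depth_mean": 0.0},
        {"group_length": 0},
        {"n_case": 1},
        {"fst_block": FstBlock(start=400_000, end=600_000)},
    ],
)
def test_invalid_configs_rejected(kwargs):
    with pytest.raises(ValueError):
        SimConfig(seed=0, **kwargs)


def test_breakpoint_outside_span_rejected():
    plan = {"01A": GroupPlan(3, breakpoints=(70_000,))}
    with pytest.raises(ValueError, match="01A"):
        SimConfig(seed=0, n_groups=1, group_length=60_000, karyotype_plan=plan)


# ---------------------------------------------------------------------------
# parents


def test_parents_determinism_byte_identical(tmp_path, small_cfg):
    pair = []
    for sub in ("a", "b"):
        parents = simulate_parents(small_cfg)
        d = tmp_path / sub
        d.mkdir()
        pio.write_fasta(
            d / "far.fasta",
            ((g, parents.groups[g][FAR]) for g in parents.groups),
        )
        pio.write_parent_vcf(parents, d / "parents.vcf")
        pair.append(d)
    assert (pair[0] / "far.fasta").read_bytes() == (pair[1] / "far.fasta").read_bytes()
    assert (pair[0] / "parents.vcf").read_bytes() == (pair[1] / "parents.vcf").read_bytes()


def test_zero_near_divergence_gives_identical_close_parents():
    cfg = SimConfig(seed=3, n_groups=2, group_length=20_000, divergence_near=0.0)
    parents = simulate_parents(cfg)
    for gid in parents.groups:
        assert np.array_equal(parents.groups[gid][NEAR1], parents.groups[gid][NEAR2])
        assert parents.diagnostic_truth(gid).empty


def test_differential_site_count_matches_binomial_expectation(small_cfg, small_sim):
    """Realized near1/near2 differences ~ Binomial(L, divergence_near)."""
    parents, _, _ = small_sim
    L = small_cfg.group_length
    p = small_cfg.divergence_near
    total_n = L * small_cfg.n_groups
    count = sum(
        int((parents.groups[g][NEAR1] != parents.groups[g][NEAR2]).sum())
        for g in parents.groups
    )
    sigma = np.sqrt(total_n * p * (1 - p))
    assert abs(count - total_n * p) <= 3 * sigma


def test_variant_table_matches_sequences(small_sim):
    parents, _, _ = small_sim
    v = parents.variants
    for gid in parents.groups:
        g = parents.groups[gid]
        expected = int(((g[FAR] != g[NEAR1]) | (g[NEAR2] != g[NEAR1])).sum())
        assert (v["chrom"] == gid).sum() == expected


# ---------------------------------------------------------------------------
# offspring


def test_offspring_copy_numbers_follow_plan():
    plan = {
        "01A": GroupPlan(1),
        "01B": GroupPlan(4, copy_number=4),
        "02A": GroupPlan(4, copy_number=2),
    }
    cfg = SimConfig(seed=5, n_groups=3, group_length=20_000, karyotype_plan=plan)
    parents = simulate_parents(cfg)
    offspring, truth = simulate_offspring(parents, cfg)
    by_group = {}
    for h in offspring:
        by_group.setdefault(h.group_id, []).append(truth.origins[h.hap_id])
    assert sorted(by_group["01A"]) == [FAR, NEAR1, NEAR2]
    assert len(by_group["01B"]) == 4
    assert len(by_group["02A"]) == 2
    # truth completeness: one record per emitted haplotype
    assert set(truth.origins) == {h.hap_id for h in offspring}
    assert set(truth.segments) == set(truth.origins)


def test_recombinant_halves_match_the_right_parent():
    """Direct sequence comparison at diagnostic sites on either side of a
    mid-span breakpoint."""
    bp = 10_000
    plan = {"01A": GroupPlan(3, breakpoints=(bp,))}
    cfg = SimConfig(seed=6, n_groups=1, group_length=20_000, karyotype_plan=plan)
    parents = simulate_parents(cfg)
    offspring, truth = simulate_offspring(parents, cfg)
    rec = next(h for h in offspring if truth.origins[h.hap_id] == RECOMBINANT)
    g = parents.groups["01A"]
    diag = parents.diagnostic_truth("01A")["pos"].to_numpy()
    left, right = diag[diag < bp], diag[diag >= bp]
    assert len(left) > 10 and len(right) > 10
    assert np.array_equal(rec.seq[left], g[NEAR1][left])
    assert np.array_equal(rec.seq[right], g[NEAR2][right])
    assert not np.array_equal(rec.seq[right], g[NEAR1][right])


def test_default_plan_structure():
    plan = default_karyotype_plan(25, 500_000)
    cats = [p.category for p in plan.values()]
    assert len(plan) == 25
    assert cats.count(3) >= 3 and cats.count(4) == 2
    assert any(len(p.breakpoints) == 2 for p in plan.values())


# ---------------------------------------------------------------------------
# depth


def test_noiseless_depth_equals_expected_means():
    cfg = SimConfig(
        seed=7, n_groups=1, group_length=20_000, depth_window=2_000, depth_noise=0.0
    )
    parents = simulate_parents(cfg)
    offspring, truth = simulate_offspring(parents, cfg)
    depth = simulate_depth(offspring, truth, cfg)
    far_hap = next(h.hap_id for h in offspring if truth.origins[h.hap_id] == FAR)
    sub = depth[depth["hap_id"] == far_hap]
    m = cfg.depth_mean
    assert np.allclose(sub[sub["sample"] == FAR]["depth"], m)
    assert np.allclose(sub[sub["sample"] == NEAR1]["depth"], cfg.cross_map_floor * m)
    n1_hap = next(h.hap_id for h in offspring if truth.origins[h.hap_id] == NEAR1)
    sub = depth[depth["hap_id"] == n1_hap]
    assert np.allclose(sub[sub["sample"] == NEAR1]["depth"], m)
    assert np.allclose(sub[sub["sample"] == NEAR2]["depth"], cfg.near_cross * m)


def test_noisy_depth_mean_within_three_standard_errors():
    cfg = SimConfig(seed=8, n_groups=2, group_length=500_000, depth_window=2_000)
    parents = simulate_parents(cfg)
    offspring, truth = simulate_offspring(parents, cfg)
    depth = simulate_depth(offspring, truth, cfg)
    far_hap = next(h.hap_id for h in offspring if truth.origins[h.hap_id] == FAR)
    vals = depth[(depth["hap_id"] == far_hap) & (depth["sample"] == FAR)]["depth"]
    assert len(vals) >= 100
    m = cfg.depth_mean
    se = np.sqrt((m + cfg.depth_noise * m * m) / len(vals))
    assert abs(vals.mean() - m) <= 3 * se


def test_recombinant_depth_switches_for_near_samples_only():
    bp = 10_000
    plan = {"01A": GroupPlan(3, breakpoints=(bp,))}
    cfg = SimConfig(
        seed=9,
        n_groups=1,
        group_length=20_000,
        depth_window=2_000,
        depth_noise=0.0,
        karyotype_plan=plan,
    )
    parents = simulate_parents(cfg)
    offspring, truth = simulate_offspring(parents, cfg)
    depth = simulate_depth(offspring, truth, cfg)
    rec = next(h.hap_id for h in offspring if truth.origins[h.hap_id] == RECOMBINANT)
    sub = depth[depth["hap_id"] == rec]
    n1 = sub[sub["sample"] == NEAR1].set_index("start")["depth"]
    assert n1.loc[0] == cfg.depth_mean  # NEAR1 side
    assert n1.loc[18_000] == cfg.near_cross * cfg.depth_mean  # NEAR2 side
    far = sub[sub["sample"] == FAR]["depth"]
    assert np.allclose(far, cfg.cross_map_floor * cfg.depth_mean)


# ---------------------------------------------------------------------------
# expression, populations, clones


def test_expression_emits_only_expressed_genes_and_recovers_proportions():
    cfg = SimConfig(seed=10, n_genes=5_000)
    truth = TruthSet()
    expr = simulate_expression(cfg, truth)
    assert (expr["e_far"] + expr["e_other"] >= cfg.expression_floor).all()
    # planted mixture recovered within binomial 99% CI
    counts = pd.Series(list(truth.triad_categories.values())).value_counts()
    n = cfg.n_genes
    for cat, p in zip(("BALANCED", "FAR_DOMINANT", "OTHER_DOMINANT"), cfg.triad_props):
        half = 2.576 * np.sqrt(p * (1 - p) / n)
        assert abs(counts.get(cat, 0) / n - p) <= half


def test_degenerate_mixture_is_all_balanced():
    cfg = SimConfig(seed=12, n_genes=200, triad_props=(1.0, 0.0, 0.0))
    truth = TruthSet()
    simulate_expression(cfg, truth)
    assert set(truth.triad_categories.values()) == {"BALANCED"}


def test_population_block_plants_fixed_difference():
    cfg = SimConfig(seed=13)
    truth = TruthSet()
    pop = simulate_populations(cfg, truth)
    blk = cfg.fst_block
    in_block = (pop.positions >= blk.start) & (pop.positions < blk.end)
    case = np.array([p == "case" for p in pop.phenotypes])
    assert np.all(pop.genotypes[np.ix_(case, np.flatnonzero(in_block))] == 2)
    assert np.all(pop.genotypes[np.ix_(~case, np.flatnonzero(in_block))] == 0)
    assert truth.hotspot == (cfg.pop_chrom, blk.start, blk.end)
    # background frequencies are shared: both groups polymorphic overall
    assert pop.genotypes[:, ~in_block].std() > 0


def test_clone_design_solves_identity_targets():
    d, q = clone_design(0.982, 0.730)
    p_same = (1 - d) ** 2 + d * d / 2
    p_diff = d * (1 - d) + d * d / 4
    assert p_same == pytest.approx(0.982, abs=1e-12)
    assert q * p_same + (1 - q) * p_diff == pytest.approx(0.730, abs=1e-12)


def test_clone_genotypes_have_planted_identity(small_cfg):
    clones = simulate_clones(small_cfg)
    g = clones.genotypes
    ids = np.asarray(clones.clone_of)
    same = ids[:, None] == ids[None, :]
    ibs = np.array(
        [[(g[i] == g[j]).mean() for j in range(len(g))] for i in range(len(g))]
    )
    off = ~np.eye(len(g), dtype=bool)
    tol_w = 3 * np.sqrt(0.982 * 0.018 / g.shape[1])
    tol_b = 3 * np.sqrt(0.730 * 0.270 / g.shape[1])
    assert abs(ibs[same & off].mean() - 0.982) <= tol_w
    assert abs(ibs[~same].mean() - 0.730) <= tol_b
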