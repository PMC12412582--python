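"""Simulate a three-parent amphitriploid genome with planted truth.

Builds the default desk-scale genome: 25 homologous groups of 500 kb,
one distant parent and two close parents, offspring haplotypes drawn
from the four karyotype categories (including recombinants and
aneuploid groups).
"""

from collections import Counter

from polyorigin.simulate import (
    SimConfig,
    simulate_offspring,
    simulate_parents,
)

cfg = SimConfig(seed=1)
parents = simulate_parents(cfg)
offspring, truth = simulate_offspring(parents, cfg)

n_diag = sum(len(parents.diagnostic_truth(g)) for g in parents.groups)
print(f"groups: {cfg.n_groups} x {cfg.group_length // 1000} kb")
print(f"differential homozygous sites between the close parents: {n_diag}")
print(f"offspring haplotypes: {len(offspring)}")
print("planted karyotype categories:", dict(sorted(Counter(truth.categories.values()).items())))
n_bp = sum(len(b) for b in truth.breakpoints.values())
print(f"planted recombination breakpoints: {n_bp}")
# A typical group carries ~1500 diagnostic sites (0.3% divergence over
# 500 kb); category counts echo the structure of a real amphitriploid
# karyogram: mostly trios with one haplotype per parent, some groups with
# a doubled close parent, a few recombinants, two aneuploids.
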