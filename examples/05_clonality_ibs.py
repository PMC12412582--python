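"""Identity-by-state clonality assessment.

Simulates three clonal lineages (10 individuals each) with planted
within-clone identity 98.2% and between-clone identity 73.0%, then
recovers both from the pairwise IBS matrix.
"""

import numpy as np

from polyorigin.fst import ibs_matrix
from polyorigin.simulate import SimConfig, simulate_clones

cfg = SimConfig(seed=1)
clones = simulate_clones(cfg)
m = ibs_matrix(clones.genotypes)

ids = np.asarray(clones.clone_of)
same = ids[:, None] == ids[None, :]
off = ~np.eye(len(m), dtype=bool)
print(f"individuals: {len(m)} ({cfg.n_clones} clones x {cfg.n_per_clone})")
print(f"mean within-clone identity:  {100 * m[same & off].mean():.2f}% (planted 98.20%)")
print(f"mean between-clone identity: {100 * m[~same].mean():.2f}% (planted 73.00%)")
# High within-clone identity with a clear gap to between-clone identity
# is the IBS signature of distinct gynogenetic clones.
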