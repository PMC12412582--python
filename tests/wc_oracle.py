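"""Independent Weir–Cockerham (1984) oracle used by the test suite.

Transcribed as a numeric nested ANOVA on per-allele indicator variables
(alleles within individuals within populations), a different route to the
same variance components than the closed-form frequency/heterozygosity
expressions in the package.
"""

import numpy as np


def anova_weir_cockerham(g1, g2):
    """Return (a, b, c) components for two diploid populations.

    ``g1``/``g2`` are alt-allele dosage vectors (0/1/2), no missing data.
    """
    pops = [np.asarray(g1), np.asarray(g2)]
    x = []
    for g in pops:
        arr = np.zeros((len(g), 2))
        arr[g == 1, 0] = 1
        arr[g == 2, :] = 1
        x.append(arr)
    r = 2
    n = [len(g) for g in pops]
    s1 = sum(n)
    ind_means = [a.mean(axis=1) for a in x]
    pop_means = [a.mean() for a in x]
    grand = sum(a.sum() for a in x) / (2 * s1)
    ssg = sum(((a - m[:, None]) ** 2).sum() for a, m in zip(x, ind_means))
    ssi = sum((2 * (m - pm) ** 2).sum() for m, pm in zip(ind_means, pop_means))
    ssp = sum(2 * ni * (pm - grand) ** 2 for ni, pm in zip(n, pop_means))
    msg = ssg / s1
    msi = ssi / (s1 - r)
    msp = ssp / (r - 1)
    nc = (s1 - sum(ni * ni for ni in n) / s1) / (r - 1)
    c = msg
    b = 0.5 * (msi - msg)
    a = (msp - msi) / (2 * nc)
    return a, b, c


def polymorphic(g1, g2):
    p = (np.sum(g1) + np.sum(g2)) / (2 * (len(g1) + len(g2)))
    return 0 < p < 1
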