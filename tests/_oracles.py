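"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation paths they check.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def gene_drop_relationship(sire, dam, n_reps, seed):
    """Monte-Carlo numerator relationships by single-locus gene dropping.

    Founders receive unique allele labels; each rep drops alleles through the
    pedigree without recombination.  a(i,j) is estimated as twice the average
    kinship (probability a random allele from i is identical by descent to a
    random allele from j, including i == j).  Returns (mean, se) matrices.
    """
    np.random.seed(seed)
    n = sire.shape[0]
    asum = np.zeros((n, n))
    asum2 = np.zeros((n, n))
    h0 = np.empty(n, dtype=np.int64)
    h1 = np.empty(n, dtype=np.int64)
    for _ in range(n_reps):
        lab = 0
        for i in range(n):
            if sire[i] < 0 and dam[i] < 0:
                h0[i] = lab
                h1[i] = lab + 1
                lab += 2
            else:
                s, d = sire[i], dam[i]
                h0[i] = h0[s] if np.random.random() < 0.5 else h1[s]
                h1[i] = h0[d] if np.random.random() < 0.5 else h1[d]
        for i in range(n):
            for j in range(i, n):
                share = 0.0
                if h0[i] == h0[j]:
                    share += 1.0
                if h0[i] == h1[j]:
                    share += 1.0
                if h1[i] == h0[j]:
                    share += 1.0
                if h1[i] == h1[j]:
                    share += 1.0
                v = share / 2.0  # 2 * (share / 4)
                asum[i, j] += v
                asum2[i, j] += v * v
    mean = np.zeros((n, n))
    se = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            mu = asum[i, j] / n_reps
            var = asum2[i, j] / n_reps - mu * mu
            s_ = np.sqrt(max(var, 0.0) / n_reps)
            mean[i, j] = mu
            mean[j, i] = mu
            se[i, j] = s_
            se[j, i] = s_
    return mean, se


def random_pedigree(n_founders, n_total, seed):
    """Random acyclic pedigree: each non-founder picks two earlier parents."""
    rng = np.random.default_rng(seed)
    sire = np.full(n_total, -1, dtype=np.int64)
    dam = np.full(n_total, -1, dtype=np.int64)
    for i in range(n_founders, n_total):
        s, d = rng.choice(i, size=2, replace=True)
        sire[i], dam[i] = s, d
    return sire, dam
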