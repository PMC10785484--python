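"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by direct enumeration or a from-scratch
formula, sharing no code with the implementation paths it checks.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np


def ls_emission(theta: float) -> np.ndarray:
    """P(genotype g | copied alleles (x, y)) by direct expansion."""
    W = np.empty((2, 2, 3))
    for x in (0, 1):
        for y in (0, 1):
            p1 = theta if x == 0 else 1 - theta
            p2 = theta if y == 0 else 1 - theta
            W[x, y, 0] = (1 - p1) * (1 - p2)
            W[x, y, 1] = p1 * (1 - p2) + (1 - p1) * p2
            W[x, y, 2] = p1 * p2
    return W


def ls_enumerate(gl, alleles, rho, theta):
    """Exhaustive-path state and genotype posteriors of the diploid copying HMM.

    Enumerates every ordered-pair state sequence; feasible for K <= 4, M <= 4.
    Returns (state_marginals (M,K,K), genotype_marginals (M,3), loglik).
    """
    K, M = alleles.shape
    W = ls_emission(theta)
    states = list(itertools.product(range(K), repeat=2))

    def trans(r, s, t):
        return (1 - r) * (s == t) + r / K

    tot = 0.0
    marg = np.zeros((M, K, K))
    gmarg = np.zeros((M, 3))
    for seq in itertools.product(states, repeat=M):
        p = 1.0 / K**2
        for m, (j, k) in enumerate(seq):
            p *= sum(gl[m, g] * W[alleles[j, m], alleles[k, m], g] for g in range(3))
            if m > 0:
                pj, pk = seq[m - 1]
                p *= trans(rho[m - 1], pj, j) * trans(rho[m - 1], pk, k)
        tot += p
        for m, (j, k) in enumerate(seq):
            marg[m, j, k] += p
            den = sum(gl[m, g] * W[alleles[j, m], alleles[k, m], g] for g in range(3))
            for g in range(3):
                gmarg[m, g] += p * gl[m, g] * W[alleles[j, m], alleles[k, m], g] / den
    return marg / tot, gmarg / tot, np.log(tot)


def ls_best_path_prob(gl, alleles, rho, theta, path):
    """Unnormalised probability of one state path (for Viterbi checks)."""
    K, M = alleles.shape
    W = ls_emission(theta)
    p = 1.0 / K**2
    for m in range(M):
        j, k = path[m]
        p *= sum(gl[m, g] * W[alleles[j, m], alleles[k, m], g] for g in range(3))
        if m > 0:
            pj, pk = path[m - 1]
            p *= ((1 - rho[m - 1]) * (pj == j) + rho[m - 1] / K) * (
                (1 - rho[m - 1]) * (pk == k) + rho[m - 1] / K
            )
    return p


def ls_max_path(gl, alleles, rho, theta):
    """Brute-force most probable path; feasible for K <= 3, M <= 4."""
    K, M = alleles.shape
    best, bestp = None, -1.0
    for seq in itertools.product(itertools.product(range(K), repeat=2), repeat=M):
        p = ls_best_path_prob(gl, alleles, rho, theta, seq)
        if p > bestp:
            bestp, best = p, seq
    return best, bestp


def ehh_pairwise(haps, core, outer):
    """EHH by counting haplotype pairs identical over span core..outer."""
    lo, hi = min(core, outer), max(core, outer)
    n = haps.shape[0]
    same = 0
    for i, j in itertools.combinations(range(n), 2):
        if np.array_equal(haps[i, lo : hi + 1], haps[j, lo : hi + 1]):
            same += 1
    return same / comb(n, 2)


def distinct_strings(blocks) -> int:
    """Set-of-strings count over a list of 1-D allele arrays."""
    return len({tuple(b.tolist()) for b in blocks})


def wilcoxon_exact(diff) -> float:
    """Two-sided signed-rank p by enumerating all 2^n sign assignments.

    Zero differences are dropped; ranks of |d| use midranks for ties.  The
    p-value is the fraction of sign assignments whose W+ is at least as
    extreme (two-sided, doubling the smaller tail, capped at 1).
    """
    from scipy.stats import rankdata

    d = np.asarray(diff, float)
    d = d[d != 0]
    n = d.size
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = np.array(
        [ranks[np.array(signs, bool)].sum()
         for signs in itertools.product([0, 1], repeat=n)]
    )
    p_le = np.mean(ws <= w_obs)
    p_ge = np.mean(ws >= w_obs)
    return min(1.0, 2.0 * min(p_le, p_ge))


def pearson_r2(x, y) -> float:
    """Squared Pearson correlation from raw sums (no numpy.corrcoef)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    sxy = (x * y).sum() - x.sum() * y.sum() / n
    sxx = (x * x).sum() - x.sum() ** 2 / n
    syy = (y * y).sum() - y.sum() ** 2 / n
    return sxy * sxy / (sxx * syy)
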