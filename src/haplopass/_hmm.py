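"""Diploid haplotype-copying HMM internals (numba-compiled).

The hidden state at each site is an ordered pair (j, k) of reference-panel
haplotypes being copied.  Transitions factorise per haplotype into the
standard copying kernel

    t(j -> j') = (1 - rho) * [j == j'] + rho / K,

which makes the K^2-state forward, backward, and Viterbi recursions
computable in O(K^2) per site via row/column sums (or maxima) instead of
O(K^4).  Emissions combine the cell's genotype-likelihood triplet with the
probability of each genotype given the copied allele pair under a symmetric
per-site copying error ``theta``; because alleles are binary, each site has
only four distinct emission values.  All recursions are scaled, so no
underflow occurs at thousands of sites.
"""

from __future__ import annotations

import numpy as np
from numba import njit


def emission_lookup(theta: float) -> np.ndarray:
    """W[x, y, g]: P(genotype g | copied alleles (x, y), copy error theta)."""
    p = np.array([theta, 1.0 - theta])  # P(allele is alt | copied allele x)
    W = np.empty((2, 2, 3))
    for x in (0, 1):
        for y in (0, 1):
            p1, p2 = p[x], p[y]
            W[x, y, 0] = (1 - p1) * (1 - p2)
            W[x, y, 1] = p1 * (1 - p2) + (1 - p1) * p2
            W[x, y, 2] = p1 * p2
    return W


@njit(cache=True)
def _site_emissions(gl: np.ndarray, W: np.ndarray) -> np.ndarray:
    """E[m, x, y]: emission value per site for each copied-allele combo."""
    M = gl.shape[0]
    E = np.empty((M, 2, 2))
    for m in range(M):
        for x in range(2):
            for y in range(2):
                E[m, x, y] = (
                    gl[m, 0] * W[x, y, 0]
                    + gl[m, 1] * W[x, y, 1]
                    + gl[m, 2] * W[x, y, 2]
                )
    return E


@njit(cache=True)
def _fb_single(gl, alleles, rho, theta, W, want_post):
    """Scaled forward-backward for one individual.

    Returns (gp (M,3), loglik, post (M,K,K) or (1,1,1) placeholder).
    """
    K, M = alleles.shape
    E = _site_emissions(gl, W)
    F = np.empty((M, K, K))
    loglik = 0.0

    s = 0.0
    for j in range(K):
        for k in range(K):
            v = E[0, alleles[j, 0], alleles[k, 0]] / (K * K)
            F[0, j, k] = v
            s += v
    for j in range(K):
        for k in range(K):
            F[0, j, k] /= s
    loglik += np.log(s)

    rowsum = np.empty(K)
    colsum = np.empty(K)
    for m in range(1, M):
        r = rho[m - 1]
        stay = 1.0 - r
        sw = r / K
        for j in range(K):
            rowsum[j] = 0.0
            colsum[j] = 0.0
        for j in range(K):
            for k in range(K):
                rowsum[j] += F[m - 1, j, k]
                colsum[k] += F[m - 1, j, k]
        s = 0.0
        for j in range(K):
            for k in range(K):
                pred = (
                    stay * stay * F[m - 1, j, k]
                    + stay * sw * (rowsum[j] + colsum[k])
                    + sw * sw
                )
                v = pred * E[m, alleles[j, m], alleles[k, m]]
                F[m, j, k] = v
                s += v
        for j in range(K):
            for k in range(K):
                F[m, j, k] /= s
        loglik += np.log(s)

    gp = np.zeros((M, 3))
    if want_post:
        post = np.empty((M, K, K))
    else:
        post = np.empty((1, 1, 1))
    b = np.ones((K, K))
    tmp = np.empty((K, K))
    mass = np.empty((2, 2))
    for m in range(M - 1, -1, -1):
        tot = 0.0
        mass[:] = 0.0
        for j in range(K):
            for k in range(K):
                p = F[m, j, k] * b[j, k]
                mass[alleles[j, m], alleles[k, m]] += p
                tot += p
        if want_post:
            for j in range(K):
                for k in range(K):
                    post[m, j, k] = F[m, j, k] * b[j, k] / tot
        # re-split each combo's mass over genotypes given the site GL
        for x in range(2):
            for y in range(2):
                den = (
                    gl[m, 0] * W[x, y, 0]
                    + gl[m, 1] * W[x, y, 1]
                    + gl[m, 2] * W[x, y, 2]
                )
                if den < 1e-300:
                    den = 1e-300
                w = mass[x, y] / tot
                for g in range(3):
                    gp[m, g] += w * gl[m, g] * W[x, y, g] / den
        if m > 0:
            r = rho[m - 1]
            stay = 1.0 - r
            sw = r / K
            for j in range(K):
                rowsum[j] = 0.0
                colsum[j] = 0.0
            ttot = 0.0
            for j in range(K):
                for k in range(K):
                    t = b[j, k] * E[m, alleles[j, m], alleles[k, m]]
                    tmp[j, k] = t
                    rowsum[j] += t
                    colsum[k] += t
                    ttot += t
            bmax = 0.0
            for j in range(K):
                for k in range(K):
                    v = (
                        stay * stay * tmp[j, k]
                        + stay * sw * (rowsum[j] + colsum[k])
                        + sw * sw * ttot
                    )
                    b[j, k] = v
                    if v > bmax:
                        bmax = v
            for j in range(K):
                for k in range(K):
                    b[j, k] /= bmax
    for m in range(M):
        gs = gp[m, 0] + gp[m, 1] + gp[m, 2]
        for g in range(3):
            gp[m, g] /= gs
    return gp, loglik, post


@njit(cache=True)
def _viterbi_single(gl, alleles, rho, theta, W):
    """Most probable ordered-pair copying path for one individual (M, 2).

    Ties resolve to the lowest state index, so the path is deterministic.
    """
    K, M = alleles.shape
    E = _site_emissions(gl, W)
    case = np.empty((M, K, K), dtype=np.uint8)
    rowarg = np.empty((M, K), dtype=np.int32)
    colarg = np.empty((M, K), dtype=np.int32)
    globj = np.empty(M, dtype=np.int32)
    globk = np.empty(M, dtype=np.int32)

    v = np.empty((K, K))
    vmax = 0.0
    for j in range(K):
        for k in range(K):
            v[j, k] = E[0, alleles[j, 0], alleles[k, 0]]
            if v[j, k] > vmax:
                vmax = v[j, k]
    for j in range(K):
        for k in range(K):
            v[j, k] /= vmax

    rmax = np.empty(K)
    cmax = np.empty(K)
    nv = np.empty((K, K))
    for m in range(1, M):
        r = rho[m - 1]
        stay = 1.0 - r + r / K  # keep the copied source
        sw = r / K              # switch source
        gbest = -1.0
        for j in range(K):
            rmax[j] = -1.0
            cmax[j] = -1.0
        for j in range(K):
            for k in range(K):
                val = v[j, k]
                if val > rmax[j]:
                    rmax[j] = val
                    rowarg[m, j] = k
                if val > cmax[k]:
                    cmax[k] = val
                    colarg[m, k] = j
                if val > gbest:
                    gbest = val
                    globj[m] = j
                    globk[m] = k
        vmax = 0.0
        for j in range(K):
            for k in range(K):
                c0 = stay * stay * v[j, k]
                c1 = stay * sw * rmax[j]
                c2 = sw * stay * cmax[k]
                c3 = sw * sw * gbest
                best = c0
                bc = 0
                if c1 > best:
                    best = c1
                    bc = 1
                if c2 > best:
                    best = c2
                    bc = 2
                if c3 > best:
                    best = c3
                    bc = 3
                case[m, j, k] = bc
                val = best * E[m, alleles[j, m], alleles[k, m]]
                nv[j, k] = val
                if val > vmax:
                    vmax = val
        for j in range(K):
            for k in range(K):
                v[j, k] = nv[j, k] / vmax

    path = np.empty((M, 2), dtype=np.int32)
    bj, bk, best = 0, 0, -1.0
    for j in range(K):
        for k in range(K):
            if v[j, k] > best:
                best = v[j, k]
                bj, bk = j, k
    path[M - 1, 0] = bj
    path[M - 1, 1] = bk
    for m in range(M - 1, 0, -1):
        c = case[m, bj, bk]
        if c == 1:
            bk = rowarg[m, bj]
        elif c == 2:
            bj = colarg[m, bk]
        elif c == 3:
            bj = globj[m]
            bk = globk[m]
        path[m - 1, 0] = bj
        path[m - 1, 1] = bk
    return path


@njit(cache=True)
def _sample_single(gl, alleles, rho, theta, W, seed):
    """Draw one ordered-pair copying path from its posterior (FFBS)."""
    np.random.seed(seed)
    K, M = alleles.shape
    E = _site_emissions(gl, W)
    F = np.empty((M, K, K))
    s = 0.0
    for j in range(K):
        for k in range(K):
            v = E[0, alleles[j, 0], alleles[k, 0]] / (K * K)
            F[0, j, k] = v
            s += v
    for j in range(K):
        for k in range(K):
            F[0, j, k] /= s
    rowsum = np.empty(K)
    colsum = np.empty(K)
    for m in range(1, M):
        r = rho[m - 1]
        stay = 1.0 - r
        sw = r / K
        for j in range(K):
            rowsum[j] = 0.0
            colsum[j] = 0.0
        for j in range(K):
            for k in range(K):
                rowsum[j] += F[m - 1, j, k]
                colsum[k] += F[m - 1, j, k]
        s = 0.0
        for j in range(K):
            for k in range(K):
                pred = (
                    stay * stay * F[m - 1, j, k]
                    + stay * sw * (rowsum[j] + colsum[k])
                    + sw * sw
                )
                v = pred * E[m, alleles[j, m], alleles[k, m]]
                F[m, j, k] = v
                s += v
        for j in range(K):
            for k in range(K):
                F[m, j, k] /= s

    path = np.empty((M, 2), dtype=np.int32)
    # sample the final state from the filtered distribution
    u = np.random.random()
    acc = 0.0
    bj, bk = K - 1, K - 1
    done = False
    for j in range(K):
        if done:
            break
        for k in range(K):
            acc += F[M - 1, j, k]
            if acc >= u:
                bj, bk = j, k
                done = True
                break
    path[M - 1, 0] = bj
    path[M - 1, 1] = bk
    w = np.empty((K, K))
    for m in range(M - 2, -1, -1):
        r = rho[m]
        stay = 1.0 - r
        sw = r / K
        nj = path[m + 1, 0]
        nk = path[m + 1, 1]
        tot = 0.0
        for j in range(K):
            tj = stay + sw if j == nj else sw
            for k in range(K):
                tk = stay + sw if k == nk else sw
                v = F[m, j, k] * tj * tk
                w[j, k] = v
                tot += v
        u = np.random.random() * tot
        acc = 0.0
        bj, bk = K - 1, K - 1
        done = False
        for j in range(K):
            if done:
                break
            for k in range(K):
                acc += w[j, k]
                if acc >= u:
                    bj, bk = j, k
                    done = True
                    break
        path[m, 0] = bj
        path[m, 1] = bk
    return path


def sample_paths(
    gl: np.ndarray,
    alleles: np.ndarray,
    rho: np.ndarray,
    theta: float,
    seed: int,
) -> np.ndarray:
    """Posterior-sampled copying paths per individual, (B, M, 2), seeded."""
    gl = np.ascontiguousarray(gl, dtype=np.float64)
    alleles = np.ascontiguousarray(alleles, dtype=np.int8)
    rho = np.ascontiguousarray(rho, dtype=np.float64)
    B, M, _ = gl.shape
    W = emission_lookup(theta)
    path = np.empty((B, M, 2), dtype=np.int32)
    for i in range(B):
        path[i] = _sample_single(gl[i], alleles, rho, theta, W, (seed + i) % 2**31)
    return path


def forward_backward(
    gl: np.ndarray,
    alleles: np.ndarray,
    rho: np.ndarray,
    theta: float,
    return_state_posteriors: bool = False,
):
    """Scaled forward-backward over ordered-pair copying states.

    Parameters
    ----------
    gl : (B, M, 3) normalised genotype-likelihood triplets for B individuals.
    alleles : (K, M) panel haplotype alleles in {0, 1}.
    rho : (M-1,) per-gap switch probability of the copying process.
    theta : per-site copying-error probability.

    Returns
    -------
    gp : (B, M, 3) posterior genotype triplets.
    loglik : (B,) data log-likelihood per individual.
    post : (B, M, K, K) state posteriors, only when requested (small problems).
    """
    gl = np.ascontiguousarray(gl, dtype=np.float64)
    alleles = np.ascontiguousarray(alleles, dtype=np.int8)
    rho = np.ascontiguousarray(rho, dtype=np.float64)
    B, M, _ = gl.shape
    K = alleles.shape[0]
    W = emission_lookup(theta)
    gp = np.empty((B, M, 3))
    loglik = np.empty(B)
    posts = np.empty((B, M, K, K)) if return_state_posteriors else None
    for i in range(B):
        g, ll, p = _fb_single(gl[i], alleles, rho, theta, W, return_state_posteriors)
        gp[i] = g
        loglik[i] = ll
        if return_state_posteriors:
            posts[i] = p
    if return_state_posteriors:
        return gp, loglik, posts
    return gp, loglik


def viterbi(
    gl: np.ndarray,
    alleles: np.ndarray,
    rho: np.ndarray,
    theta: float,
) -> np.ndarray:
    """Most probable ordered-pair copying path per individual, (B, M, 2)."""
    gl = np.ascontiguousarray(gl, dtype=np.float64)
    alleles = np.ascontiguousarray(alleles, dtype=np.int8)
    rho = np.ascontiguousarray(rho, dtype=np.float64)
    B, M, _ = gl.shape
    W = emission_lookup(theta)
    path = np.empty((B, M, 2), dtype=np.int32)
    for i in range(B):
        path[i] = _viterbi_single(gl[i], alleles, rho, theta, W)
    return path
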