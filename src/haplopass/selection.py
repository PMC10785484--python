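"""Cross-population extended haplotype homozygosity (XP-EHH).

EHH at extension distance d from a core site is the probability that two
randomly drawn haplotypes are identical over all spanned sites,
``sum_h C(n_h, 2) / C(n, 2)`` over the partition of haplotypes into
identity groups.  iHH integrates EHH against physical distance (trapezoid
rule) outward on each side until the curve falls below a cutoff — linearly
interpolated to the exact crossing — or hits the chromosome end.  The
cross-population statistic at a core is ``ln(iHH_A / iHH_B)``, standardised
genome-wide to Z-scores: extended homozygosity (haplotype fixation) in
population B drives the score negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "XPEHHResult",
    "ehh_curve",
    "ihh",
    "ihh_site",
    "xpehh_scan",
    "standardize_scores",
    "significant_z",
]


@dataclass
class XPEHHResult:
    """Per-core-site XP-EHH statistics over a shared site list."""

    positions: np.ndarray
    ihh_a: np.ndarray    # NaN where undefined
    ihh_b: np.ndarray
    raw: np.ndarray      # ln(iHH_A / iHH_B)
    z: np.ndarray        # standardised over included sites
    included: np.ndarray  # bool: MAF pass and both iHH defined


def ehh_curve(
    haps: np.ndarray,
    core: int,
    direction: str = "right",
    ehh_cutoff: float = 0.05,
    max_extension_sites: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """EHH decay curve outward from a core site, as site offsets and values.

    Returns ``(indices, ehh)`` where ``indices[t]`` is the outermost site
    index spanned at step ``t`` and ``ehh[t]`` the haplotype homozygosity
    over sites ``core..indices[t]`` inclusive (the core allele is part of
    every span).  ``indices[0] == core`` carries the zero-site-span
    convention EHH = 1 at distance 0.  The curve stops after the first value
    below ``ehh_cutoff``, at the chromosome end, or after
    ``max_extension_sites`` extension steps.

    Identity groups are refined incrementally (a group splits only when the
    new site is polymorphic within it), so long homozygous stretches cost
    almost nothing per step.
    """
    haps = np.asarray(haps)
    n, M = haps.shape
    if n < 2:
        raise ValueError("need at least two haplotypes")
    if direction not in ("left", "right"):
        raise ValueError("direction must be 'left' or 'right'")
    step = 1 if direction == "right" else -1
    pairs_total = n * (n - 1) // 2
    # partition by core allele; the first recorded point extends one site out
    col = haps[:, core]
    groups = [np.flatnonzero(col == 0), np.flatnonzero(col == 1)]
    groups = [g for g in groups if g.size >= 2]
    pair_sum = sum(g.size * (g.size - 1) // 2 for g in groups)
    idx = [core]
    vals = [1.0]
    m = core
    steps = 0
    while True:
        nxt = m + step
        if nxt < 0 or nxt >= M:
            break
        if max_extension_sites is not None and steps >= max_extension_sites:
            break
        col = haps[:, nxt]
        new_groups = []
        for g in groups:
            a = col[g]
            ones = int(a.sum())
            if ones == 0 or ones == g.size:
                new_groups.append(g)
                continue
            pair_sum -= g.size * (g.size - 1) // 2
            for sub in (g[a == 0], g[a == 1]):
                if sub.size >= 2:
                    new_groups.append(sub)
                    pair_sum += sub.size * (sub.size - 1) // 2
        groups = new_groups
        ehh = pair_sum / pairs_total
        idx.append(nxt)
        vals.append(ehh)
        m = nxt
        steps += 1
        if ehh < ehh_cutoff:
            break
    return np.array(idx), np.array(vals)


def ihh(
    distances: np.ndarray,
    ehh: np.ndarray,
    ehh_cutoff: float = 0.05,
    interpolate: bool = True,
) -> float:
    """Trapezoidal integral of one EHH decay curve against distance (bp).

    When the final value lies below the cutoff, integration stops at the
    linearly interpolated crossing point (or at the last point at/above the
    cutoff when ``interpolate`` is off).
    """
    d = np.abs(np.asarray(distances, float))
    e = np.asarray(ehh, float)
    if d.size == 0:
        raise ValueError("empty EHH curve")
    if d.size == 1:
        return 0.0
    if e[-1] < ehh_cutoff:
        if interpolate and e[-2] > e[-1]:
            frac = (e[-2] - ehh_cutoff) / (e[-2] - e[-1])
            d_cross = d[-2] + frac * (d[-1] - d[-2])
            d = np.concatenate([d[:-1], [d_cross]])
            e = np.concatenate([e[:-1], [ehh_cutoff]])
        else:
            d, e = d[:-1], e[:-1]
    if d.size < 2:
        return 0.0
    return float(np.trapezoid(e, d))


def ihh_site(
    haps: np.ndarray,
    positions: np.ndarray,
    core: int,
    ehh_cutoff: float = 0.05,
    interpolate: bool = True,
    max_extension_sites: int | None = None,
) -> tuple[float, bool]:
    """Two-sided iHH at a core site; (value, edge_truncated_flag).

    A side that hits the chromosome end (or the extension cap) before
    decaying to the cutoff contributes its one-sided integral and raises the
    flag; with no extension possible on either side the value is NaN.
    """
    total = 0.0
    edge = False
    any_curve = False
    for direction in ("left", "right"):
        idx, vals = ehh_curve(haps, core, direction, ehh_cutoff, max_extension_sites)
        if idx.size < 2:
            continue
        any_curve = True
        if vals[-1] >= ehh_cutoff:
            edge = True
        total += ihh(positions[idx] - positions[core], vals, ehh_cutoff, interpolate)
    if not any_curve:
        return float("nan"), False
    return total, edge


def xpehh_scan(
    hapsA: np.ndarray,
    hapsB: np.ndarray,
    positions: np.ndarray,
    maf_cutoff: float = 0.05,
    ehh_cutoff: float = 0.05,
    interpolate: bool = True,
    max_extension_sites: int | None = None,
) -> XPEHHResult:
    """XP-EHH scan with cores at every site passing the pooled MAF cutoff.

    ``raw = ln(iHH_A / iHH_B)``; fixation of an extended haplotype in
    population B inflates iHH_B and drives the score negative.  Scores are
    standardised genome-wide over included sites.
    """
    hapsA = np.asarray(hapsA)
    hapsB = np.asarray(hapsB)
    if hapsA.shape[0] < 2 or hapsB.shape[0] < 2:
        raise ValueError("both populations need at least two haplotypes")
    if hapsA.shape[1] != hapsB.shape[1] or hapsA.shape[1] != len(positions):
        raise ValueError("populations must share the site list")
    M = hapsA.shape[1]
    pooled = np.vstack([hapsA, hapsB])
    af = pooled.mean(axis=0)
    maf = np.minimum(af, 1.0 - af)
    ihh_a = np.full(M, np.nan)
    ihh_b = np.full(M, np.nan)
    raw = np.full(M, np.nan)
    included = np.zeros(M, dtype=bool)
    for m in np.flatnonzero(maf >= maf_cutoff):
        va, _ = ihh_site(hapsA, positions, m, ehh_cutoff, interpolate, max_extension_sites)
        vb, _ = ihh_site(hapsB, positions, m, ehh_cutoff, interpolate, max_extension_sites)
        ihh_a[m], ihh_b[m] = va, vb
        if va > 0 and vb > 0:
            raw[m] = np.log(va / vb)
            included[m] = True
    z = np.full(M, np.nan)
    if included.sum() >= 2 and np.std(raw[included]) > 0:
        z[included] = standardize_scores(raw[included])
    return XPEHHResult(
        positions=np.asarray(positions),
        ihh_a=ihh_a,
        ihh_b=ihh_b,
        raw=raw,
        z=z,
        included=included,
    )


def standardize_scores(raw: np.ndarray) -> np.ndarray:
    """Genome-wide Z-standardisation (population sd) of raw scores."""
    raw = np.asarray(raw, float)
    if raw.size < 2:
        raise ValueError("need at least two scores to standardise")
    sd = raw.std()
    if sd == 0:
        raise ValueError("scores have zero variance")
    return (raw - raw.mean()) / sd


def significant_z(
    z: np.ndarray, threshold: float = 4.0
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of significantly positive and negative Z-scores."""
    z = np.asarray(z, float)
    with np.errstate(invalid="ignore"):
        return np.flatnonzero(z > threshold), np.flatnonzero(z < -threshold)
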