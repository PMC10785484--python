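"""Genotype- and haplotype-level agreement metrics against a truth callset.

All rates are computed over "comparable" cells only: non-missing in both
callsets and passing any depth / truth-certainty gates.  Undefined rates
(empty denominators) are flagged with NaN plus a zero count, never silently
reported as 0.  Genotype matrices use {0, 1, 2} with ``MISSING`` (−1) for
no-calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .likelihoods import MISSING

__all__ = [
    "ConcordanceReport",
    "genotype_discordance",
    "aggregate_r2_by_maf",
    "nonref_discordance",
    "dosage_r2",
    "mismatch_by_class",
    "haplotype_discordance",
    "switch_error_rate",
    "DEFAULT_MAF_BINS",
]

DEFAULT_MAF_BINS = (0.0, 0.001, 0.005, 0.01, 0.05, 0.1, 0.2, 0.5)


@dataclass
class ConcordanceReport:
    """Bundle of agreement metrics for one test callset vs truth."""

    maf_bins: np.ndarray
    r2_by_bin: np.ndarray        # NaN where undefined
    n_by_bin: np.ndarray
    dosage_r2: float
    dosage_r2_per_site: np.ndarray
    nrd: float
    class_mismatch: np.ndarray   # rates for truth RR, RA, AA
    class_share: np.ndarray      # share of total mismatches per truth class
    discordance: float
    switch_error: np.ndarray     # per individual, NaN when < 2 het sites
    n_compared: int


def _comparable(test: np.ndarray, truth: np.ndarray) -> np.ndarray:
    return (test != MISSING) & (truth != MISSING)


def genotype_discordance(
    test: np.ndarray,
    truth: np.ndarray,
    depth: np.ndarray | None = None,
    min_depth: int = 0,
    truth_gp: np.ndarray | None = None,
    min_truth_certainty: float = 0.9999,
    windows: np.ndarray | None = None,
    positions: np.ndarray | None = None,
) -> float | tuple[float, np.ndarray]:
    """Fraction of comparable cells where the test genotype differs from truth.

    Cells are comparable when both calls are present, the sequencing depth
    meets ``min_depth``, and — when the truth callset carries GP triplets —
    the truth call's maximum GP reaches ``min_truth_certainty`` (a no-op for
    exact simulated truth).  With ``windows`` (bin edges over ``positions``),
    additionally returns the per-window discordance fractions.
    """
    test = np.asarray(test)
    truth = np.asarray(truth)
    if test.shape != truth.shape:
        raise ValueError("test and truth shapes differ")
    ok = _comparable(test, truth)
    if depth is not None:
        ok &= np.asarray(depth) >= min_depth
    if truth_gp is not None:
        ok &= truth_gp.max(axis=-1) >= min_truth_certainty
    n = int(ok.sum())
    if n == 0:
        raise ValueError("no comparable cells")
    mism = ok & (test != truth)
    overall = mism.sum() / n
    if windows is None:
        return float(overall)
    if positions is None:
        raise ValueError("windows require positions")
    wi = np.digitize(positions, windows) - 1
    nw = len(windows) - 1
    per = np.full(nw, np.nan)
    for w in range(nw):
        cols = wi == w
        d = ok[:, cols].sum()
        if d:
            per[w] = mism[:, cols].sum() / d
    return float(overall), per


def aggregate_r2_by_maf(
    dosage: np.ndarray,
    truth: np.ndarray,
    panel_af: np.ndarray,
    bins: tuple | np.ndarray = DEFAULT_MAF_BINS,
    missing: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pooled squared Pearson correlation of dosage vs truth, per MAF bin.

    Sites are binned by panel MAF ``min(af, 1 - af)``; within a bin all
    (dosage, truth-genotype) cell pairs are pooled.  Bins with fewer than two
    distinct truth values are undefined (NaN, flagged by the count vector).

    Returns ``(bin_edges, r2_by_bin, n_pairs_by_bin)``.
    """
    bins = np.asarray(bins, float)
    if bins[0] > 0.0 or bins[-1] < 0.5:
        raise ValueError("bins must cover (0, 0.5]")
    maf = np.minimum(panel_af, 1.0 - panel_af)
    bi = np.digitize(maf, bins, right=True) - 1
    nb = len(bins) - 1
    r2 = np.full(nb, np.nan)
    n = np.zeros(nb, dtype=np.int64)
    ok = truth != MISSING
    if missing is not None:
        ok &= ~missing
    for b in range(nb):
        cols = bi == b
        if not cols.any():
            continue
        cell_ok = ok[:, cols]
        x = dosage[:, cols][cell_ok]
        y = truth[:, cols][cell_ok].astype(float)
        n[b] = x.size
        if x.size >= 2 and np.unique(y).size >= 2 and np.ptp(x) > 0:
            r = np.corrcoef(x, y)[0, 1]
            r2[b] = r * r
    return bins, r2, n


def dosage_r2(
    dosage: np.ndarray,
    truth: np.ndarray,
    missing: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Pooled and per-site squared Pearson correlation of dosage vs truth.

    The pooled value correlates all comparable cells at once; the per-site
    vector correlates each site's dosages with its truth genotypes across
    individuals (NaN where either is constant).
    """
    dosage = np.asarray(dosage, float)
    truth = np.asarray(truth)
    ok = truth != MISSING
    if missing is not None:
        ok &= ~missing
    x = dosage[ok]
    y = truth[ok].astype(float)
    if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        pooled = np.nan
    else:
        r = np.corrcoef(x, y)[0, 1]
        pooled = float(r * r)
    M = truth.shape[1]
    per_site = np.full(M, np.nan)
    for m in range(M):
        cells = ok[:, m]
        if cells.sum() < 2:
            continue
        xs = dosage[cells, m]
        ys = truth[cells, m].astype(float)
        if np.ptp(xs) == 0 or np.ptp(ys) == 0:
            continue
        r = np.corrcoef(xs, ys)[0, 1]
        per_site[m] = r * r
    return pooled, per_site


def nonref_discordance(test: np.ndarray, truth: np.ndarray) -> float:
    """Non-reference discordance: errors over errors plus non-ref agreements.

    ``NRD = e / (e + m_RA + m_AA)`` with ``e`` the count of discordant
    comparable cells and ``m_RA``, ``m_AA`` the concordant het and hom-alt
    counts; concordant hom-ref cells do not enter the denominator.
    """
    test = np.asarray(test)
    truth = np.asarray(truth)
    if test.shape != truth.shape:
        raise ValueError("test and truth shapes differ")
    ok = _comparable(test, truth)
    e = int((ok & (test != truth)).sum())
    m_ra = int((ok & (test == truth) & (truth == 1)).sum())
    m_aa = int((ok & (test == truth) & (truth == 2)).sum())
    den = e + m_ra + m_aa
    if den == 0:
        raise ValueError("NRD undefined: no discordant or non-reference cells")
    return e / den


def mismatch_by_class(
    test: np.ndarray, truth: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Mismatch rate and mismatch share per truth genotype class (RR, RA, AA).

    The rate is the fraction of comparable cells of that truth class that
    were miscalled; the share is each class's fraction of all mismatches.
    Empty classes are NaN.
    """
    test = np.asarray(test)
    truth = np.asarray(truth)
    ok = _comparable(test, truth)
    rates = np.full(3, np.nan)
    shares = np.full(3, np.nan)
    total_mism = int((ok & (test != truth)).sum())
    for g in range(3):
        cls = ok & (truth == g)
        n = int(cls.sum())
        if n:
            m = int((cls & (test != truth)).sum())
            rates[g] = m / n
            if total_mism:
                shares[g] = m / total_mism
    return rates, shares


def haplotype_discordance(
    test_phased: np.ndarray,
    truth_phased: np.ndarray,
    hap_index: int,
    windows: np.ndarray,
    positions: np.ndarray,
    missing: np.ndarray | None = None,
    repair: bool = False,
) -> np.ndarray:
    """Per-window allele mismatch fraction for one haplotype label.

    Haplotypes are compared as emitted (label A vs A, B vs B) — the literal
    splitting procedure; with ``repair`` the per-window minimum over the two
    label assignments is reported instead.  Windows with no comparable site
    are NaN.
    """
    if hap_index not in (0, 1):
        raise ValueError("hap_index must be 0 (A) or 1 (B)")
    N, M, _ = test_phased.shape
    ok = np.ones((N, M), dtype=bool) if missing is None else ~missing
    wi = np.digitize(positions, windows) - 1
    nw = len(windows) - 1
    out = np.full(nw, np.nan)
    t = test_phased[..., hap_index]
    u = truth_phased[..., hap_index]
    t_swap = test_phased[..., 1 - hap_index]
    for w in range(nw):
        cols = wi == w
        if not cols.any():
            continue
        m = ok[:, cols]
        n = int(m.sum())
        if n == 0:
            continue
        d = (t[:, cols] != u[:, cols])[m].sum() / n
        if repair:
            d2 = (t_swap[:, cols] != u[:, cols])[m].sum() / n
            d = min(d, d2)
        out[w] = d
    return out


def switch_error_rate(
    test_phased: np.ndarray,
    truth_phased: np.ndarray,
    missing: np.ndarray | None = None,
) -> np.ndarray:
    """Per-individual switch error rate over consecutive truth-het sites.

    Among consecutive heterozygous sites (in truth), the fraction whose
    relative phase in the test callset disagrees with truth.  Individuals
    with fewer than two usable het sites are NaN.
    """
    N, M, _ = truth_phased.shape
    out = np.full(N, np.nan)
    for i in range(N):
        het = truth_phased[i, :, 0] != truth_phased[i, :, 1]
        het &= test_phased[i, :, 0] != test_phased[i, :, 1]
        if missing is not None:
            het &= ~missing[i]
        idx = np.flatnonzero(het)
        if idx.size < 2:
            continue
        # phase orientation at each het site: does test hap A carry the same
        # allele as truth hap A?
        agree = test_phased[i, idx, 0] == truth_phased[i, idx, 0]
        switches = np.sum(agree[1:] != agree[:-1])
        out[i] = switches / (idx.size - 1)
    return out
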