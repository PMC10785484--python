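"""Synthetic reference panel, target cohort, and read-pileup generators.

The generators emulate the data structure that low-pass imputation studies
rely on: a phased, breed-structured reference panel of biallelic SNV
haplotypes; a target cohort whose true haplotypes are mosaics of panel
haplotypes from one breed, optionally carrying private alleles the panel has
never seen; and shallow-sequencing read pileups at a configurable mean depth,
with regional and per-individual depth modifiers.  Everything is driven by a
``numpy.random.Generator`` seed and reproduces bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "HaplotypePanel",
    "CohortTruth",
    "ReadPileup",
    "simulate_panel",
    "subset_panel",
    "simulate_cohort",
    "simulate_pileup",
    "thin_pileup",
    "inject_switch_errors",
]


@dataclass
class HaplotypePanel:
    """Phased reference haplotypes on a single chromosome.

    Attributes
    ----------
    alleles : ndarray of shape (K, M), dtype int8
        Haplotype alleles in {0, 1}; K is even and haplotypes ``2i`` and
        ``2i + 1`` form diploid individual ``i``.
    positions : ndarray of shape (M,), dtype int64
        1-based physical coordinates, strictly increasing.
    panel_af : ndarray of shape (M,)
        Alternate-allele frequency per site (column mean of ``alleles``).
    breed_label : ndarray of shape (K,), dtype object/str
        Breed tag per haplotype; identical within a diploid pair.
    """

    alleles: np.ndarray
    positions: np.ndarray
    panel_af: np.ndarray
    breed_label: np.ndarray

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def validate(self) -> None:
        K, M = self.alleles.shape
        if K % 2:
            raise ValueError("panel must contain an even number of haplotypes")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if not np.allclose(self.panel_af, self.alleles.mean(axis=0)):
            raise ValueError("panel_af inconsistent with alleles")


@dataclass
class CohortTruth:
    """Gold-standard phased diplotypes for the target cohort."""

    hapA: np.ndarray          # (N, M) int8
    hapB: np.ndarray          # (N, M) int8
    phenotype: np.ndarray     # (N,) int8, 1 = case (homozygous alt at causal site)
    sex: np.ndarray           # (N,) int8
    causal_site: int
    private_mask: np.ndarray  # (N, 2, M) bool, allele absent from the panel

    @property
    def genotypes(self) -> np.ndarray:
        """Unphased genotype matrix (N, M) in {0, 1, 2}."""
        return (self.hapA + self.hapB).astype(np.int8)

    @property
    def n_individuals(self) -> int:
        return self.hapA.shape[0]

    def validate(self) -> None:
        g_causal = self.hapA[:, self.causal_site] + self.hapB[:, self.causal_site]
        if not np.array_equal(self.phenotype, (g_causal == 2).astype(np.int8)):
            raise ValueError("phenotype must equal homozygous-alt status at the causal site")


@dataclass
class ReadPileup:
    """Per-site, per-individual read counts from shallow sequencing."""

    ref_count: np.ndarray   # (N, M) int64
    alt_count: np.ndarray   # (N, M) int64
    epsilon: float          # per-base error probability
    lambda_target: float    # nominal mean depth (X)
    region_multiplier: np.ndarray = field(default=None)      # (M,)
    individual_multiplier: np.ndarray = field(default=None)  # (N,)

    @property
    def depth(self) -> np.ndarray:
        return self.ref_count + self.alt_count


def simulate_panel(
    n_breeds: int,
    haps_per_breed: int,
    n_sites: int,
    chrom_length_bp: int,
    founder_div: float = 0.2,
    mutation_rate: float = 0.01,
    recomb_switch_rate: float = 5e-7,
    seed: int = 0,
    home_founder_prob: float = 0.75,
) -> HaplotypePanel:
    """Simulate a breed-structured phased reference panel.

    One ancestral 0/1 string is drawn; each breed founder mutates it
    independently at rate ``founder_div``.  Every panel haplotype is then a
    recombinant mosaic that starts on its own breed founder, switches source
    founder at rate ``recomb_switch_rate`` per bp (returning to the home
    founder with probability ``home_founder_prob``, otherwise copying a
    uniformly chosen other founder), and finally receives private flips at
    ``mutation_rate`` per site.  Site positions are drawn uniformly without
    replacement from ``1..chrom_length_bp``.
    """
    if n_sites < 2:
        raise ValueError("n_sites must be >= 2")
    if haps_per_breed % 2:
        raise ValueError("haps_per_breed must be even (haplotypes come in diploid pairs)")
    if n_sites > chrom_length_bp:
        raise ValueError("n_sites cannot exceed chrom_length_bp")
    for name, p in [("founder_div", founder_div), ("mutation_rate", mutation_rate)]:
        if not 0.0 <= p < 1.0:
            raise ValueError(f"{name} must be a probability in [0, 1)")
    rng = np.random.default_rng(seed)

    positions = np.sort(rng.choice(chrom_length_bp, size=n_sites, replace=False)) + 1
    ancestral = rng.integers(0, 2, size=n_sites).astype(np.int8)
    founders = np.empty((n_breeds, n_sites), dtype=np.int8)
    for b in range(n_breeds):
        flips = rng.random(n_sites) < founder_div
        founders[b] = np.where(flips, 1 - ancestral, ancestral)

    K = n_breeds * haps_per_breed
    gap = np.diff(positions)
    p_switch = 1.0 - np.exp(-recomb_switch_rate * gap)
    alleles = np.empty((K, n_sites), dtype=np.int8)
    labels = np.empty(K, dtype=object)
    h = 0
    for b in range(n_breeds):
        for _ in range(haps_per_breed):
            source = np.empty(n_sites, dtype=np.int64)
            cur = b
            source[0] = cur
            switch = rng.random(n_sites - 1) < p_switch
            for m in range(1, n_sites):
                if switch[m - 1]:
                    if n_breeds == 1 or rng.random() < home_founder_prob:
                        cur = b
                    else:
                        cur = rng.choice([x for x in range(n_breeds) if x != b])
                source[m] = cur
            hap = founders[source, np.arange(n_sites)]
            flips = rng.random(n_sites) < mutation_rate
            alleles[h] = np.where(flips, 1 - hap, hap)
            labels[h] = f"breed{b}"
            h += 1

    panel = HaplotypePanel(
        alleles=alleles,
        positions=positions.astype(np.int64),
        panel_af=alleles.mean(axis=0),
        breed_label=labels,
    )
    panel.validate()
    return panel


def subset_panel(
    panel: HaplotypePanel,
    target_breed: str,
    n_total_diploids: int,
    include_target: bool = True,
    max_per_breed: int = 2,
    seed: int = 0,
) -> HaplotypePanel:
    """Subset a panel by diploid individuals, keeping haplotype pairs together.

    With ``include_target`` set, all available target-breed diploids are kept
    and the remainder is filled with non-target diploids capped at
    ``max_per_breed`` per breed (the target-enriched "panel 1" analogue).
    Without it, at most one target-breed diploid survives (the target-depleted
    "panel 2" analogue).  ``panel_af`` is recomputed on the subset.
    """
    K = panel.n_haplotypes
    n_diploids = K // 2
    if n_total_diploids > n_diploids:
        raise ValueError("requested more diploids than the panel contains")
    rng = np.random.default_rng(seed)
    pair_labels = panel.breed_label[::2]
    target_pairs = np.flatnonzero(pair_labels == target_breed)
    if include_target and target_pairs.size == 0:
        raise ValueError(f"target breed {target_breed!r} absent from panel")
    other_pairs = np.flatnonzero(pair_labels != target_breed)

    chosen: list[int] = []
    if include_target:
        take = target_pairs[: n_total_diploids]
        chosen.extend(take.tolist())
    else:
        if target_pairs.size:
            chosen.append(int(rng.choice(target_pairs)))
    # fill with non-target diploids, capped per breed
    counts: dict[str, int] = {}
    for p in rng.permutation(other_pairs):
        if len(chosen) >= n_total_diploids:
            break
        lab = pair_labels[p]
        if counts.get(lab, 0) >= max_per_breed:
            continue
        counts[lab] = counts.get(lab, 0) + 1
        chosen.append(int(p))
    if len(chosen) < n_total_diploids:
        # relax the per-breed cap rather than under-deliver
        remaining = [int(p) for p in rng.permutation(other_pairs) if p not in chosen]
        chosen.extend(remaining[: n_total_diploids - len(chosen)])
    chosen = sorted(set(chosen))[:n_total_diploids]

    hap_idx = np.sort(np.concatenate([[2 * p, 2 * p + 1] for p in chosen]))
    alleles = panel.alleles[hap_idx]
    sub = HaplotypePanel(
        alleles=alleles,
        positions=panel.positions.copy(),
        panel_af=alleles.mean(axis=0),
        breed_label=panel.breed_label[hap_idx].copy(),
    )
    sub.validate()
    return sub


def simulate_cohort(
    panel: HaplotypePanel,
    n_individuals: int = 30,
    n_cases: int = 6,
    mosaic_switch_rate: float = 1e-7,
    private_allele_rate: float = 0.002,
    target_breed: str = "breed0",
    causal_maf_range: tuple[float, float] = (0.15, 0.35),
    seed: int = 0,
) -> CohortTruth:
    """Simulate true phased diplotypes for the target cohort.

    Each of the ``2 * n_individuals`` truth haplotypes is a mosaic over the
    target breed's panel haplotypes (switch rate per bp), with private alleles
    flipped in at ``private_allele_rate`` per site and recorded in
    ``private_mask``.  A causal site is chosen among sites whose panel MAF
    lies in ``causal_maf_range``; genotypes there are overwritten so that
    exactly ``n_cases`` individuals are homozygous for the alternate allele,
    and the fully penetrant recessive phenotype is derived from that state.
    """
    if not 0 < n_cases < n_individuals:
        raise ValueError("need 0 < n_cases < n_individuals")
    rng = np.random.default_rng(seed)
    M = panel.n_sites
    src_idx = np.flatnonzero(panel.breed_label == target_breed)
    if src_idx.size == 0:
        raise ValueError(f"target breed {target_breed!r} absent from panel")
    sources = panel.alleles[src_idx]
    n_src = sources.shape[0]

    gap = np.diff(panel.positions)
    p_switch = 1.0 - np.exp(-mosaic_switch_rate * gap)

    haps = np.empty((2 * n_individuals, M), dtype=np.int8)
    private = np.zeros((2 * n_individuals, M), dtype=bool)
    for h in range(2 * n_individuals):
        cur = rng.integers(n_src)
        source = np.empty(M, dtype=np.int64)
        source[0] = cur
        switch = rng.random(M - 1) < p_switch
        for m in range(1, M):
            if switch[m - 1]:
                cur = rng.integers(n_src)
            source[m] = cur
        hap = sources[source, np.arange(M)]
        flips = rng.random(M) < private_allele_rate
        haps[h] = np.where(flips, 1 - hap, hap)
        # flips are recorded as-is; whether the flipped state is truly absent
        # from the panel column depends on that column's polymorphism
        private[h] = flips

    hapA = haps[0::2].copy()
    hapB = haps[1::2].copy()
    privA = private[0::2]
    privB = private[1::2]

    maf = np.minimum(panel.panel_af, 1.0 - panel.panel_af)
    lo, hi = causal_maf_range
    candidates = np.flatnonzero((maf >= lo) & (maf <= hi))
    if candidates.size == 0:
        raise ValueError(
            f"no site with panel MAF in [{lo}, {hi}]; loosen the range or add variation"
        )
    causal_site = int(rng.choice(candidates))

    cases = rng.choice(n_individuals, size=n_cases, replace=False)
    is_case = np.zeros(n_individuals, dtype=bool)
    is_case[cases] = True
    # overwrite causal genotypes: cases homozygous alt, everyone else not
    hapA[is_case, causal_site] = 1
    hapB[is_case, causal_site] = 1
    hom_ctrl = ~is_case & (hapA[:, causal_site] == 1) & (hapB[:, causal_site] == 1)
    hapB[hom_ctrl, causal_site] = 0
    # the causal allele segregates in the panel, so it is never private
    privA[:, causal_site] = False
    privB[:, causal_site] = False

    truth = CohortTruth(
        hapA=hapA,
        hapB=hapB,
        phenotype=is_case.astype(np.int8),
        sex=rng.integers(0, 2, size=n_individuals).astype(np.int8),
        causal_site=causal_site,
        private_mask=np.stack([privA, privB], axis=1),
    )
    truth.validate()
    return truth


def simulate_pileup(
    truth: CohortTruth,
    lambda_target: float,
    epsilon: float = 0.001,
    region_profile: np.ndarray | None = None,
    indiv_profile: np.ndarray | None = None,
    seed: int = 0,
) -> ReadPileup:
    """Simulate per-site read pileups at a nominal mean depth.

    Depth at cell (i, m) is Poisson with mean
    ``lambda_target * region_profile[m] * indiv_profile[i]``; alternate-read
    counts are binomial with success probability
    ``q_g = (g/2)(1-eps) + (1-g/2) eps`` for true genotype ``g``.
    """
    if lambda_target <= 0:
        raise ValueError("lambda_target must be positive")
    N, M = truth.hapA.shape
    region = np.ones(M) if region_profile is None else np.asarray(region_profile, float)
    indiv = np.ones(N) if indiv_profile is None else np.asarray(indiv_profile, float)
    if np.any(region <= 0) or np.any(indiv <= 0):
        raise ValueError("depth profiles must be positive")
    rng = np.random.default_rng(seed)

    mean = lambda_target * indiv[:, None] * region[None, :]
    depth = rng.poisson(mean)
    g = truth.genotypes.astype(float)
    q = (g / 2.0) * (1.0 - epsilon) + (1.0 - g / 2.0) * epsilon
    alt = rng.binomial(depth, q)
    return ReadPileup(
        ref_count=(depth - alt).astype(np.int64),
        alt_count=alt.astype(np.int64),
        epsilon=epsilon,
        lambda_target=lambda_target,
        region_multiplier=region,
        individual_multiplier=indiv,
    )


def thin_pileup(pileup: ReadPileup, retain_fraction: float, seed: int = 0) -> ReadPileup:
    """Binomially thin a pileup, keeping each read with ``retain_fraction``.

    Reference and alternate reads are thinned independently; the error rate
    is unchanged.  Thinning a mean-depth-43.5 pileup at 0.40 yields a
    mean-depth-17.4 pileup in expectation.
    """
    if not 0.0 <= retain_fraction <= 1.0:
        raise ValueError("retain_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    ref = rng.binomial(pileup.ref_count, retain_fraction)
    alt = rng.binomial(pileup.alt_count, retain_fraction)
    return replace(
        pileup,
        ref_count=ref.astype(np.int64),
        alt_count=alt.astype(np.int64),
        lambda_target=pileup.lambda_target * retain_fraction,
    )


def inject_switch_errors(
    hapA: np.ndarray, hapB: np.ndarray, rate: float, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Corrupt phasing by swapping haplotypes from random points onward.

    At each inter-site boundary, a switch occurs independently with
    probability ``rate``; where the cumulative switch parity is odd the two
    haplotypes are exchanged.  Genotypes are untouched — only the relative
    phase of heterozygous sites degrades.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    N, M = hapA.shape
    switches = rng.random((N, M - 1)) < rate
    parity = np.zeros((N, M), dtype=bool)
    parity[:, 1:] = np.cumsum(switches, axis=1) % 2 == 1
    newA = np.where(parity, hapB, hapA)
    newB = np.where(parity, hapA, hapB)
    return newA.astype(hapA.dtype), newB.astype(hapB.dtype)
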