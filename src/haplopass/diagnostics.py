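"""Haplotype-consistency diagnostics across sequencing depths.

A phased callset is produced per depth of coverage; if imputation and
phasing were consistent, any genomic region would show at most two distinct
haplotypes per individual across all depth datasets (one if fully
homozygous).  These routines sample fixed-variant-count regions, count the
distinct haplotype strings per individual across depths, test regional depth
depressions against the chromosome average with a paired Wilcoxon
signed-rank test, compute 1-Mb window discordance metrics, and run the
supporting OLS regressions and correlation summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .impute import ImputedCallset
from .simulate import ReadPileup

__all__ = [
    "RegionSet",
    "sample_regions",
    "count_region_haplotypes",
    "region_haplotype_table",
    "region_depth_wilcoxon",
    "window_metrics",
    "ols_regress",
    "correlation_suite",
]


@dataclass
class RegionSet:
    """Consecutive-site regions with a fixed variant count."""

    start_index: np.ndarray     # (R,) first site index of each region
    variants_per_region: int
    positions: np.ndarray       # (M,) site coordinates the indices refer to

    @property
    def n_regions(self) -> int:
        return self.start_index.size

    @property
    def end_index(self) -> np.ndarray:
        """Exclusive end site index per region."""
        return self.start_index + self.variants_per_region

    @property
    def start_bp(self) -> np.ndarray:
        return self.positions[self.start_index]

    @property
    def end_bp(self) -> np.ndarray:
        return self.positions[self.end_index - 1]

    @property
    def size_bp(self) -> np.ndarray:
        return self.end_bp - self.start_bp + 1

    def sites(self, r: int) -> np.ndarray:
        return np.arange(self.start_index[r], self.start_index[r] + self.variants_per_region)


def sample_regions(
    positions: np.ndarray,
    n_regions: int = 10_000,
    variants_per_region: int = 100,
    seed: int = 0,
) -> RegionSet:
    """Uniformly sample regions of exactly ``variants_per_region`` sites.

    Start indices are drawn uniformly (with replacement across regions) from
    the range where a full-length region fits, which is equivalent to
    resampling regions truncated at the chromosome end.
    """
    positions = np.asarray(positions)
    M = positions.size
    if M < variants_per_region:
        raise ValueError(
            f"chromosome has {M} sites, fewer than variants_per_region={variants_per_region}"
        )
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, M - variants_per_region + 1, size=n_regions)
    return RegionSet(
        start_index=starts.astype(np.int64),
        variants_per_region=int(variants_per_region),
        positions=positions,
    )


def _phased_missing(callset) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(callset, ImputedCallset):
        return callset.phased, callset.missing
    phased = np.asarray(callset)
    return phased, np.zeros(phased.shape[:2], dtype=bool)


MISSING_ALLELE = 2  # symbol for a GP-masked cell in an emitted haplotype string


def count_region_haplotypes(
    phased_by_depth: list,
    region_sites: np.ndarray,
    individual: int,
    mode: str = "symbol",
) -> int | None:
    """Distinct haplotype strings for one individual over one region.

    Collects the ``2 * n_depths`` haplotype allele-strings over the region's
    sites and counts distinct strings.  ``mode`` controls masked-cell
    handling:

    - ``"symbol"`` (default): strings are compared as emitted, with a masked
      cell as its own symbol — so depth-dependent masking differences count
      as haplotype differences, as they do when comparing written phased
      VCFs directly.
    - ``"restrict"``: positions masked in any depth dataset for this
      individual are dropped before comparing; returns ``None`` (flagged
      undefined) when fewer than two positions remain.
    """
    if len(phased_by_depth) < 1:
        raise ValueError("need at least one depth dataset")
    if mode not in ("symbol", "restrict"):
        raise ValueError("mode must be 'symbol' or 'restrict'")
    region_sites = np.asarray(region_sites)
    usable = np.ones(region_sites.size, dtype=bool)
    haps = []
    for cs in phased_by_depth:
        phased, missing = _phased_missing(cs)
        if region_sites.max() >= phased.shape[1]:
            raise ValueError("region sites exceed the callset's site range")
        miss = missing[individual, region_sites]
        block = phased[individual][region_sites].astype(np.int8).copy()
        if mode == "symbol":
            block[miss] = MISSING_ALLELE
        else:
            usable &= ~miss
        haps.append(block)
    if mode == "restrict":
        if usable.sum() < 2:
            return None
        strings = {hap[usable, a].tobytes() for hap in haps for a in (0, 1)}
    else:
        strings = {hap[:, a].tobytes() for hap in haps for a in (0, 1)}
    return len(strings)


def region_haplotype_table(
    phased_by_depth: list,
    regions: RegionSet,
    mode: str = "symbol",
) -> pd.DataFrame:
    """Haplotype counts per region x individual; NaN where undefined.

    Columns: region, individual, n_haplotypes.
    """
    n_indiv = _phased_missing(phased_by_depth[0])[0].shape[0]
    rows = []
    for r in range(regions.n_regions):
        sites = regions.sites(r)
        for i in range(n_indiv):
            c = count_region_haplotypes(phased_by_depth, sites, i, mode=mode)
            rows.append((r, i, np.nan if c is None else c))
    return pd.DataFrame(rows, columns=["region", "individual", "n_haplotypes"])


def region_depth_wilcoxon(pileup: ReadPileup, region_sites: np.ndarray) -> float:
    """Paired Wilcoxon signed-rank p-value: region vs chromosome mean depth.

    Pairs are per-individual (mean depth over the region's sites, mean depth
    over the whole chromosome); zero differences are dropped; all-zero
    differences return p = 1 by convention.
    """
    depth = pileup.depth
    n = depth.shape[0]
    if n < 6:
        raise ValueError("need at least six individuals for a signed-rank test")
    region_mean = depth[:, np.asarray(region_sites)].mean(axis=1)
    chrom_mean = depth.mean(axis=1)
    diff = region_mean - chrom_mean
    if np.all(diff == 0):
        return 1.0
    return float(stats.wilcoxon(diff, zero_method="wilcox", method="auto").pvalue)


def window_metrics(
    callsets_by_depth: dict[float, ImputedCallset],
    ref_pre_calls: np.ndarray,
    pileups_by_depth: dict[float, ReadPileup],
    z_by_depth: dict[float, np.ndarray],
    positions: np.ndarray,
    ref_post: ImputedCallset | None = None,
    window_bp: float = 1e6,
    trim_quantiles: tuple[float, float] = (0.01, 0.99),
) -> pd.DataFrame:
    """Per-window, per-depth depth / discordance / XP-EHH metrics.

    For each window of ``window_bp`` and each depth: mean sequencing depth,
    genotype discordance of the post-imputation calls against the top-depth
    pre-imputation calls (``ref_pre_calls``), haplotype A/B discordance
    against the top-depth post-imputation haplotypes (``ref_post``), and the
    median XP-EHH Z.  Windows whose mean depth falls outside the
    ``trim_quantiles`` band of that depth's window-depth distribution are
    dropped.  Empty windows are absent from the table.
    """
    from .concordance import genotype_discordance, haplotype_discordance
    from .likelihoods import MISSING

    positions = np.asarray(positions)
    lo = positions.min()
    hi = positions.max()
    edges = np.arange(lo, hi + window_bp, window_bp)
    if edges[-1] <= hi:
        edges = np.append(edges, hi + 1)
    nw = len(edges) - 1
    rows = []
    for depth_x, cs in callsets_by_depth.items():
        pu = pileups_by_depth[depth_x]
        z = np.asarray(z_by_depth[depth_x], float)
        test = cs.genotypes.astype(np.int8).copy()
        test[cs.missing] = MISSING
        _, disc = genotype_discordance(
            test, ref_pre_calls, windows=edges, positions=positions
        )
        if ref_post is not None:
            hapA = haplotype_discordance(
                cs.phased, ref_post.phased, 0, edges, positions, missing=cs.missing
            )
            hapB = haplotype_discordance(
                cs.phased, ref_post.phased, 1, edges, positions, missing=cs.missing
            )
        else:
            hapA = np.full(nw, np.nan)
            hapB = np.full(nw, np.nan)
        wi = np.digitize(positions, edges) - 1
        for w in range(nw):
            cols = wi == w
            if not cols.any():
                continue
            zw = z[cols]
            zw = zw[np.isfinite(zw)]
            rows.append(
                {
                    "depth": depth_x,
                    "window": w,
                    "window_start": edges[w],
                    "mean_depth": pu.depth[:, cols].mean(),
                    "geno_discordance": disc[w],
                    "hapA_discordance": hapA[w],
                    "hapB_discordance": hapB[w],
                    "median_z": np.median(zw) if zw.size else np.nan,
                }
            )
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    keep = np.ones(len(table), dtype=bool)
    for depth_x, grp in table.groupby("depth"):
        qlo, qhi = np.quantile(grp["mean_depth"], trim_quantiles)
        bad = (grp["mean_depth"] < qlo) | (grp["mean_depth"] > qhi)
        keep[grp.index[bad]] = False
    return table[keep].reset_index(drop=True)


def ols_regress(y: np.ndarray, X: pd.DataFrame, baseline: dict | None = None) -> dict:
    """OLS with intercept and treatment-coded categorical covariates.

    Categorical (object/category dtype) columns of ``X`` are expanded to
    treatment contrasts; ``baseline`` maps column name to the reference
    level (default: first level in sorted order).  Returns a dict with a
    coefficient table (coef, se, t, p) and the model r-squared.
    """
    X = X.copy()
    for col in X.columns:
        if X[col].dtype == object or isinstance(X[col].dtype, pd.CategoricalDtype):
            levels = sorted(X[col].unique())
            ref = (baseline or {}).get(col, levels[0])
            for lev in levels:
                if lev == ref:
                    continue
                X[f"{col}[{lev}]"] = (X[col] == lev).astype(float)
            X = X.drop(columns=[col])
    design = sm.add_constant(X.astype(float), has_constant="add")
    y = np.asarray(y, float)
    if len(y) <= design.shape[1]:
        raise ValueError("need more observations than design columns")
    rank = np.linalg.matrix_rank(design.values)
    if rank < design.shape[1]:
        for col in design.columns[1:]:
            if np.linalg.matrix_rank(design.drop(columns=[col]).values) == rank:
                raise ValueError(f"design is rank deficient; column {col!r} is redundant")
        raise ValueError("design is rank deficient")
    fit = sm.OLS(y, design).fit()
    table = pd.DataFrame(
        {
            "coef": fit.params,
            "se": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
        }
    )
    return {"table": table, "r2": float(fit.rsquared), "fit": fit}


def correlation_suite(
    vec_by_depth: dict[float, np.ndarray],
    reference_depth: float,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Pearson r of each depth's vector vs the reference.

    Returns ``(summary, pairs)``: the summary has one row per depth with r,
    r^2, and the pair count (NaN r when fewer than 3 complete pairs); the
    pairs table holds the biplot-ready complete pairs.
    """
    ref = np.asarray(vec_by_depth[reference_depth], float)
    rows = []
    pair_rows = []
    for depth_x, vec in vec_by_depth.items():
        v = np.asarray(vec, float)
        ok = np.isfinite(ref) & np.isfinite(v)
        n = int(ok.sum())
        if n >= 3 and np.std(v[ok]) > 0 and np.std(ref[ok]) > 0:
            r = float(np.corrcoef(v[ok], ref[ok])[0, 1])
        else:
            r = np.nan
        rows.append({"depth": depth_x, "r": r, "r2": r * r if np.isfinite(r) else np.nan, "n": n})
        for idx in np.flatnonzero(ok):
            pair_rows.append(
                {"depth": depth_x, "index": int(idx), "value": v[idx], "reference": ref[idx]}
            )
    return pd.DataFrame(rows), pd.DataFrame(pair_rows)
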