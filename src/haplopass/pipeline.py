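"""End-to-end experiment driver.

``run_experiment`` executes the whole evaluation at desk scale: simulate a
breed-structured reference panel and a target cohort; sequence the cohort at
the top depth and derive the depth grid (independent resequencing for the
low depths, binomial read thinning for the middle ones); compute genotype
likelihoods; call the top-depth pre-imputation validation genotypes; impute
and phase every depth with every reference panel; apply GP masking; and run
the concordance, association, XP-EHH, and haplotype-consistency diagnostic
suites.  The result is a bundle of tidy tables, all reproducible
bit-identically from the config seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import concordance as cc
from . import diagnostics as dg
from . import selection as sel
from .association import LinearMixedModel, significant_hits
from .config import ExperimentConfig, stage_seed
from .impute import LiStephensImputer, ImputedCallset
from .likelihoods import MISSING, naive_calls, pileup_to_gl
from .simulate import (
    simulate_cohort,
    simulate_panel,
    simulate_pileup,
    subset_panel,
    thin_pileup,
)

logger = logging.getLogger("haplopass")

__all__ = ["ExperimentReport", "run_experiment"]


@dataclass
class ExperimentReport:
    """Tidy result tables plus (optionally) the underlying objects."""

    config: ExperimentConfig
    tables: dict[str, pd.DataFrame]
    objects: dict = field(default_factory=dict)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.config.to_yaml(outdir / "config.yaml")
        for name, table in self.tables.items():
            table.to_csv(outdir / f"{name}.tsv", sep="\t", index=False, na_rep="NA")


def _hard_calls(cs: ImputedCallset) -> np.ndarray:
    g = cs.genotypes.astype(np.int8).copy()
    g[cs.missing] = MISSING
    return g


def _simulate_inputs(cfg: ExperimentConfig):
    panel = simulate_panel(
        n_breeds=cfg.n_breeds,
        haps_per_breed=cfg.haps_per_breed,
        n_sites=cfg.n_sites,
        chrom_length_bp=cfg.chrom_length_bp,
        founder_div=cfg.founder_div,
        mutation_rate=cfg.mutation_rate,
        recomb_switch_rate=cfg.recomb_switch_rate,
        seed=stage_seed(cfg.seed, "panel"),
    )
    panels = {
        "full": panel,
        "panel1": subset_panel(
            panel,
            cfg.target_breed,
            cfg.subset_diploids,
            include_target=True,
            max_per_breed=cfg.subset_max_per_breed,
            seed=stage_seed(cfg.seed, "panel1"),
        ),
        "panel2": subset_panel(
            panel,
            cfg.target_breed,
            cfg.subset_diploids,
            include_target=False,
            max_per_breed=cfg.subset_max_per_breed,
            seed=stage_seed(cfg.seed, "panel2"),
        ),
    }
    truth = simulate_cohort(
        panel,
        n_individuals=cfg.n_individuals,
        n_cases=cfg.n_cases,
        mosaic_switch_rate=cfg.mosaic_switch_rate,
        private_allele_rate=cfg.private_allele_rate,
        target_breed=cfg.target_breed,
        causal_maf_range=cfg.causal_maf_range,
        seed=stage_seed(cfg.seed, "cohort"),
    )
    return panels, truth


def _region_profile(cfg: ExperimentConfig, rng: np.random.Generator) -> np.ndarray:
    """Flat depth profile with planted depressed segments (site space)."""
    profile = np.ones(cfg.n_sites)
    span = cfg.depressed_segment_sites
    for _ in range(cfg.n_depressed_segments):
        start = rng.integers(0, max(1, cfg.n_sites - span))
        profile[start : start + span] = cfg.depressed_multiplier
    return profile


def _sequence(cfg: ExperimentConfig, truth) -> dict[float, object]:
    """Pileups for every depth: fresh draws and thinned top-depth data."""
    rng = np.random.default_rng(stage_seed(cfg.seed, "region-profile"))
    profile = _region_profile(cfg, rng)
    top = cfg.top_depth
    pileups = {
        top: simulate_pileup(
            truth, top, epsilon=cfg.epsilon, region_profile=profile,
            seed=stage_seed(cfg.seed, f"pileup-{top}"),
        )
    }
    for d in cfg.depths[:-1]:
        if d in cfg.thinned_depths:
            pileups[d] = thin_pileup(
                pileups[top], d / top, seed=stage_seed(cfg.seed, f"thin-{d}")
            )
        else:
            pileups[d] = simulate_pileup(
                truth, d, epsilon=cfg.epsilon, region_profile=profile,
                seed=stage_seed(cfg.seed, f"pileup-{d}"),
            )
    return pileups, profile


def run_experiment(
    cfg: ExperimentConfig | None = None,
    outdir=None,
    keep_objects: bool = False,
) -> ExperimentReport:
    """Run the full depth x panel evaluation and return the report bundle."""
    cfg = cfg or ExperimentConfig()
    cfg.validate()
    logger.info("simulate: seed=%d sites=%d", cfg.seed, cfg.n_sites)
    panels, truth = _simulate_inputs(cfg)
    positions = panels["full"].positions
    top = cfg.top_depth

    logger.info("sequencing: depths=%s", cfg.depths)
    pileups, region_profile = _sequence(cfg, truth)
    gls = {d: pileup_to_gl(pileups[d]) for d in cfg.depths}
    validation = naive_calls(gls[top], min_depth=cfg.min_depth_map[top])

    # pre-imputation per-depth discordance vs the top-depth validation calls
    pre_rows = []
    for d in cfg.depths:
        calls = naive_calls(gls[d], min_depth=cfg.min_depth_map[d])
        disc = cc.genotype_discordance(calls, validation)
        pre_rows.append(
            {
                "depth": d,
                "discordance": disc,
                "missing_rate": float((calls == MISSING).mean()),
                "mean_depth": float(pileups[d].depth.mean()),
            }
        )
    pre_table = pd.DataFrame(pre_rows)

    logger.info("imputation: %d datasets", len(cfg.depths) * len(panels))
    callsets: dict[tuple[str, float], ImputedCallset] = {}
    for pname, panel in panels.items():
        imputer = LiStephensImputer(
            recomb_rate=cfg.recomb_rate,
            ne_scale=cfg.ne_scale,
            mismatch_theta=cfg.mismatch_theta,
            chunk_bp=cfg.chunk_bp,
            chunk_overlap_bp=cfg.chunk_overlap_bp,
            gp_threshold=cfg.gp_threshold,
            phase_method=cfg.phase_method,
        ).fit(panel)
        for d in cfg.depths:
            imputer.set_params(phase_seed=stage_seed(cfg.seed, f"phase-{pname}-{d}"))
            callsets[(pname, d)] = imputer.transform(gls[d])
            logger.info("imputed depth=%.1f panel=%s", d, pname)

    # ----- concordance suite (vs top-depth pre-imputation validation calls)
    conc_rows, maf_rows, site_rows = [], [], []
    for (pname, d), cs in callsets.items():
        test = _hard_calls(cs)
        disc = cc.genotype_discordance(
            test, validation, depth=pileups[d].depth, min_depth=cfg.min_depth_map[d]
        )
        nrd = cc.nonref_discordance(test, validation)
        rates, shares = cc.mismatch_by_class(test, validation)
        pooled_r2, per_site_r2 = cc.dosage_r2(cs.dosage, validation, cs.missing)
        sw = cc.switch_error_rate(cs.phased, np.stack([truth.hapA, truth.hapB], -1),
                                  missing=cs.missing)
        conc_rows.append(
            {
                "panel": pname,
                "depth": d,
                "discordance": disc,
                "nrd": nrd,
                "dosage_r2": pooled_r2,
                "rate_rr": rates[0],
                "rate_ra": rates[1],
                "rate_aa": rates[2],
                "share_rr": shares[0],
                "share_ra": shares[1],
                "share_aa": shares[2],
                "masked_rate": float(cs.missing.mean()),
                "median_info": float(np.median(cs.info)),
                "switch_error_median": float(np.nanmedian(sw)),
            }
        )
        bins, r2b, nb = cc.aggregate_r2_by_maf(
            cs.dosage, validation, cs.panel_af_used, missing=cs.missing
        )
        for b in range(len(r2b)):
            maf_rows.append(
                {
                    "panel": pname,
                    "depth": d,
                    "bin_low": bins[b],
                    "bin_high": bins[b + 1],
                    "r2": r2b[b],
                    "n_pairs": nb[b],
                }
            )
        maf = np.minimum(cs.panel_af_used, 1 - cs.panel_af_used)
        for m in range(cfg.n_sites):
            if np.isfinite(per_site_r2[m]):
                site_rows.append(
                    {"panel": pname, "depth": d, "site": m, "maf": maf[m],
                     "r2": per_site_r2[m], "info": cs.info[m]}
                )
    conc_table = pd.DataFrame(conc_rows)
    maf_table = pd.DataFrame(maf_rows)
    site_table = pd.DataFrame(site_rows)

    # ----- association (LMM on dosage, sex covariate, kinship from dosage)
    logger.info("association")
    assoc_rows, hit_rows = [], []
    logp = {}
    for (pname, d), cs in callsets.items():
        model = LinearMixedModel(maf_threshold=cfg.assoc_maf)
        model.fit(cs.dosage, truth.phenotype.astype(float), covariates=truth.sex)
        res = model.result_()
        logp[(pname, d)] = -np.log10(res.pvalue)
        hits = significant_hits(res, cfg.assoc_alpha)
        for m in np.flatnonzero(res.analysed):
            assoc_rows.append(
                {"panel": pname, "depth": d, "site": m, "pos": positions[m],
                 "beta": res.beta[m], "se": res.se[m], "p": res.pvalue[m]}
            )
        hit_rows.append(
            {"panel": pname, "depth": d, "n_hits": hits.size,
             "hits": ",".join(map(str, hits))}
        )
    assoc_table = pd.DataFrame(assoc_rows)
    hits_table = pd.DataFrame(hit_rows)

    # ----- XP-EHH (population A = controls, population B = cases)
    logger.info("xp-ehh")
    ctrl = truth.phenotype == 0
    case = ~ctrl
    xpehh_rows, sig_rows = [], []
    zvec = {}
    for (pname, d), cs in callsets.items():
        hapsA = np.vstack([cs.phased[ctrl, :, 0], cs.phased[ctrl, :, 1]])
        hapsB = np.vstack([cs.phased[case, :, 0], cs.phased[case, :, 1]])
        res = sel.xpehh_scan(
            hapsA, hapsB, positions,
            maf_cutoff=cfg.xpehh_maf, ehh_cutoff=cfg.ehh_cutoff,
            max_extension_sites=cfg.max_extension_sites,
        )
        zvec[(pname, d)] = res.z
        pos_idx, neg_idx = sel.significant_z(res.z, cfg.z_threshold)
        sig_rows.append(
            {"panel": pname, "depth": d, "n_pos": pos_idx.size, "n_neg": neg_idx.size}
        )
        for m in np.flatnonzero(res.included):
            xpehh_rows.append(
                {"panel": pname, "depth": d, "site": m, "pos": positions[m],
                 "ihh_a": res.ihh_a[m], "ihh_b": res.ihh_b[m],
                 "xpehh": res.raw[m], "z": res.z[m]}
            )
    xpehh_table = pd.DataFrame(xpehh_rows)
    xpehh_sig_table = pd.DataFrame(sig_rows)

    # ----- cross-depth correlation suites (vs the top depth, per panel)
    corr_rows = []
    for metric, vecs in (("assoc_logp", logp), ("xpehh_z", zvec)):
        for pname in panels:
            by_depth = {d: vecs[(pname, d)] for d in cfg.depths}
            summary, _ = dg.correlation_suite(by_depth, top)
            for _, row in summary.iterrows():
                corr_rows.append(
                    {"metric": metric, "panel": pname, "depth": row["depth"],
                     "r": row["r"], "r2": row["r2"], "n": row["n"]}
                )
    corr_table = pd.DataFrame(corr_rows)

    # ----- haplotype-consistency diagnostics (full-panel callsets)
    logger.info("diagnostics: %d regions", cfg.n_regions)
    regions = dg.sample_regions(
        positions, cfg.n_regions, cfg.variants_per_region,
        seed=stage_seed(cfg.seed, "regions"),
    )
    depth_callsets = [callsets[("full", d)] for d in cfg.depths]
    hap_counts = dg.region_haplotype_table(depth_callsets, regions)
    med_counts = hap_counts.groupby("region")["n_haplotypes"].median()

    wilcox = np.empty((regions.n_regions, len(cfg.depths)))
    for di, d in enumerate(cfg.depths):
        pu = pileups[d]
        depth_mat = pu.depth
        cs_depth = np.cumsum(depth_mat, axis=1, dtype=float)
        chrom_mean = depth_mat.mean(axis=1)
        for r in range(regions.n_regions):
            s = regions.start_index[r]
            e = s + cfg.variants_per_region
            seg = (cs_depth[:, e - 1] - (cs_depth[:, s - 1] if s else 0.0)) / cfg.variants_per_region
            diff = seg - chrom_mean
            if np.all(diff == 0):
                wilcox[r, di] = 1.0
            else:
                from scipy.stats import wilcoxon
                wilcox[r, di] = wilcoxon(diff, zero_method="wilcox", method="approx").pvalue
    region_z = np.full((regions.n_regions, len(cfg.depths)), np.nan)
    for di, d in enumerate(cfg.depths):
        z = zvec[("full", d)]
        for r in range(regions.n_regions):
            s = regions.start_index[r]
            zz = z[s : s + cfg.variants_per_region]
            zz = zz[np.isfinite(zz)]
            if zz.size:
                region_z[r, di] = np.median(zz)

    depressed = region_profile < 1.0
    region_rows = []
    for r in range(regions.n_regions):
        sites = regions.sites(r)
        mc = med_counts.get(r, np.nan)
        region_rows.append(
            {
                "region": r,
                "start_bp": regions.start_bp[r],
                "end_bp": regions.end_bp[r],
                "size_bp": regions.size_bp[r],
                "n_variants": cfg.variants_per_region,
                "median_haplotypes": mc,
                "haps_rounded_up": int(np.ceil(mc)) if np.isfinite(mc) else -1,
                "flagged": bool(np.isfinite(mc) and np.ceil(mc) >= cfg.haplotype_flag_threshold),
                "wilcox_p_median": float(np.median(wilcox[r])),
                "median_z": float(np.nanmedian(region_z[r])) if np.isfinite(region_z[r]).any() else np.nan,
                "frac_depressed": float(depressed[sites].mean()),
            }
        )
    region_table = pd.DataFrame(region_rows)

    # ----- 1-Mb window metrics
    win_callsets = {d: callsets[("full", d)] for d in cfg.depths}
    win_z = {d: zvec[("full", d)] for d in cfg.depths}
    window_table = dg.window_metrics(
        win_callsets, validation, pileups, win_z, positions,
        ref_post=callsets[("full", top)],
        window_bp=cfg.window_bp, trim_quantiles=cfg.trim_quantiles,
    )

    # ----- regression suite
    regress_rows = []
    ok = maf_table.dropna(subset=["r2"]).copy()
    if len(ok) > 4:
        ok["maf_mid"] = (ok["bin_low"] + ok["bin_high"]) / 2
        fit = dg.ols_regress(
            ok["r2"].values,
            ok[["maf_mid", "depth", "panel"]].rename(columns={"maf_mid": "MAF"}),
        )
        for name, row in fit["table"].iterrows():
            regress_rows.append({"model": "r2~MAF+depth+panel", "term": name, **row})
    if len(site_table) > 4:
        fit = dg.ols_regress(site_table["r2"].values, site_table[["depth", "panel"]])
        for name, row in fit["table"].iterrows():
            regress_rows.append({"model": "dosage_r2~depth+panel", "term": name, **row})
    valid = region_table[region_table["haps_rounded_up"] > 0]
    if len(valid) > 4 and valid["haps_rounded_up"].nunique() > 1:
        fit = dg.ols_regress(
            valid["wilcox_p_median"].values,
            valid[["haps_rounded_up"]].rename(columns={"haps_rounded_up": "haps"}),
        )
        for name, row in fit["table"].iterrows():
            regress_rows.append({"model": "p~haps", "term": name, **row})
    regress_table = pd.DataFrame(regress_rows)

    tables = {
        "pre_imputation": pre_table,
        "concordance": conc_table,
        "maf_r2": maf_table,
        "dosage_r2_sites": site_table,
        "association": assoc_table,
        "assoc_hits": hits_table,
        "xpehh": xpehh_table,
        "xpehh_significant": xpehh_sig_table,
        "correlations": corr_table,
        "regions": region_table,
        "region_haplotypes": hap_counts,
        "windows": window_table,
        "regressions": regress_table,
    }
    report = ExperimentReport(config=cfg, tables=tables)
    if keep_objects:
        report.objects = {
            "panels": panels,
            "truth": truth,
            "pileups": pileups,
            "callsets": callsets,
            "validation": validation,
            "regions": regions,
            "region_profile": region_profile,
            "zvec": zvec,
            "logp": logp,
        }
    if outdir is not None:
        report.write(outdir)
        logger.info("report written to %s", outdir)
    return report
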