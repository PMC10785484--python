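# haplopass

Desk-scale evaluation of **low-pass whole-genome sequencing with
reference-panel imputation**, focused on a question that per-site
concordance metrics cannot answer: *how consistent are the phased
haplotypes that imputation produces?*

Low-pass sequencing (≲4X) recovers genotypes by combining shallow read
pileups with a panel of phased reference haplotypes: per-site genotype
likelihoods are fed to a haplotype-copying model that imputes and phases
every sample. The approach is attractive wherever sample sizes are limited
and pedigrees unavailable — companion-animal genetics being a canonical
example — but any downstream analysis built on *haplotypes* (extended
haplotype homozygosity scans, haplotype-based association) inherits the
phasing errors that per-variant dosage metrics never see.

`haplopass` builds the whole evaluation loop synthetically, so every claim
can be checked against known truth:

- **simulate** — a breed-structured phased reference panel (founder-mosaic
  model), a target cohort whose true diplotypes are mosaics of one breed's
  panel haplotypes plus private alleles the panel has never seen, a fully
  penetrant recessive phenotype (6 cases / 30 individuals by default), read
  pileups at mean depths {0.9, 3.8, 9.6, 17.4, 43.5}X with planted
  low-coverage segments, and binomial read thinning.
- **likelihoods** — genotype likelihoods `L(g | a ref, b alt) ∝ (1−q_g)^a q_g^b`
  with `q_g = (g/2)(1−ε) + (1−g/2)ε`, and naive maximum-likelihood calls.
- **impute** — an exact diploid Li–Stephens HMM over ordered pairs of panel
  haplotypes (`LiStephensImputer`, sklearn-style `fit(panel)` /
  `transform(gl)`): forward–backward genotype posteriors (GP), dosages
  `GP₁ + 2·GP₂`, IMPUTE-style INFO scores, Viterbi (or seeded
  posterior-sampled) phasing, chunked imputation with overlap ligation, and
  GP < 0.95 masking.
- **concordance** — genotype discordance, non-reference discordance
  (NRD = errors / (errors + non-reference agreements)), MAF-binned and
  pooled dosage r², per-truth-class mismatch rates, same-label haplotype
  discordance, and switch-error rates.
- **association** — EMMAX-style linear mixed model (`LinearMixedModel`)
  with a centred GRM, sex covariate, REML variance components and per-site
  GLS Wald tests.
- **selection** — EHH decay curves, trapezoid-integrated iHH, and the
  cross-population statistic XP-EHH `ln(iHH_A/iHH_B)` standardised to
  genome-wide Z-scores.
- **diagnostics** — the haplotype-consistency suite: sample fixed-size
  genomic regions, count the distinct phased haplotype strings each
  individual shows *across* the depth grid (a consistent pipeline can only
  show 1 or 2), paired Wilcoxon tests of regional vs chromosome depth, 1-Mb
  window metrics, and the supporting OLS regressions and correlation
  tables.

## Worked example

```python
from haplopass import ExperimentConfig, run_experiment

cfg = ExperimentConfig(seed=7, n_sites=800, n_regions=1000)
report = run_experiment(cfg)

conc = report.tables["concordance"]
print(conc[conc["panel"] == "full"][
    ["depth", "discordance", "nrd", "dosage_r2", "masked_rate"]
].to_string(index=False))
```

```
 depth  discordance      nrd  dosage_r2  masked_rate
   0.9     0.003939 0.009430   0.993778     0.043792
   3.8     0.001042 0.003166   0.997679     0.012250
   9.6     0.000052 0.000599   0.999612     0.005917
  17.4     0.000000 0.000000   0.999998     0.001792
  43.5     0.000000 0.000000   1.000000     0.000042
```

Per-site accuracy is excellent from ~4X up: at 3.8X only 0.1% of
genotypes disagree with the high-depth validation calls and dosage r²
is 0.998. The haplotype picture is very different:

```python
hap = report.tables["region_haplotypes"]["n_haplotypes"].dropna()
print(hap.median(), hap.ge(8).mean())
```

```
6.0 0.224
```

Across the five depth datasets an individual should show at most two
distinct haplotypes in any region; the median here is 6 and 22% of
region × individual cells show eight or more (this small 800-site run is
noisier than the 2,000-site default, which gives median 4 and a ~5%
tail). Cross-depth correlation of the mixed-model −log₁₀(p) vectors tells
the same story from the association side — single-marker results are robust
at moderate depth while the lowest depth degrades:

```
 depth        r
   0.9 0.569796
   3.8 0.624320
   9.6 0.919463
  17.4 0.955632
  43.5 1.000000
```

The same pipeline is exposed as a CLI:

```bash
haplopass run-all --seed 7 --outdir runs/demo        # full report bundle
haplopass simulate --seed 7 --outdir runs/sim        # VCF + pileup artifacts
```

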