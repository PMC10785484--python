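# Methods

This note records the models behind `haplopass`, the defaults and why they
were chosen, and the boundaries of what the synthetic evaluation can show.

## Synthetic data model

**Reference panel.** The panel is a founder-mosaic model, not a coalescent
simulation: one ancestral 0/1 string is mutated independently at rate
`founder_div` (default 0.2) into one founder per breed; each panel
haplotype then copies its breed founder, switching source at
`recomb_switch_rate` per bp (default 5·10⁻⁷; at a switch the home founder
is re-chosen with probability 0.75, otherwise a random other founder), with
private flips at `mutation_rate` (default 0.01 per site). This produces
what the downstream analyses actually require — haplotype sharing within
and between breeds and a realistic allele-frequency spectrum — without
modelling genealogies. Site positions are uniform draws on a single
20-Mb chromosome.

**Cohort.** True diplotypes are mosaics over the *target breed's* panel
haplotypes with switch rate `mosaic_switch_rate` (default 10⁻⁷ per bp,
≈ 2 switches per haplotype per chromosome), plus private alleles at
`private_allele_rate` (default 0.002 per site per haplotype) recorded in a
mask — these model variation absent from any reference panel, the known
worst case for imputation. A causal site is drawn among sites with panel
MAF in [0.15, 0.35] (keeping the locus imputable while a 6/30
homozygote-case configuration is achievable), and genotypes there are
overwritten — rather than rejection-sampled — so that exactly `n_cases`
individuals are homozygous for the alternate allele; the fully penetrant
recessive phenotype follows from that state. Sex is an independent fair
coin.

**Sequencing.** Read depth at cell (i, m) is Poisson with mean
`λ · region_profile[m] · indiv_profile[i]`; alternate-read counts are
binomial with error ε = 0.001 per base (a single symmetric error rate — no
base-quality spread, mapping error, or read-length correlation). Regional
structure comes only from `region_profile`: the default experiment plants
three 100-site segments at multiplier 0.5, emulating mappability-driven
coverage depressions. The depth grid replays the two real acquisition
mechanisms: 0.9X and 3.8X are independent sequencing runs (fresh Poisson
draws), while 9.6X and 17.4X are binomial thinnings of the 43.5X pileup
(retention d/43.5, so the 17.4X dataset retains 40% of top-depth reads) and
therefore share its read noise.

## Imputation model

The imputer is an exact diploid Li–Stephens HMM: the hidden state is an
*ordered pair* (j, k) of panel haplotypes being copied. Transitions
factorise per haplotype into `t(j→j') = (1−ρ_m)·[j=j'] + ρ_m/K` with
`ρ_m = 1 − exp(−recomb_rate · ne_scale · Δbp)`; physical distance is used
directly (no genetic map), with `ne_scale` defaulting to 10⁻⁷ per bp to
match the scale of the cohort mosaic process. Emissions combine the cell's
genotype-likelihood triplet with the genotype distribution implied by the
copied allele pair under a symmetric per-site copying error θ; the default
θ is the Watterson-style `t/(2(t+K))` with `t = 1/H_{K−1}`. Because the
transition kernel is separable, forward, backward and Viterbi all run in
O(K²) per site via row/column sums or maxima (numba-compiled), and the
K ≤ 512 cap keeps the exact state space tractable; a brute-force
path-enumeration oracle verifies the recursions to 10⁻¹⁰ on small
instances.

Phasing takes the Viterbi ordered-pair path by default — deterministic, so
concordance and diagnostic results are exactly reproducible. A seeded
posterior-sampling mode (`phase_method="sample"`, forward-filter
backward-sample) reproduces the run-to-run variability of stochastic
phasing tools when that phenomenon itself is under study. In either mode,
phased alleles are reconciled with the argmax-GP genotype (ties send the
alternate allele to haplotype A), and each individual's A/B labels are put
in a canonical gauge — haplotype A carries the alternate allele at the
first heterozygous site. The gauge is pure relabelling (diploid hap labels
carry no information), but it makes "same-label" haplotype comparisons
across independently produced callsets meaningful; without it, an arbitrary
per-individual orientation flip dominates every cross-dataset haplotype
metric.

Long chromosomes are imputed in `chunk_bp` windows extended by a 250-kb
overlap; each site's output comes from the chunk owning it, and haplotype
labelling is ligated across chunks by majority phase agreement over shared
heterozygous sites in the overlap. Genotype posteriors yield GP triplets,
dosage, a per-site IMPUTE-style INFO score
(`1 − Σ(f_i − e_i²)/(2Nθ̂(1−θ̂))`, defined as 1 for estimated-monomorphic
sites, clamped to [0, 1]), and a missing mask wherever max GP < 0.95.

## Analysis conventions

- **Concordance** counts only comparable cells (both calls present, depth
  gate passed, truth-certainty gate when truth carries GPs). Undefined
  rates are NaN-flagged, never silently zero. NRD excludes concordant
  hom-ref cells from its denominator. MAF bin edges default to
  (0, 0.001, 0.005, 0.01, 0.05, 0.1, 0.2, 0.5]; the printed r² per bin
  pools all cell pairs in the bin.
- **Association** is an EMMAX-style approximation: REML variance components
  estimated once under the null via the eigendecomposition of the centred
  GRM (grid search on log₁₀δ ∈ [−5, 5] then bounded refinement), then
  per-site GLS Wald tests with t-distributed statistics (df = n − q − 1).
  The binary phenotype is analysed as a quantitative trait; tests use
  imputed dosage by default (hard-call mode is a caller choice). With the
  random effect forced off, the tests reduce exactly to OLS — a tested
  closed-form limit.
- **XP-EHH** uses cores at every site with pooled MAF ≥ 0.05, EHH cutoff
  0.05, trapezoid integration against physical distance with linear
  interpolation to the exact cutoff crossing (truncation at the last
  at-or-above-cutoff point is switchable), one-sided integrals flagged at
  chromosome edges, and genome-wide (not frequency-binned)
  Z-standardisation. An optional `max_extension_sites` cap (400 in the
  default experiment) bounds the per-core scan; a capped side is treated
  like an edge truncation.
- **Haplotype counting** across depth datasets compares phased strings *as
  emitted*, with a GP-masked cell as its own symbol (mode `"symbol"`).
  This choice is deliberate: masking patterns are depth-dependent, and
  treating them as part of the emitted haplotype is what comparing written
  phased VCFs does. The stricter alternative — dropping positions masked
  in any depth (`"restrict"`) — systematically *removes* the unstable sites
  in low-coverage regions and thereby hides exactly the regional
  inconsistency the diagnostic exists to detect; it remains available as a
  mode. Regions are fixed variant-count (100 sites) windows sampled
  uniformly with replacement.
- **Wilcoxon** signed-rank tests drop zero differences and use the exact
  distribution when tie-free and small, the tie-corrected normal
  approximation otherwise (the bulk region scan uses the approximation
  throughout for speed). All-zero differences return p = 1 by convention.

## Default problem sizes

The default `ExperimentConfig` uses one 20-Mb chromosome with 2,000 sites,
a 40-haplotype full panel (5 breeds × 8), 24-haplotype target-enriched and
target-depleted subset panels (per-breed cap 2, at most one target diploid
in the depleted panel), 30 individuals with 6 cases, and 10,000 sampled
regions. These sizes keep the full five-depth × three-panel grid, the
ten-seed ordering properties, and the acceptance run within a few minutes
on a single CPU while leaving every analysed effect (depth orderings,
depression enrichment, causal-site recovery) clearly resolved; all sizes
are plain config fields, and a denser chromosome is a one-line change.

## What the generator does and does not emulate

It emulates the statistical structure the analyses rest on: haplotype
sharing with breed structure, panel-absent private variation, depth-scaled
genotype-likelihood informativeness, shared read noise between thinned
datasets, and regional coverage depressions. It does not emulate read
alignment or mappability (beyond the region multiplier), base-quality
variation, INDELs or multi-allelic sites, linked-read or pedigree phasing
information, genetic-map heterogeneity, or reference-panel phasing errors
(panel haplotypes are true haplotypes). Consequently, passing tests
demonstrate correctness and internal consistency of the *methods* under a
controlled generative model — they do not certify accuracy levels on real
sequencing data, where panel mis-phasing and alignment artefacts add error
modes this model excludes by construction.

## Known limitations

- The exact K²-state HMM is quadratic in panel size; it is meant for
  panels up to a few hundred haplotypes, not biobank-scale panels (no PBWT
  acceleration, no iterative refinement).
- Variance components in the mixed model are estimated once under the null
  (EMMAX approximation) rather than per marker.
- The EMMAX REML profile is only weakly identified when the cohort kinship
  is near-identity; structured relatedness (as in the default breed cohort)
  is assumed.
- Binary phenotypes are treated as quantitative; no liability-scale model.
- Haplotype-based diagnostics depend on the masking threshold through the
  symbol-mode counting convention; the `restrict` mode answers a different,
  narrower question (consistency of confidently-called sites only).
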