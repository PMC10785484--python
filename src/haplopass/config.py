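"""Experiment configuration: depth grid, thresholds, simulator parameters.

The defaults encode the study conditions the pipeline evaluates: a
30-individual target cohort with a 6-case fully penetrant recessive
phenotype, sequencing depths {0.9, 3.8, 9.6, 17.4, 43.5}X (the two middle
depths produced by binomial thinning of the top-depth data, the low depths
by independent resequencing), three reference panels (full, target-enriched,
target-depleted), GP masking at 0.95, and the analysis cutoffs used
throughout (association MAF 0.01 and alpha 1e-6, XP-EHH MAF/EHH 0.05 and
|Z| > 4, per-depth minimum read depths {0.9:1, 3.8:2, 9.6:5, 17.4:10}).
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields

import yaml

__all__ = ["ExperimentConfig", "stage_seed"]


def stage_seed(base_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from a master seed (< 2^31)."""
    h = hashlib.sha256(f"{base_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


@dataclass
class ExperimentConfig:
    """All knobs of the end-to-end experiment, YAML round-trippable."""

    seed: int = 0

    # depth grid (X); ascending; the top depth is the validation dataset
    depths: tuple = (0.9, 3.8, 9.6, 17.4, 43.5)
    thinned_depths: tuple = (9.6, 17.4)  # derived by thinning the top depth
    min_depth_map: dict = field(
        default_factory=lambda: {0.9: 1, 3.8: 2, 9.6: 5, 17.4: 10, 43.5: 10}
    )

    # thresholds
    gp_threshold: float = 0.95
    assoc_maf: float = 0.01
    assoc_alpha: float = 1e-6
    xpehh_maf: float = 0.05
    ehh_cutoff: float = 0.05
    z_threshold: float = 4.0
    truth_certainty: float = 0.9999

    # panel simulator
    n_breeds: int = 5
    haps_per_breed: int = 8
    n_sites: int = 2000
    chrom_length_bp: int = 20_000_000
    founder_div: float = 0.2
    mutation_rate: float = 0.01
    recomb_switch_rate: float = 5e-7
    target_breed: str = "breed0"
    subset_diploids: int = 12
    subset_max_per_breed: int = 2

    # cohort simulator
    n_individuals: int = 30
    n_cases: int = 6
    mosaic_switch_rate: float = 1e-7
    private_allele_rate: float = 0.002
    causal_maf_range: tuple = (0.15, 0.35)

    # sequencing
    epsilon: float = 0.001
    n_depressed_segments: int = 3
    depressed_segment_sites: int = 100
    depressed_multiplier: float = 0.5

    # copying-model (imputation) parameters
    recomb_rate: float = 1.0
    ne_scale: float = 1e-7
    mismatch_theta: float | None = None
    chunk_bp: float = 20e6
    chunk_overlap_bp: float = 250_000.0
    # "viterbi" is fully deterministic; "sample" reproduces the run-to-run
    # variability of stochastic phasing tools (seeded)
    phase_method: str = "viterbi"

    # diagnostics
    n_regions: int = 10_000
    variants_per_region: int = 100
    window_bp: float = 1e6
    trim_quantiles: tuple = (0.01, 0.99)
    haplotype_flag_threshold: int = 8
    max_extension_sites: int | None = 400

    def validate(self) -> None:
        if list(self.depths) != sorted(self.depths):
            raise ValueError("depth grid must be ascending")
        if not 0 < self.gp_threshold <= 1:
            raise ValueError("gp_threshold must lie in (0, 1]")
        for name in ("assoc_maf", "xpehh_maf"):
            v = getattr(self, name)
            if not 0 <= v < 0.5:
                raise ValueError(f"{name} must lie in [0, 0.5)")
        if not 0 < self.ehh_cutoff < 1:
            raise ValueError("ehh_cutoff must lie in (0, 1)")
        if self.z_threshold < 0:
            raise ValueError("z_threshold must be non-negative")
        if self.phase_method not in ("viterbi", "sample"):
            raise ValueError("phase_method must be 'viterbi' or 'sample'")
        for d in self.depths:
            if d not in self.min_depth_map:
                raise ValueError(f"min_depth_map lacks an entry for depth {d}")
        for d in self.thinned_depths:
            if d >= self.top_depth:
                raise ValueError("thinned depths must be below the top depth")

    @property
    def top_depth(self) -> float:
        return self.depths[-1]

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["depths"] = list(self.depths)
        d["thinned_depths"] = list(self.thinned_depths)
        d["causal_maf_range"] = list(self.causal_maf_range)
        d["trim_quantiles"] = list(self.trim_quantiles)
        d["min_depth_map"] = {str(k): v for k, v in self.min_depth_map.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("depths", "thinned_depths", "causal_maf_range", "trim_quantiles"):
            if key in d:
                d[key] = tuple(d[key])
        if "min_depth_map" in d:
            d["min_depth_map"] = {float(k): int(v) for k, v in d["min_depth_map"].items()}
        cfg = cls(**d)
        cfg.validate()
        return cfg
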