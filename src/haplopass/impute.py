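"""Reference-panel genotype imputation and phasing via a diploid Li-Stephens HMM.

The imputer treats each target individual as copying an ordered pair of
reference-panel haplotypes, with per-haplotype switch probability derived
from physical distance and a symmetric per-site copying error.  Posterior
genotype probabilities (GP), dosages, and a per-site imputation INFO score
come from the exact forward-backward recursion; phased alleles come from the
Viterbi ordered-pair path, which is deterministic.  Genotypes whose maximum
GP falls below a threshold are masked as missing.

The estimator surface is sklearn-style: ``LiStephensImputer().fit(panel)``
learns nothing statistical (the panel *is* the prior) but freezes the panel
and derived parameters; ``transform(gl)`` produces an :class:`ImputedCallset`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import _hmm
from .likelihoods import GenotypeLikelihoods
from .simulate import HaplotypePanel

__all__ = [
    "LSParams",
    "ImputedCallset",
    "LiStephensImputer",
    "ls_posteriors",
    "impute_phase",
    "info_score",
    "mask_low_gp",
]

MAX_PANEL_HAPLOTYPES = 512  # exact K^2-state HMM is the desk-scale regime


@dataclass
class LSParams:
    """Parameters of the haplotype-copying process.

    ``rho_m = 1 - exp(-recomb_rate * ne_scale * gap_bp)`` is the per-gap
    switch probability; ``mismatch_theta`` is the per-site copying-error
    probability (``None`` selects the Watterson-style default
    ``t / (2 (t + K))`` with ``t = 1 / H_{K-1}``).
    """

    recomb_rate: float = 1.0
    mismatch_theta: float | None = None
    ne_scale: float = 1e-7

    def validate(self) -> None:
        if self.recomb_rate <= 0 or self.ne_scale <= 0:
            raise ValueError("recomb_rate and ne_scale must be positive")
        if self.mismatch_theta is not None and not 0 < self.mismatch_theta < 0.5:
            raise ValueError("mismatch_theta must lie in (0, 0.5)")

    def theta_for(self, n_haplotypes: int) -> float:
        if self.mismatch_theta is not None:
            return self.mismatch_theta
        t = 1.0 / np.sum(1.0 / np.arange(1, n_haplotypes))
        return float(t / (2.0 * (t + n_haplotypes)))

    def rho(self, positions: np.ndarray) -> np.ndarray:
        gap = np.diff(positions).astype(float)
        return 1.0 - np.exp(-self.recomb_rate * self.ne_scale * gap)


@dataclass
class ImputedCallset:
    """Imputed, phased genotypes with posterior quality annotations."""

    phased: np.ndarray         # (N, M, 2) alleles {0, 1}
    gp: np.ndarray             # (N, M, 3) posterior triplets
    dosage: np.ndarray         # (N, M) = GP1 + 2 * GP2
    info: np.ndarray           # (M,) imputation INFO score in [0, 1]
    missing: np.ndarray        # (N, M) bool, True once GP-masked
    panel_af_used: np.ndarray  # (M,) allele frequency of the imputation panel
    positions: np.ndarray      # (M,) bp

    @property
    def genotypes(self) -> np.ndarray:
        """Hard calls from phased alleles, (N, M) in {0, 1, 2}."""
        return self.phased.sum(axis=-1).astype(np.int8)

    @property
    def n_individuals(self) -> int:
        return self.phased.shape[0]


def ls_posteriors(
    gl_row: np.ndarray,
    panel: HaplotypePanel,
    params: LSParams | None = None,
    return_state_posteriors: bool = False,
):
    """Forward-backward posteriors for a single individual.

    Parameters
    ----------
    gl_row : (M, 3) normalised genotype-likelihood triplets.
    panel : reference haplotypes conditioning the copying process.
    params : copying-process parameters; defaults to :class:`LSParams`.

    Returns ``(genotype_posteriors, loglik)`` of shapes ``(M, 3)`` and
    scalar, plus ``(M, K, K)`` ordered-pair state posteriors when requested
    (intended for small problems and oracle checks).
    """
    params = params or LSParams()
    params.validate()
    K = panel.n_haplotypes
    if K > MAX_PANEL_HAPLOTYPES:
        raise ValueError(
            f"panel has {K} haplotypes; the exact K^2-state HMM is capped at "
            f"{MAX_PANEL_HAPLOTYPES} — subset the panel or chunk by region"
        )
    gl = np.asarray(gl_row, float)[None]
    rho = params.rho(panel.positions)
    theta = params.theta_for(K)
    out = _hmm.forward_backward(
        gl, panel.alleles, rho, theta, return_state_posteriors=return_state_posteriors
    )
    if return_state_posteriors:
        gp, loglik, post = out
        return gp[0], float(loglik[0]), post[0]
    gp, loglik = out
    return gp[0], float(loglik[0])


def _phase_block(
    gl: np.ndarray,
    alleles: np.ndarray,
    positions: np.ndarray,
    params: LSParams,
    phase_method: str = "viterbi",
    phase_seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Run FB + phasing for a block of individuals over one site range."""
    K = alleles.shape[0]
    rho = params.rho(positions)
    theta = params.theta_for(K)
    gp, _ = _hmm.forward_backward(gl, alleles, rho, theta)
    if phase_method == "viterbi":
        path = _hmm.viterbi(gl, alleles, rho, theta)
    elif phase_method == "sample":
        path = _hmm.sample_paths(gl, alleles, rho, theta, phase_seed)
    else:
        raise ValueError("phase_method must be 'viterbi' or 'sample'")
    hapA = alleles[path[:, :, 0], np.arange(positions.size)[None, :]]
    hapB = alleles[path[:, :, 1], np.arange(positions.size)[None, :]]
    phased = np.stack([hapA, hapB], axis=-1).astype(np.int8)
    # reconcile phased alleles with the argmax-GP genotype so downstream
    # hard calls and phase agree
    ghat = gp.argmax(axis=-1)
    gsum = phased.sum(axis=-1)
    fix = gsum != ghat
    hom0 = fix & (ghat == 0)
    hom2 = fix & (ghat == 2)
    het = fix & (ghat == 1)
    phased[hom0] = 0
    phased[hom2] = 1
    # a het disagreeing with the copied pair had (0,0) or (1,1) copied, so
    # neither haplotype is favoured: the alt goes on haplotype A (deterministic)
    phased[het] = [1, 0]
    return phased, gp


def _choose_block(n: int, K: int, m: int, budget_bytes: float = 1.5e9) -> int:
    per_indiv = m * K * K * 8.0 * 2.5  # forward store + viterbi codes
    block = max(1, int(budget_bytes // max(per_indiv, 1.0)))
    if per_indiv > budget_bytes:
        raise MemoryError(
            "K^2 x M workspace exceeds the configured cap for a single "
            "individual; impute in smaller genomic chunks (reduce chunk_bp)"
        )
    return min(n, block)


def impute_phase(
    gl: GenotypeLikelihoods,
    panel: HaplotypePanel,
    params: LSParams | None = None,
    chunk_bp: float = 20e6,
    chunk_overlap_bp: float = 250_000.0,
    gp_threshold: float | None = None,
    phase_method: str = "viterbi",
    phase_seed: int = 0,
) -> ImputedCallset:
    """Impute and phase all individuals, chunking long chromosomes.

    Chunks of ``chunk_bp`` (extended by ``chunk_overlap_bp`` on each side)
    are imputed independently; each site's output comes from the chunk whose
    core interval owns it, and haplotype labelling is ligated across chunks
    by matching phase over the overlap.  With ``gp_threshold`` set, cells
    whose maximum GP falls below it are masked (see :func:`mask_low_gp`).

    ``phase_method`` selects the phasing rule: ``"viterbi"`` (deterministic
    most-probable copying path) or ``"sample"`` (one seeded draw from the
    posterior over copying paths, reproducing the run-to-run variability of
    stochastic phasing tools).
    """
    params = params or LSParams()
    params.validate()
    if gl.n_sites != panel.n_sites or gl.n_sites == 0:
        raise ValueError("GL matrix and panel must share the site list")
    N, M = gl.depth.shape
    K = panel.n_haplotypes
    if K > MAX_PANEL_HAPLOTYPES:
        raise ValueError(
            f"panel has {K} haplotypes; cap is {MAX_PANEL_HAPLOTYPES}"
        )
    pos = panel.positions
    span_start, span_end = int(pos[0]), int(pos[-1])
    chunk_bp = float(chunk_bp)

    # core intervals tile [span_start, span_end]
    n_chunks = max(1, int(np.ceil((span_end - span_start + 1) / chunk_bp)))
    phased = np.empty((N, M, 2), dtype=np.int8)
    gp = np.empty((N, M, 3))

    prev_ext_idx: np.ndarray | None = None
    prev_ext_phased: np.ndarray | None = None
    flip = np.zeros(N, dtype=bool)  # cumulative hap-label flip per individual
    block = _choose_block(N, K, M)

    for c in range(n_chunks):
        core_lo = span_start + c * chunk_bp
        core_hi = span_start + (c + 1) * chunk_bp
        ext_lo = core_lo - chunk_overlap_bp
        ext_hi = core_hi + chunk_overlap_bp
        ext_idx = np.flatnonzero((pos >= ext_lo) & (pos < ext_hi))
        own = np.flatnonzero((pos[ext_idx] >= core_lo) & (pos[ext_idx] < core_hi))
        if ext_idx.size == 0:
            continue
        sub_alleles = panel.alleles[:, ext_idx]
        sub_pos = pos[ext_idx]
        ph_ext = np.empty((N, ext_idx.size, 2), dtype=np.int8)
        gp_ext = np.empty((N, ext_idx.size, 3))
        for lo in range(0, N, block):
            hi = min(N, lo + block)
            ph_ext[lo:hi], gp_ext[lo:hi] = _phase_block(
                gl.gl[lo:hi][:, ext_idx], sub_alleles, sub_pos, params,
                phase_method=phase_method,
                phase_seed=phase_seed + 1000 * c + lo,
            )
        if prev_ext_idx is not None:
            # ligate: orient this chunk's haplotype labels to the previous
            # chunk's using het sites shared in the overlap
            shared, ia, ib = np.intersect1d(
                prev_ext_idx, ext_idx, return_indices=True
            )
            for i in range(N):
                prev_ph = prev_ext_phased[i][ia]
                if flip[i]:
                    prev_ph = prev_ph[:, ::-1]
                cur_ph = ph_ext[i][ib]
                het = (prev_ph[:, 0] != prev_ph[:, 1]) & (cur_ph[:, 0] != cur_ph[:, 1])
                if het.any():
                    same = np.sum(prev_ph[het, 0] == cur_ph[het, 0])
                    swapped = het.sum() - same
                    flip[i] = swapped > same
                # else: keep previous orientation
        out_idx = ext_idx[own]
        ph_own = ph_ext[:, own]
        for i in range(N):
            phased[i, out_idx] = ph_own[i][:, ::-1] if flip[i] else ph_own[i]
        gp[:, out_idx] = gp_ext[:, own]
        prev_ext_idx = ext_idx
        prev_ext_phased = ph_ext.copy()

    # canonical label gauge: haplotype A carries the alternate allele at the
    # individual's first heterozygous site.  The A/B labelling of a diploid
    # is arbitrary; fixing it deterministically makes emitted labels
    # comparable across datasets without touching relative phase.
    het = phased[..., 0] != phased[..., 1]
    for i in range(N):
        idx = np.flatnonzero(het[i])
        if idx.size and phased[i, idx[0], 0] == 0:
            phased[i] = phased[i, :, ::-1]

    dosage = gp[..., 1] + 2.0 * gp[..., 2]
    callset = ImputedCallset(
        phased=phased,
        gp=gp,
        dosage=dosage,
        info=np.array([info_score(gp[:, m]) for m in range(M)]),
        missing=np.zeros((N, M), dtype=bool),
        panel_af_used=panel.panel_af.copy(),
        positions=pos.copy(),
    )
    if gp_threshold is not None:
        callset = mask_low_gp(callset, gp_threshold)
    return callset


def info_score(gp_site: np.ndarray) -> float:
    """IMPUTE-style INFO score for one site from its GP triplets.

    With expected dosage ``e_i = GP1 + 2 GP2`` and second moment
    ``f_i = GP1 + 4 GP2``, the score is
    ``1 - sum(f_i - e_i^2) / (2 N p (1 - p))`` where ``p`` is the estimated
    allele frequency ``sum(e_i) / 2N``; it is 1 by convention when the site
    is estimated monomorphic, and clamped to [0, 1].
    """
    gp_site = np.asarray(gp_site, float)
    if gp_site.ndim != 2 or gp_site.shape[0] < 1:
        raise ValueError("need GP triplets for at least one individual")
    e = gp_site[:, 1] + 2.0 * gp_site[:, 2]
    f = gp_site[:, 1] + 4.0 * gp_site[:, 2]
    n = gp_site.shape[0]
    theta = e.sum() / (2.0 * n)
    if theta <= 0.0 or theta >= 1.0:
        return 1.0
    info = 1.0 - np.sum(f - e**2) / (2.0 * n * theta * (1.0 - theta))
    return float(min(1.0, max(0.0, info)))


def mask_low_gp(callset: ImputedCallset, gp_threshold: float = 0.95) -> ImputedCallset:
    """Mask genotypes whose maximum GP falls below the threshold.

    Phased alleles at masked cells are retained internally (downstream
    operations decide whether to use them); the ``missing`` flag is the
    contract.
    """
    if not 0.0 < gp_threshold <= 1.0:
        raise ValueError("gp_threshold must lie in (0, 1]")
    missing = callset.gp.max(axis=-1) < gp_threshold
    return replace(callset, missing=callset.missing | missing)


class LiStephensImputer(BaseEstimator, TransformerMixin):
    """Sklearn-style wrapper around the diploid copying-model imputer.

    ``fit`` freezes the reference panel (the imputation prior) and the
    derived copying parameters; ``transform`` maps a
    :class:`~haplopass.likelihoods.GenotypeLikelihoods` object to an
    :class:`ImputedCallset`.

    Parameters
    ----------
    recomb_rate, ne_scale : copying-switch intensity per bp (their product).
    mismatch_theta : per-site copying error; ``None`` = Watterson-style default.
    chunk_bp, chunk_overlap_bp : imputation window size and ligation overlap.
    gp_threshold : max-GP masking threshold applied after imputation
        (``None`` disables masking).
    phase_method, phase_seed : ``"viterbi"`` (deterministic) or ``"sample"``
        (one seeded posterior draw per individual).
    """

    def __init__(
        self,
        recomb_rate: float = 1.0,
        ne_scale: float = 1e-7,
        mismatch_theta: float | None = None,
        chunk_bp: float = 20e6,
        chunk_overlap_bp: float = 250_000.0,
        gp_threshold: float | None = 0.95,
        phase_method: str = "viterbi",
        phase_seed: int = 0,
    ):
        self.recomb_rate = recomb_rate
        self.ne_scale = ne_scale
        self.mismatch_theta = mismatch_theta
        self.chunk_bp = chunk_bp
        self.chunk_overlap_bp = chunk_overlap_bp
        self.gp_threshold = gp_threshold
        self.phase_method = phase_method
        self.phase_seed = phase_seed

    def fit(self, X: HaplotypePanel, y=None) -> "LiStephensImputer":
        X.validate()
        self.panel_ = X
        self.params_ = LSParams(
            recomb_rate=self.recomb_rate,
            mismatch_theta=self.mismatch_theta,
            ne_scale=self.ne_scale,
        )
        self.params_.validate()
        self.theta_ = self.params_.theta_for(X.n_haplotypes)
        return self

    def transform(self, X: GenotypeLikelihoods) -> ImputedCallset:
        if not hasattr(self, "panel_"):
            raise RuntimeError("imputer is not fitted; call fit(panel) first")
        return impute_phase(
            X,
            self.panel_,
            self.params_,
            chunk_bp=self.chunk_bp,
            chunk_overlap_bp=self.chunk_overlap_bp,
            gp_threshold=self.gp_threshold,
            phase_method=self.phase_method,
            phase_seed=self.phase_seed,
        )
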