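"""Genotype likelihoods from read pileups, and naive per-site calls.

The likelihood model is the standard symmetric single-error-rate one: a read
is alternate with probability ``q_g = (g/2)(1-eps) + (1-g/2) eps`` under true
genotype ``g``, so ``L(g | a ref, b alt) ∝ (1-q_g)^a q_g^b``.  Likelihoods
are computed in log space and normalised to sum to one per cell; cells with
no reads carry the uninformative triplet (1/3, 1/3, 1/3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .simulate import ReadPileup

__all__ = ["GenotypeLikelihoods", "pileup_to_gl", "naive_calls", "MISSING"]

MISSING = -1  # genotype code for "no call"


@dataclass
class GenotypeLikelihoods:
    """Normalised genotype likelihood triplets (order RR, RA, AA)."""

    gl: np.ndarray     # (N, M, 3) floats, each triplet sums to 1
    depth: np.ndarray  # (N, M) ints

    @property
    def n_individuals(self) -> int:
        return self.gl.shape[0]

    @property
    def n_sites(self) -> int:
        return self.gl.shape[1]


def pileup_to_gl(pileup: ReadPileup) -> GenotypeLikelihoods:
    """Convert read counts to normalised genotype likelihood triplets."""
    eps = pileup.epsilon
    if not 0.0 < eps < 0.5:
        raise ValueError("epsilon must lie in (0, 0.5)")
    a = pileup.ref_count
    b = pileup.alt_count
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("read counts must be non-negative")
    q = np.array([eps, 0.5, 1.0 - eps])  # P(alt read | g) for g = 0, 1, 2
    logl = (
        a[..., None] * np.log1p(-q)[None, None, :]
        + b[..., None] * np.log(q)[None, None, :]
    )
    gl = np.exp(logl - logsumexp(logl, axis=-1, keepdims=True))
    return GenotypeLikelihoods(gl=gl, depth=(a + b).astype(np.int64))


def naive_calls(gl: GenotypeLikelihoods, min_depth: int = 1) -> np.ndarray:
    """Per-cell maximum-likelihood genotype calls.

    Returns an (N, M) int8 matrix in {0, 1, 2, MISSING}.  A cell is missing
    when its depth is below ``min_depth`` or its triplet is uninformative
    (uniform).  Ties break toward the lower genotype index, i.e. toward the
    reference; such cells carry no read information and are masked anyway.
    """
    if min_depth < 0:
        raise ValueError("min_depth must be >= 0")
    calls = np.argmax(gl.gl, axis=-1).astype(np.int8)
    uniform = np.ptp(gl.gl, axis=-1) < 1e-12
    calls[uniform | (gl.depth < min_depth)] = MISSING
    return calls
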