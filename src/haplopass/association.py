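"""Single-marker mixed-model association on imputed genotypes.

The model is ``y = W a + x b + u + e`` with ``u ~ N(0, sg2 K)`` for a
genomic-relationship kinship ``K`` and covariates ``W`` (intercept + sex).
Variance components are estimated once by REML under the null via the
eigendecomposition of ``K`` (the EMMAX approximation), after which every
site gets a generalised-least-squares Wald test for ``b``.  The binary
phenotype is analysed as quantitative, as linear mixed models applied to
case/control GWAS do.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator

__all__ = [
    "AssociationResult",
    "kinship_matrix",
    "maf_filter",
    "LinearMixedModel",
    "lmm_assoc",
    "significant_hits",
    "RemlError",
]


class RemlError(RuntimeError):
    """REML failed to locate an interior or boundary optimum.

    Carries the profiled-likelihood grid evaluated during the search in
    ``grid`` (log10-delta, REML log-likelihood).
    """

    def __init__(self, msg: str, grid: np.ndarray):
        super().__init__(msg)
        self.grid = grid


@dataclass
class AssociationResult:
    """Per-site Wald statistics plus the fitted variance model."""

    beta: np.ndarray       # (M,), NaN where not analysed
    se: np.ndarray
    pvalue: np.ndarray
    analysed: np.ndarray   # (M,) bool
    sigma_g2: float
    sigma_e2: float
    kinship: np.ndarray
    covariates: np.ndarray


def kinship_matrix(genotypes: np.ndarray) -> np.ndarray:
    """Centred and scaled genomic relationship matrix (GRM).

    Columns are centred by ``2 p`` and scaled by ``sqrt(2 p (1 - p))`` with
    ``p`` the sample allele frequency; monomorphic sites are skipped;
    ``K = Gs Gs' / M_used``.
    """
    G = np.asarray(genotypes, float)
    p = G.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if poly.sum() < 2:
        raise ValueError("need at least two polymorphic sites for a kinship matrix")
    Gp = G[:, poly]
    pp = p[poly]
    Gs = (Gp - 2 * pp) / np.sqrt(2 * pp * (1 - pp))
    K = Gs @ Gs.T / poly.sum()
    return (K + K.T) / 2.0


def maf_filter(genotypes: np.ndarray, threshold: float = 0.01) -> np.ndarray:
    """Analysed mask: sample MAF >= threshold (inclusive) and polymorphic."""
    if not 0.0 <= threshold < 0.5:
        raise ValueError("threshold must lie in [0, 0.5)")
    G = np.asarray(genotypes, float)
    p = G.mean(axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    return (maf >= threshold) & (np.ptp(G, axis=0) > 0)


def _reml_loglik(log_delta: float, S: np.ndarray, Wt: np.ndarray, yt: np.ndarray) -> float:
    delta = 10.0 ** log_delta
    D = S + delta
    n, q = Wt.shape
    Dinv = 1.0 / D
    WtD = Wt * Dinv[:, None]
    A = Wt.T @ WtD
    alpha = np.linalg.solve(A, WtD.T @ yt)
    r = yt - Wt @ alpha
    rss = float(r @ (r * Dinv))
    sg2 = rss / (n - q)
    sign, logdetA = np.linalg.slogdet(A)
    if sign <= 0 or sg2 <= 0:
        return -np.inf
    return -0.5 * (
        (n - q) * (np.log(2 * np.pi * sg2) + 1.0)
        + np.sum(np.log(D))
        + logdetA
    )


class LinearMixedModel(BaseEstimator):
    """EMMAX-style linear mixed model for genome-wide single-marker tests.

    ``fit(X, y)`` takes an (N, M) genotype/dosage matrix and an (N,)
    phenotype; ``covariates`` (e.g. sex) are passed at construction or fit
    time and always include an intercept.  Variance components come from a
    single REML fit under the null; each analysed site then receives a GLS
    Wald test.

    Fitted attributes: ``beta_``, ``se_``, ``pvalues_``, ``analysed_``,
    ``sigma_g2_``, ``sigma_e2_``, ``delta_``, ``kinship_``.

    Parameters
    ----------
    maf_threshold : minimum sample MAF for a site to be analysed.
    force_sigma_g_zero : drop the random effect (GLS degenerates to OLS);
        mainly for validation against ordinary least squares.
    """

    def __init__(self, maf_threshold: float = 0.01, force_sigma_g_zero: bool = False):
        self.maf_threshold = maf_threshold
        self.force_sigma_g_zero = force_sigma_g_zero

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        covariates: np.ndarray | None = None,
        kinship: np.ndarray | None = None,
    ) -> "LinearMixedModel":
        G = np.asarray(X, float)
        y = np.asarray(y, float)
        n, M = G.shape
        W = np.ones((n, 1))
        if covariates is not None:
            C = np.atleast_2d(np.asarray(covariates, float))
            if C.shape[0] != n:
                C = C.T
            W = np.column_stack([W, C])
        if np.linalg.matrix_rank(W) < W.shape[1]:
            raise ValueError("covariate design is rank deficient")
        K = kinship_matrix(G) if kinship is None else np.asarray(kinship, float)

        S, U = np.linalg.eigh(K)
        S = np.maximum(S, 0.0)
        yt = U.T @ y
        Wt = U.T @ W

        if self.force_sigma_g_zero:
            delta = np.inf
            Dinv = np.ones(n)
            self.sigma_g2_, self.sigma_e2_ = 0.0, float(np.var(y))
        else:
            grid = np.linspace(-5.0, 5.0, 61)
            ll = np.array([_reml_loglik(g, S, Wt, yt) for g in grid])
            if not np.isfinite(ll).any():
                raise RemlError("REML likelihood undefined on the whole grid",
                                np.column_stack([grid, ll]))
            best = int(np.nanargmax(ll))
            lo = grid[max(best - 1, 0)]
            hi = grid[min(best + 1, len(grid) - 1)]
            res = optimize.minimize_scalar(
                lambda g: -_reml_loglik(g, S, Wt, yt), bounds=(lo, hi), method="bounded"
            )
            if not res.success:
                raise RemlError("REML optimiser failed",
                                np.column_stack([grid, ll]))
            delta = 10.0 ** res.x
            Dinv = 1.0 / (S + delta)
            WtD = Wt * Dinv[:, None]
            A = Wt.T @ WtD
            alpha = np.linalg.solve(A, WtD.T @ yt)
            r = yt - Wt @ alpha
            sg2 = float(r @ (r * Dinv)) / (n - W.shape[1])
            self.sigma_g2_, self.sigma_e2_ = sg2, sg2 * delta

        self.delta_ = float(delta)
        self.kinship_ = K
        self.covariates_ = W

        analysed = maf_filter(G, self.maf_threshold)
        beta = np.full(M, np.nan)
        se = np.full(M, np.nan)
        pval = np.full(M, np.nan)
        sqD = np.sqrt(Dinv)
        Wtw = Wt * sqD[:, None]
        ytw = yt * sqD
        Gt = (U.T @ G) * sqD[:, None]
        q = W.shape[1]
        df = n - q - 1
        for m in np.flatnonzero(analysed):
            Xm = np.column_stack([Wtw, Gt[:, m]])
            XtX = Xm.T @ Xm
            try:
                XtXi = np.linalg.inv(XtX)
            except np.linalg.LinAlgError:
                analysed[m] = False
                continue
            coef = XtXi @ (Xm.T @ ytw)
            resid = ytw - Xm @ coef
            s2 = float(resid @ resid) / df
            b = coef[-1]
            var_b = s2 * XtXi[-1, -1]
            if not np.isfinite(var_b) or var_b <= 0:
                analysed[m] = False
                continue
            sb = np.sqrt(var_b)
            t = b / sb
            beta[m] = b
            se[m] = sb
            pval[m] = 2.0 * stats.t.sf(abs(t), df)
        # guard the open-interval contract p in (0, 1]
        self.beta_, self.se_ = beta, se
        self.pvalues_ = np.clip(pval, np.finfo(float).tiny, 1.0)
        self.pvalues_[~analysed] = np.nan
        self.analysed_ = analysed
        return self

    def result_(self) -> AssociationResult:
        return AssociationResult(
            beta=self.beta_,
            se=self.se_,
            pvalue=self.pvalues_,
            analysed=self.analysed_,
            sigma_g2=self.sigma_g2_,
            sigma_e2=self.sigma_e2_,
            kinship=self.kinship_,
            covariates=self.covariates_,
        )


def lmm_assoc(
    genotypes: np.ndarray,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
    kinship: np.ndarray | None = None,
    maf_threshold: float = 0.01,
    force_sigma_g_zero: bool = False,
) -> AssociationResult:
    """Functional wrapper over :class:`LinearMixedModel`."""
    model = LinearMixedModel(
        maf_threshold=maf_threshold, force_sigma_g_zero=force_sigma_g_zero
    )
    model.fit(genotypes, phenotype, covariates=covariates, kinship=kinship)
    return model.result_()


def significant_hits(result: AssociationResult, alpha: float = 1e-6) -> np.ndarray:
    """Indices of analysed sites with p < alpha."""
    with np.errstate(invalid="ignore"):
        return np.flatnonzero(result.analysed & (result.pvalue < alpha))
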