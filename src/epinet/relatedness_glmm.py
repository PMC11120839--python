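"""Mixed-model association machinery: GRM, REML null fit, and score tests.

The null model is ``y = X beta + g + e`` with ``g ~ N(0, sigma_g2 K)`` and
``e ~ N(0, sigma_e2 I)``. Variance components are estimated by REML with
the heritability ratio ``h2 = sigma_g2 / (sigma_g2 + sigma_e2)`` profiled
on the eigenbasis of ``K`` — one O(n^3) eigendecomposition, then O(n)
likelihood evaluations inside a bounded 1-D search. Per-SNP association
uses the score test ``U = g' P y``, ``Var(U) = g' P g`` with the null
projection ``P = V^-1 - V^-1 X (X' V^-1 X)^-1 X' V^-1``, so the genome
scan costs one matrix-vector product per variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import GenotypeMatrix
from .errors import DataError, NumericalError

#: median of the chi-square(1) distribution, the null reference for lambda_GC
CHI2_1_MEDIAN = 0.4549364231195724

GENOME_WIDE_P = 5e-8
SUGGESTIVE_P = 1e-5


def compute_grm(G: GenotypeMatrix) -> np.ndarray:
    """Centered genetic relationship matrix ``K = W W' / m``.

    Column ``j`` of ``W`` is the mean-imputed dosage centered by ``2 p_j``
    with ``p_j`` the sample allele frequency — the "centered" estimator
    that is the default of the standard GRM tools. The expected diagonal
    is the mean ``2 p q`` over markers rather than 1.
    """
    if G.n_snps < 2:
        raise DataError("GRM needs at least two post-QC SNPs")
    W = G.imputed()
    W = W - W.mean(axis=0, keepdims=True)
    K = (W @ W.T) / G.n_snps
    return (K + K.T) / 2.0


@dataclass
class NullModel:
    """Fitted null GLMM, holding everything the score test needs."""

    beta_hat: np.ndarray
    sigma_g2_hat: float
    sigma_e2_hat: float
    h2_hat: float
    loglik: float
    P: np.ndarray | None  # projection operator for score tests
    Py: np.ndarray | None  # P @ y, cached
    X: np.ndarray
    y: np.ndarray


def _reml_neg_loglik(h2: float, s: np.ndarray, Xt: np.ndarray, yt: np.ndarray):
    """Negative REML log-likelihood profiled over the total variance."""
    n, p = Xt.shape
    d = h2 * s + (1.0 - h2)
    w = 1.0 / d
    XtW = Xt * w[:, None]
    XtWX = Xt.T @ XtW
    XtWy = XtW.T @ yt
    try:
        beta = np.linalg.solve(XtWX, XtWy)
    except np.linalg.LinAlgError as exc:
        raise NumericalError("collinear covariates in the null design") from exc
    r = yt - Xt @ beta
    rss = float(np.sum(w * r * r))
    sigma2 = rss / (n - p)
    sign, logdet_xtwx = np.linalg.slogdet(XtWX)
    if sign <= 0:
        raise NumericalError("X' V^-1 X not positive definite")
    nll = 0.5 * (
        (n - p) * (np.log(2.0 * np.pi * sigma2) + 1.0)
        + np.sum(np.log(d))
        + logdet_xtwx
    )
    return nll, beta, sigma2, w


def fit_null(
    y: np.ndarray,
    X: np.ndarray,
    K: np.ndarray,
    *,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
    compute_P: bool = True,
) -> NullModel:
    """REML fit of the one-kinship-component null model.

    ``X`` is the fixed-effect design (include the intercept column).
    ``eig`` may pass a precomputed ``numpy.linalg.eigh(K)`` result so many
    traits can be fitted against one kinship at O(n^2) each;
    ``compute_P=False`` skips the O(n^3) score-test projection when only
    the variance components and fixed effects are needed.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = y.size
    if X.shape[0] != n:
        raise DataError("design and trait have different lengths")
    if np.isnan(y).any() or np.isnan(X).any():
        raise DataError("fit_null requires complete cases (drop missing first)")
    if eig is None:
        s, U = np.linalg.eigh(K)
    else:
        s, U = eig
    s = np.clip(s, 0.0, None)
    Xt = U.T @ X
    yt = U.T @ y

    def objective(h2: float) -> float:
        return _reml_neg_loglik(h2, s, Xt, yt)[0]

    eps = 1e-6
    res = optimize.minimize_scalar(
        objective, bounds=(eps, 1.0 - eps), method="bounded",
        options={"xatol": 1e-8},
    )
    h2 = float(res.x)
    # the profile can be monotone toward the boundary; take h2 = 0 if better
    if objective(eps) <= res.fun + 1e-9:
        h2 = 0.0
    nll, beta, sigma2, w = _reml_neg_loglik(max(h2, 0.0), s, Xt, yt)
    sigma_g2 = h2 * sigma2
    sigma_e2 = (1.0 - h2) * sigma2

    # P = V^-1 - V^-1 X (X'V^-1X)^-1 X'V^-1, assembled in the eigenbasis
    P = Py = None
    if compute_P:
        Uw = U * w[None, :]
        Vinv = (Uw @ U.T) / sigma2
        XtW = Xt * w[:, None]
        XtWX = Xt.T @ XtW
        VinvX = (U @ XtW) / sigma2
        P = Vinv - VinvX @ np.linalg.solve(XtWX / sigma2, VinvX.T)
        P = (P + P.T) / 2.0
        Py = P @ y
    return NullModel(
        beta_hat=beta,
        sigma_g2_hat=float(sigma_g2),
        sigma_e2_hat=float(sigma_e2),
        h2_hat=float(h2),
        loglik=float(-nll),
        P=P,
        Py=Py,
        X=X,
        y=y,
    )


def score_test(null: NullModel, g: np.ndarray) -> tuple[float, float, float]:
    """Score test of one dosage vector against the fitted null.

    Returns ``(U, var, p)`` with ``U = g' P y`` (positive U = the minor
    allele increases the transformed trait), ``var = g' P g`` and the
    p-value the upper chi-square(1) tail of ``U^2 / var``. A variant that
    is constant after projection gets ``p = 1``.
    """
    g = np.asarray(g, dtype=float)
    if np.isnan(g).any():
        m = np.nanmean(g)
        g = np.where(np.isnan(g), m, g)
    U = float(g @ null.Py)
    var = float(g @ (null.P @ g))
    if var <= 1e-12:
        return 0.0, 0.0, 1.0
    p = float(stats.chi2.sf(U * U / var, df=1))
    return U, var, max(p, np.finfo(float).tiny)


def score_test_many(null: NullModel, G: GenotypeMatrix) -> pd.DataFrame:
    """Vectorized score tests for every SNP of ``G``.

    Returns the GWAS result frame: snp_id, chrom, pos, maf, score,
    score_var, p (p = 1 with a flag for post-projection-constant SNPs).
    """
    dos = G.imputed()
    U = dos.T @ null.Py
    PG = null.P @ dos
    var = np.einsum("ij,ij->j", dos, PG)
    ok = var > 1e-12
    chi2 = np.zeros_like(var)
    chi2[ok] = U[ok] ** 2 / var[ok]
    p = np.ones_like(var)
    p[ok] = np.maximum(stats.chi2.sf(chi2[ok], df=1), np.finfo(float).tiny)
    return pd.DataFrame(
        {
            "snp_id": G.snps["snp_id"].to_numpy(),
            "chrom": G.snps["chrom"].to_numpy(),
            "pos": G.snps["pos"].to_numpy(),
            "maf": G.snps["maf"].to_numpy(),
            "score": np.where(ok, U, 0.0),
            "score_var": var,
            "p": p,
            "flagged": ~ok,
        }
    )


def classify_significance(
    p: np.ndarray | pd.Series,
    genome_wide: float = GENOME_WIDE_P,
    suggestive: float = SUGGESTIVE_P,
) -> np.ndarray:
    """Label p-values genome-wide / suggestive / none (strict thresholds)."""
    p = np.asarray(p, dtype=float)
    labels = np.where(
        p < genome_wide, "genome-wide", np.where(p < suggestive, "suggestive", "none")
    )
    return labels


def genomic_inflation(p: np.ndarray | pd.Series) -> float:
    """Genomic-control lambda: median observed chi-square(1) over 0.4549."""
    p = np.asarray(p, dtype=float)
    if p.size < 100:
        raise DataError("lambda_GC needs at least 100 tests")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / CHI2_1_MEDIAN)


def ols_score_tests(y: np.ndarray, X: np.ndarray, G: GenotypeMatrix) -> np.ndarray:
    """Naive (kinship-free) per-SNP score tests, for inflation comparisons.

    Equivalent to :func:`score_test_many` with ``K = I`` and
    ``sigma_g2 = 0``: ordinary regression of the trait on each SNP with
    covariate adjustment, ignoring relatedness entirely.
    """
    n = y.size
    null = fit_null(y, X, np.eye(n), eig=(np.ones(n), np.eye(n)))
    # force the homoscedastic independent-errors null
    return score_test_many(null, G)["p"].to_numpy()
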