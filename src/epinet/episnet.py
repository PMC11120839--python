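"""Pairwise epistasis scan and weighted interaction-network modules.

The stage takes GWAS-prefiltered SNPs, prunes them for LD (greedy blocks
on D'), fits the two-locus interaction model

    y = mu + b_i SNP_i + b_j SNP_j + b_ij (SNP_i x SNP_j) + e

by ordinary least squares for every unordered pair, and turns the
interaction significances into a weighted network: similarity = rescaled
-log10 p, soft-thresholded adjacency, topological overlap, average-linkage
clustering into color-named modules, module eigengenes, and a mixed-model
eigengene-trait association that brings family relatedness back in.

Family structure is deliberately *not* modeled inside the O(k^2) pair
scan — only in the module-level mixed model — trading exactness for a
tractable genome-scale screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .containers import GenotypeMatrix
from .errors import ConfigurationError, DataError, NumericalError
from . import relatedness_glmm

#: module color sequence, largest module first ("grey" = unassigned)
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
]


# ---------------------------------------------------------------------------
# SNP selection and LD pruning
# ---------------------------------------------------------------------------

def filter_by_gwas(gwas: pd.DataFrame, p_cut: float = 0.01) -> np.ndarray:
    """Indices of SNPs passing the loose GWAS screen (p < p_cut), in input order."""
    keep = np.flatnonzero(gwas["p"].to_numpy() < p_cut)
    if keep.size == 0:
        raise DataError(f"no SNP passes the GWAS screen at p < {p_cut}")
    return keep


def em_haplotype_freq(
    g1: np.ndarray, g2: np.ndarray, *, max_iter: int = 200, tol: float = 1e-8
) -> tuple[float, float, float, bool]:
    """EM estimate of the two-locus haplotype frequency from dosages.

    Only the double heterozygote is phase-ambiguous; EM splits its count
    between the cis and trans configurations until the frequency of the
    minor-minor haplotype converges. Returns ``(p11, pA, pB, converged)``
    where p11 is the frequency of the haplotype carrying the counted
    allele at both loci.
    """
    mask = ~(np.isnan(g1) | np.isnan(g2))
    a = g1[mask].astype(int)
    b = g2[mask].astype(int)
    n = a.size
    if n == 0 or a.min() == a.max() or b.min() == b.max():
        raise DataError("haplotype frequencies undefined for a monomorphic SNP")
    # 3x3 genotype table counts
    tab = np.zeros((3, 3))
    np.add.at(tab, (a, b), 1.0)
    # known haplotype contributions (counting allele-1 at each locus)
    pA = a.sum() / (2.0 * n)
    pB = b.sum() / (2.0 * n)
    n_dh = tab[1, 1]
    # haplotype counts excluding double hets: h11, h10, h01, h00
    h11 = 2 * tab[2, 2] + tab[2, 1] + tab[1, 2]
    h10 = 2 * tab[2, 0] + tab[2, 1] + tab[1, 0]
    h01 = 2 * tab[0, 2] + tab[0, 1] + tab[1, 2]
    h00 = 2 * tab[0, 0] + tab[0, 1] + tab[1, 0]
    total = 2.0 * n
    p11 = pA * pB  # start from linkage equilibrium
    converged = False
    for _ in range(max_iter):
        p10 = pA - p11
        p01 = pB - p11
        p00 = 1.0 - pA - pB + p11
        denom = p11 * p00 + p10 * p01
        cis = 0.5 if denom <= 0 else p11 * p00 / denom
        new_p11 = (h11 + n_dh * cis) / total
        new_p11 = min(max(new_p11, max(0.0, pA + pB - 1.0)), min(pA, pB))
        if abs(new_p11 - p11) < tol:
            p11 = new_p11
            converged = True
            break
        p11 = new_p11
    return float(p11), float(pA), float(pB), converged


def estimate_dprime(g1: np.ndarray, g2: np.ndarray, *, max_iter: int = 200,
                    tol: float = 1e-8) -> float:
    """D' between two unphased dosage vectors, ``|D| / D_max`` in [0, 1].

    Haplotype frequencies come from :func:`em_haplotype_freq`; a pair
    whose EM does not converge is treated as unlinked (D' = 0).
    """
    p11, pA, pB, converged = em_haplotype_freq(g1, g2, max_iter=max_iter, tol=tol)
    if not converged:
        return 0.0
    D = p11 - pA * pB
    if D >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    if dmax <= 0:
        return 0.0
    return float(min(abs(D) / dmax, 1.0))


def ld_prune(
    G: GenotypeMatrix, dprime_min: float = 0.9, max_block: int = 1000
) -> np.ndarray:
    """Greedy left-to-right LD pruning within chromosomes.

    SNPs must be sorted by (chromosome, position). The current block's tag
    is its leftmost SNP; a candidate joins the block while its D' with the
    tag is >= ``dprime_min`` and the block holds fewer than ``max_block``
    members, otherwise it opens a new block. Returns indices of the tags.
    """
    snps = G.snps
    order_ok = snps.groupby("chrom", sort=False)["pos"].apply(
        lambda s: bool(s.is_monotonic_increasing)
    )
    if not order_ok.all():
        raise DataError("SNPs must be sorted by chromosome and position")
    tags: list[int] = []
    for _, idx in snps.groupby("chrom", sort=False).indices.items():
        idx = np.sort(idx)
        tag = None
        block_size = 0
        for j in idx:
            if tag is None:
                tag, block_size = j, 1
                tags.append(int(j))
                continue
            g_tag = G.dosages[:, tag]
            g_j = G.dosages[:, j]
            try:
                dp = estimate_dprime(g_tag, g_j)
            except DataError:
                dp = 0.0
            if dp >= dprime_min and block_size < max_block:
                block_size += 1
            else:
                tag, block_size = j, 1
                tags.append(int(j))
    return np.array(sorted(tags))


# ---------------------------------------------------------------------------
# Pairwise interaction scan
# ---------------------------------------------------------------------------

@dataclass
class InteractionResult:
    """Upper-triangular store of all pairwise interaction fits.

    Pairs are kept in condensed order (i < j, row-major, as in
    :func:`scipy.spatial.distance.squareform`); ``estimable`` is False
    for degenerate pairs, which carry ``p = 1`` and ``beta = t = 0``.
    """

    n_snps: int
    beta: np.ndarray
    tstat: np.ndarray
    p: np.ndarray
    estimable: np.ndarray
    snp_ids: np.ndarray

    @property
    def n_pairs(self) -> int:
        return self.beta.size

    def pair_indices(self) -> tuple[np.ndarray, np.ndarray]:
        i, j = np.triu_indices(self.n_snps, k=1)
        return i, j

    def neglog10p(self) -> np.ndarray:
        return -np.log10(np.maximum(self.p, np.finfo(float).tiny))

    def to_dataframe(self) -> pd.DataFrame:
        i, j = self.pair_indices()
        return pd.DataFrame(
            {
                "snp_i": self.snp_ids[i],
                "snp_j": self.snp_ids[j],
                "beta": self.beta,
                "t": self.tstat,
                "p": self.p,
                "estimable": self.estimable,
            }
        )


def residualize_covariates(y: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Residual of the trait on (intercept, covariates) — the scan phenotype."""
    X = np.column_stack([np.ones(y.size), covariates])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def pairwise_scan(
    G: GenotypeMatrix, y_adj: np.ndarray, *, chunk: int = 250_000
) -> InteractionResult:
    """OLS interaction fit for every unordered SNP pair.

    All pair-level cross products are assembled from a handful of k x k
    matrix products, then the 4-parameter normal equations are solved in
    vectorized batches, so the scan is O(n k^2) BLAS work rather than
    k^2 regression calls. Pairs whose design is singular (constant SNP,
    collinear product) are flagged non-estimable with p = 1.
    """
    dos = G.imputed()
    n, k = dos.shape
    if n <= 4:
        raise DataError("pairwise scan needs more than 4 samples")
    y = np.asarray(y_adj, dtype=float)
    G2 = dos * dos
    Gy = dos * y[:, None]

    s_g = dos.sum(axis=0)            # sum g_i
    s_g2 = G2.sum(axis=0)            # sum g_i^2
    s_gy = dos.T @ y                 # sum g_i y
    S_gg = dos.T @ dos               # sum g_i g_j
    S_g2g = G2.T @ dos               # [i, j] = sum g_i^2 g_j
    S_g2g2 = G2.T @ G2               # sum g_i^2 g_j^2
    S_ggy = Gy.T @ dos               # sum g_i g_j y  (symmetric)
    s_y = y.sum()
    s_yy = float(y @ y)

    ii, jj = np.triu_indices(k, k=1)
    n_pairs = ii.size
    beta_out = np.zeros(n_pairs)
    t_out = np.zeros(n_pairs)
    p_out = np.ones(n_pairs)
    ok_out = np.zeros(n_pairs, dtype=bool)
    df = n - 4

    for lo in range(0, n_pairs, chunk):
        hi = min(lo + chunk, n_pairs)
        i = ii[lo:hi]
        j = jj[lo:hi]
        m = i.size
        XtX = np.empty((m, 4, 4))
        XtX[:, 0, 0] = n
        XtX[:, 0, 1] = XtX[:, 1, 0] = s_g[i]
        XtX[:, 0, 2] = XtX[:, 2, 0] = s_g[j]
        XtX[:, 0, 3] = XtX[:, 3, 0] = S_gg[i, j]
        XtX[:, 1, 1] = s_g2[i]
        XtX[:, 1, 2] = XtX[:, 2, 1] = S_gg[i, j]
        XtX[:, 1, 3] = XtX[:, 3, 1] = S_g2g[i, j]
        XtX[:, 2, 2] = s_g2[j]
        XtX[:, 2, 3] = XtX[:, 3, 2] = S_g2g[j, i]
        XtX[:, 3, 3] = S_g2g2[i, j]
        Xty = np.empty((m, 4))
        Xty[:, 0] = s_y
        Xty[:, 1] = s_gy[i]
        Xty[:, 2] = s_gy[j]
        Xty[:, 3] = S_ggy[i, j]

        # estimability check via determinant relative to the scale of XtX
        det = np.linalg.det(XtX)
        scale = np.abs(XtX).max(axis=(1, 2)) ** 4
        good = det > 1e-10 * np.maximum(scale, 1.0)
        if good.any():
            A = XtX[good]
            rhs = np.stack([Xty[good], np.broadcast_to([0.0, 0, 0, 1.0], (good.sum(), 4))],
                           axis=2)
            sol = np.linalg.solve(A, rhs)
            coef = sol[:, :, 0]
            inv_last = sol[:, 3, 1]        # (X'X)^-1 [3, 3]
            rss = s_yy - np.einsum("ij,ij->i", coef, Xty[good])
            rss = np.maximum(rss, 0.0)
            sigma2 = rss / df
            with np.errstate(divide="ignore", invalid="ignore"):
                se = np.sqrt(sigma2 * inv_last)
                t = np.where(se > 0, coef[:, 3] / se, 0.0)
            p = 2.0 * stats.t.sf(np.abs(t), df)
            sel = np.flatnonzero(good) + lo
            beta_out[sel] = coef[:, 3]
            t_out[sel] = t
            p_out[sel] = np.maximum(p, np.finfo(float).tiny)
            ok_out[sel] = (se > 0) & (inv_last > 0)
    # non-estimable pairs keep p = 1
    p_out[~ok_out] = 1.0
    beta_out[~ok_out] = 0.0
    t_out[~ok_out] = 0.0
    return InteractionResult(
        n_snps=k,
        beta=beta_out,
        tstat=t_out,
        p=p_out,
        estimable=ok_out,
        snp_ids=G.snps["snp_id"].to_numpy(),
    )


# ---------------------------------------------------------------------------
# Hotspots and per-SNP totals
# ---------------------------------------------------------------------------

def interaction_hotspots(
    result: InteractionResult,
    chrom: np.ndarray,
    quantile: float = 0.9,
    n_chrom: int = 22,
) -> np.ndarray:
    """Chromosome-pair interaction intensity matrix, min-max scaled to [0, 1].

    Cell (a, b) holds the ``quantile`` (default 0.9) of -log10 p over all
    estimable pairs with one SNP on chromosome a and one on b; cells with
    no pairs are NaN. If every populated cell is identical the rescale is
    degenerate and all populated cells are set to 1.
    """
    chrom_idx = np.asarray([int(c) - 1 for c in chrom])
    i, j = result.pair_indices()
    nlp = result.neglog10p()
    est = result.estimable
    ca, cb = chrom_idx[i[est]], chrom_idx[j[est]]
    v = nlp[est]
    lo_c = np.minimum(ca, cb)
    hi_c = np.maximum(ca, cb)
    mat = np.full((n_chrom, n_chrom), np.nan)
    cell = lo_c * n_chrom + hi_c
    order = np.argsort(cell, kind="stable")
    cell_sorted = cell[order]
    v_sorted = v[order]
    starts = np.flatnonzero(np.r_[True, np.diff(cell_sorted) > 0])
    bounds = np.r_[starts, cell_sorted.size]
    for s, e in zip(bounds[:-1], bounds[1:]):
        c = cell_sorted[s]
        q = float(np.quantile(v_sorted[s:e], quantile))
        a, b = divmod(c, n_chrom)
        mat[a, b] = mat[b, a] = q
    finite = np.isfinite(mat)
    if finite.any():
        vmin, vmax = np.nanmin(mat), np.nanmax(mat)
        if vmax > vmin:
            mat[finite] = (mat[finite] - vmin) / (vmax - vmin)
        else:
            mat[finite] = 1.0
    return mat


def sum_effect_sizes(result: InteractionResult) -> np.ndarray:
    """Per-SNP interaction total: sum of -log10 p over all estimable partners.

    This is the pseudo-Manhattan statistic; summing per-SNP totals double
    counts each pair, so ``totals.sum() == 2 * pairwise sum``.
    """
    i, j = result.pair_indices()
    nlp = np.where(result.estimable, result.neglog10p(), 0.0)
    totals = np.zeros(result.n_snps)
    np.add.at(totals, i, nlp)
    np.add.at(totals, j, nlp)
    return totals


# ---------------------------------------------------------------------------
# Network construction and modules
# ---------------------------------------------------------------------------

#: -log10 p saturation ceiling for the similarity rescale; evidence beyond
#: genome-wide strength adds no ranking information, and without a ceiling a
#: single extreme pair squashes every other true edge toward zero
NEGLOGP_CAP = 8.0


def similarity_matrix(
    result: InteractionResult, kind: str = "neglogp", cap: float = NEGLOGP_CAP
) -> np.ndarray:
    """Pair similarity in [0, 1]: -log10 p (default) or |t|, scaled by the max.

    ``-log10 p`` values are truncated at ``cap`` before rescaling (set
    ``cap = inf`` for the raw division-by-max).
    """
    if kind == "neglogp":
        v = np.where(result.estimable, np.minimum(result.neglog10p(), cap), 0.0)
    elif kind == "abs_t":
        v = np.where(result.estimable, np.abs(result.tstat), 0.0)
    else:
        raise ConfigurationError(f"unknown similarity kind {kind!r}")
    vmax = v.max()
    if vmax <= 0:
        raise NumericalError("all-zero interaction similarity")
    S = np.zeros((result.n_snps, result.n_snps))
    i, j = result.pair_indices()
    S[i, j] = S[j, i] = v / vmax
    return S


def pick_soft_power(
    S: np.ndarray,
    powers: range = range(1, 21),
    r2_target: float = 0.8,
    fallback: int = 6,
    n_bins: int = 10,
) -> tuple[int, pd.DataFrame]:
    """Smallest soft-threshold power with scale-free fit R^2 >= target.

    The fit regresses log10 frequency on log10 binned connectivity; only
    powers with a negative slope count. Falls back to ``fallback`` when no
    power reaches the target.
    """
    records = []
    chosen = None
    for pw in powers:
        A = S ** pw
        np.fill_diagonal(A, 0.0)
        k = A.sum(axis=0)
        k = k[k > 0]
        if k.size < n_bins:
            records.append({"power": pw, "r2": 0.0, "slope": 0.0})
            continue
        edges = np.quantile(k, np.linspace(0, 1, n_bins + 1))
        edges = np.unique(edges)
        if edges.size < 3:
            records.append({"power": pw, "r2": 0.0, "slope": 0.0})
            continue
        which = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, edges.size - 2)
        log_k = np.array([np.log10(k[which == b].mean())
                          for b in range(edges.size - 1) if (which == b).any()])
        log_f = np.array([np.log10((which == b).mean())
                          for b in range(edges.size - 1) if (which == b).any()])
        if log_k.size < 3:
            records.append({"power": pw, "r2": 0.0, "slope": 0.0})
            continue
        slope, _, r, *_ = stats.linregress(log_k, log_f)
        r2 = r * r if slope < 0 else 0.0
        records.append({"power": pw, "r2": float(r2), "slope": float(slope)})
        if chosen is None and r2 >= r2_target:
            chosen = pw
    return (chosen if chosen is not None else fallback), pd.DataFrame(records)


def build_network(
    result: InteractionResult,
    soft_power: int | None = None,
    similarity: str = "neglogp",
) -> tuple[np.ndarray, np.ndarray, int]:
    """Adjacency and topological overlap from the interaction similarities.

    ``a_ij = s_ij^power``; ``TOM_ij = (sum_u a_iu a_uj + a_ij) /
    (min(k_i, k_j) + 1 - a_ij)``. Returns (adjacency, TOM, power used);
    ``soft_power=None`` selects the power by scale-free fit.
    """
    S = similarity_matrix(result, similarity)
    if soft_power is None:
        soft_power, _ = pick_soft_power(S)
    if soft_power < 1:
        raise ConfigurationError("soft_power must be >= 1")
    A = S ** soft_power
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=0)
    num = A @ A + A
    den = np.minimum.outer(k, k) + 1.0 - A
    TOM = num / den
    np.fill_diagonal(TOM, 1.0)
    TOM = np.clip((TOM + TOM.T) / 2.0, 0.0, 1.0)
    return A, TOM, int(soft_power)


def detect_modules(
    dissim: np.ndarray,
    min_module_size: int = 30,
    cut_height_frac: float = 0.99,
) -> np.ndarray:
    """Average-linkage clustering of the TOM dissimilarity into modules.

    The dendrogram is cut at ``cut_height_frac`` of its maximum merge
    height; clusters smaller than ``min_module_size`` become "grey"
    (unassigned). Remaining modules are named by decreasing size along the
    conventional color sequence, largest = "turquoise".
    """
    k = dissim.shape[0]
    if k < min_module_size:
        raise DataError("fewer SNPs than min_module_size")
    i, j = np.triu_indices(k, 1)
    condensed = dissim[i, j]
    Z = hierarchy.linkage(condensed, method="average")
    cut = cut_height_frac * Z[:, 2].max()
    raw = hierarchy.fcluster(Z, t=cut, criterion="distance")
    labels = np.full(k, "grey", dtype=object)
    sizes = pd.Series(raw).value_counts()
    big = sizes[sizes >= min_module_size].index.tolist()
    big.sort(key=lambda c: (-sizes[c], c))
    for rank, c in enumerate(big):
        color = MODULE_COLORS[rank] if rank < len(MODULE_COLORS) else f"module{rank + 1}"
        labels[raw == c] = color
    return labels


def module_eigengene(G: GenotypeMatrix, labels: np.ndarray) -> pd.DataFrame:
    """First principal component of each module's standardized dosages.

    Columns are unit-norm n-vectors, sign-fixed to correlate positively
    with the module's mean standardized dosage. "grey" is skipped.
    """
    out = {}
    dos = G.imputed()
    for module in [m for m in pd.unique(labels) if m != "grey"]:
        cols = np.flatnonzero(labels == module)
        Z = dos[:, cols] - dos[:, cols].mean(axis=0)
        sd = Z.std(axis=0)
        sd[sd == 0] = 1.0
        Z = Z / sd
        U, sv, _ = np.linalg.svd(Z, full_matrices=False)
        me = U[:, 0]
        ref = Z.mean(axis=1)
        if me @ ref < 0:
            me = -me
        out[module] = me
    return pd.DataFrame(out, index=G.samples)


def module_association(
    me: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray,
    K: np.ndarray,
    *,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[float, float]:
    """Wald test of a module eigengene as a fixed effect in the kinship GLMM.

    Refits the REML variance components with the eigengene in the design
    (intercept + covariates + ME) and reports its signed coefficient and a
    two-sided normal p-value.
    """
    me = np.asarray(me, dtype=float)
    X = np.column_stack([np.ones(me.size), covariates, me])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DataError("eigengene collinear with covariates")
    fit = relatedness_glmm.fit_null(y, X, K, eig=eig, compute_P=False)
    # SE of the last fixed effect from (X' V^-1 X)^-1
    if eig is None:
        s, U = np.linalg.eigh(K)
    else:
        s, U = eig
    s = np.clip(s, 0.0, None)
    d = fit.h2_hat * s + (1.0 - fit.h2_hat)
    sigma2 = fit.sigma_g2_hat + fit.sigma_e2_hat
    Xt = U.T @ X
    XtWX = Xt.T @ (Xt / d[:, None])
    cov = np.linalg.inv(XtWX) * sigma2
    coef = float(fit.beta_hat[-1])
    se = float(np.sqrt(cov[-1, -1]))
    z = coef / se
    p = float(max(2.0 * stats.norm.sf(abs(z)), np.finfo(float).tiny))
    return coef, p


@dataclass
class ModuleSet:
    """Module labels, eigengenes, and their trait associations."""

    labels: pd.Series            # snp_id -> module color ("grey" = none)
    eigengenes: pd.DataFrame     # samples x modules
    assoc: pd.DataFrame = field(default_factory=pd.DataFrame)  # module, size, coef, p

    def members(self, module: str) -> list[str]:
        return self.labels.index[self.labels == module].tolist()


def build_module_set(
    G: GenotypeMatrix,
    labels: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray,
    K: np.ndarray,
    *,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
) -> ModuleSet:
    """Assemble eigengenes and GLMM associations for every non-grey module."""
    if eig is None:
        eig = np.linalg.eigh(K)
    mes = module_eigengene(G, labels)
    rows = []
    for module in mes.columns:
        coef, p = module_association(mes[module].to_numpy(), y, covariates, K, eig=eig)
        rows.append(
            {
                "module": module,
                "n_snps": int((labels == module).sum()),
                "coef": coef,
                "p": p,
            }
        )
    assoc = pd.DataFrame(rows, columns=["module", "n_snps", "coef", "p"])
    if len(assoc):
        assoc = assoc.sort_values("p").reset_index(drop=True)
    return ModuleSet(
        labels=pd.Series(labels, index=G.snps["snp_id"].to_numpy(), name="module"),
        eigengenes=mes,
        assoc=assoc,
    )
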