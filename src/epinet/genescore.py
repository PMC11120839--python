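"""Gene mapping, sum-of-chi-square gene tests, and gene-set enrichment.

SNPs are assigned to a gene when they fall within a window (default 50 kb)
of its transcript span; a gene's statistic is the sum of its SNPs'
chi-square(1) quantiles, referred either to a chi-square(n) (independence
assumption) or to a Monte-Carlo multivariate-normal null that honors the
local LD correlation. Enrichment of a selected gene list against
user-supplied gene sets uses the one-sided hypergeometric test with
Benjamini-Hochberg correction across sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, DataError


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

def normalize_chrom(label: str) -> str:
    """Strip a leading 'chr' so '1' and 'chr1' compare equal."""
    s = str(label)
    return s[3:] if s.lower().startswith("chr") else s


def read_gene_bed(path: str | Path) -> pd.DataFrame:
    """Read a gene annotation BED (chrom, start, end, gene_id).

    BED is 0-based half-open; internally coordinates are 1-based inclusive,
    so ``start`` gains 1 and ``end`` is kept.
    """
    genes = pd.read_csv(
        path,
        sep="\t",
        header=None,
        usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "gene_id"],
        dtype={"chrom": str, "gene_id": str},
        comment="#",
    )
    genes["chrom"] = genes["chrom"].map(normalize_chrom)
    genes["start"] = genes["start"] + 1
    bad = genes["start"] > genes["end"]
    if bad.any():
        raise DataError(f"{bad.sum()} gene records with start > end")
    return genes


def map_snps_to_genes(
    snps: pd.DataFrame, genes: pd.DataFrame, window: int = 50_000
) -> dict[str, list[str]]:
    """Map SNPs to genes within ``window`` bp of the gene span (inclusive).

    A SNP maps to gene g iff ``g.start - window <= pos <= g.end + window``
    on the same chromosome; one SNP may hit several genes. Chromosome
    labels are normalized ('chr1' == '1') with a warning when the two
    inputs mix conventions.
    """
    snp_chrom = snps["chrom"].map(normalize_chrom)
    if (snp_chrom != snps["chrom"].astype(str)).any() or (
        genes["chrom"].map(normalize_chrom) != genes["chrom"].astype(str)
    ).any():
        warnings.warn("chromosome labels normalized ('chrN' -> 'N')", stacklevel=2)
    trees: dict[str, IntervalTree] = {}
    for row in genes.itertuples(index=False):
        c = normalize_chrom(row.chrom)
        lo = max(int(row.start) - window, 0)
        hi = int(row.end) + window + 1  # interval end exclusive
        trees.setdefault(c, IntervalTree()).addi(lo, hi, row.gene_id)
    mapping: dict[str, list[str]] = {g: [] for g in genes["gene_id"]}
    for snp_id, c, pos in zip(snps["snp_id"], snp_chrom, snps["pos"]):
        tree = trees.get(str(c))
        if tree is None:
            continue
        for hit in tree.at(int(pos)):
            mapping[hit.data].append(snp_id)
    return {g: ids for g, ids in mapping.items() if ids}


# ---------------------------------------------------------------------------
# Gene-based test
# ---------------------------------------------------------------------------

@dataclass
class GeneTestResult:
    gene_id: str
    n_snps: int
    stat: float
    p: float
    method: str


def gene_test(
    snp_pvalues: np.ndarray,
    ld_matrix: np.ndarray | None = None,
    *,
    n_draws: int = 100_000,
    rng: np.random.Generator | None = None,
    gene_id: str = "",
) -> GeneTestResult:
    """Sum-of-chi-square gene statistic with closed-form or LD-aware null.

    Each SNP p-value becomes its upper-tail chi-square(1) quantile and the
    gene statistic is the sum. Without ``ld_matrix`` the null is
    chi-square(n). With it, the null is simulated: multivariate normal
    draws with the given genotype correlation, summed squared components,
    and the p-value is the exceedance proportion with a +1 correction so
    it stays in (0, 1].
    """
    p = np.asarray(snp_pvalues, dtype=float)
    if p.size < 1:
        raise DataError("gene test needs at least one SNP p-value")
    if (p <= 0).any():
        warnings.warn("p-values of 0 clipped to the smallest positive float",
                      stacklevel=2)
        p = np.maximum(p, np.finfo(float).tiny)
    if (p > 1).any():
        raise DataError("p-values must lie in (0, 1]")
    n = p.size
    stat = float(stats.chi2.isf(p, df=1).sum())
    if ld_matrix is None:
        return GeneTestResult(gene_id, n, stat, float(stats.chi2.sf(stat, df=n)),
                              "closed_form")
    R = np.asarray(ld_matrix, dtype=float)
    if R.shape != (n, n):
        raise ConfigurationError("ld_matrix shape does not match the SNP count")
    rng = rng or np.random.default_rng()
    s, U = np.linalg.eigh((R + R.T) / 2.0)
    L = U * np.sqrt(np.clip(s, 0.0, None))
    exceed = 0
    block = 20_000
    done = 0
    while done < n_draws:
        b = min(block, n_draws - done)
        Z = rng.standard_normal((b, n)) @ L.T
        exceed += int(((Z * Z).sum(axis=1) >= stat).sum())
        done += b
    p_gene = (exceed + 1.0) / (n_draws + 1.0)
    return GeneTestResult(gene_id, n, stat, float(p_gene), "mvn_sim")


def gene_tests(
    gene_map: dict[str, list[str]],
    snp_p: pd.Series,
    genotypes: pd.DataFrame | None = None,
    *,
    n_draws: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene test for every mapped gene.

    ``snp_p`` maps snp_id -> GWAS p-value. When ``genotypes`` (a samples x
    snp_id dosage frame) is given, each gene's test uses the Monte-Carlo
    null with the observed genotype correlation; otherwise the closed-form
    independence null.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for gene, ids in gene_map.items():
        ids = [i for i in ids if i in snp_p.index]
        if not ids:
            continue
        pvals = snp_p.loc[ids].to_numpy(dtype=float)
        ld = None
        if genotypes is not None and len(ids) > 1:
            sub = genotypes[ids].to_numpy(dtype=float)
            sd = sub.std(axis=0)
            keepable = sd > 0
            if keepable.all():
                ld = np.corrcoef(sub, rowvar=False)
        res = gene_test(pvals, ld, n_draws=n_draws, rng=rng, gene_id=gene)
        rows.append(res.__dict__)
    out = pd.DataFrame(rows, columns=["gene_id", "n_snps", "stat", "p", "method"])
    return out.sort_values("p").reset_index(drop=True) if len(out) else out


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT-like TSV: set name, description, then member genes."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(parts[2:])
    return sets


def enrich(
    genes_selected: set[str] | list[str],
    gene_sets: dict[str, set[str]],
    background: set[str] | list[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of each set in the selection.

    One-sided upper tail P[X >= overlap]; fold = observed / expected
    overlap; Benjamini-Hochberg adjusted p across all sets in the call.
    """
    background = set(background)
    if not background:
        raise DataError("empty background gene universe")
    selected = set(genes_selected) & background
    M = len(background)
    N = len(selected)
    rows = []
    for name, members in gene_sets.items():
        members = set(members) & background
        K = len(members)
        k = len(members & selected)
        # P[X >= k] with X ~ Hypergeom(M, K, N)
        p = float(stats.hypergeom.sf(k - 1, M, K, N)) if K else 1.0
        expected = K * N / M if M else 0.0
        fold = (k / expected) if expected > 0 else np.nan
        rows.append({"set": name, "n_set": K, "overlap": k,
                     "fold": fold, "p": min(p, 1.0)})
    out = pd.DataFrame(rows, columns=["set", "n_set", "overlap", "fold", "p"])
    if len(out):
        out["p_adj"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
        out = out.sort_values("p").reset_index(drop=True)
    else:
        out["p_adj"] = []
    return out
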