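"""Genotype/phenotype file handling, marker QC, and the trait transformation.

Covers reading and writing PLINK binary filesets (bed/bim/fam, SNP-major
v1.00), minor-allele orientation, the MAF and exact Hardy–Weinberg filters,
and the rank-based inverse normal transformation (INT) applied to the trait
before any association testing.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .containers import GenotypeMatrix, QcReport
from .errors import ConfigurationError, DataError, FormatError

_BED_MAGIC = b"\x6c\x1b\x01"  # v1.00, SNP-major

# 2-bit codes -> dosage of the A1 allele (PLINK convention):
# 00 hom A1, 01 missing, 10 het, 11 hom A2
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


# ---------------------------------------------------------------------------
# PLINK binary fileset
# ---------------------------------------------------------------------------

def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read ``prefix``.bed/.bim/.fam into a :class:`GenotypeMatrix`.

    Dosages count the *minor* allele regardless of which allele the file
    stores as A1: the orientation is recomputed from the sample allele
    frequency (ties broken toward the lexicographically smaller allele),
    so the downstream 0/1/2 coding is always relative to the minor allele.
    """
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "snp_id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype=str,
    )
    n, m = len(fam), len(bim)
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise FormatError(f"{prefix}.bed: bad magic bytes (need SNP-major v1.00)")
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != bytes_per_snp * m:
        raise FormatError(
            f"{prefix}.bed: {body.size} data bytes, expected {bytes_per_snp * m} "
            f"for {n} samples x {m} SNPs"
        )
    # unpack 2-bit genotype codes, one SNP per row
    codes = body.reshape(m, bytes_per_snp)
    expanded = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    for shift in range(4):
        expanded[:, shift::4] = (codes >> (2 * shift)) & 0b11
    a1_dosage = _CODE_TO_DOSAGE[expanded[:, :n]].T  # (n, m)

    dosages, snps = orient_to_minor(a1_dosage, bim)
    return GenotypeMatrix(dosages, snps, pd.Index(fam["iid"]))


def orient_to_minor(
    a1_dosage: np.ndarray, bim: pd.DataFrame
) -> tuple[np.ndarray, pd.DataFrame]:
    """Flip dosage columns so they count the empirically minor allele."""
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(a1_dosage, axis=0) / 2.0
    freq = np.where(np.isnan(freq), 0.0, freq)
    a1 = bim["a1"].to_numpy()
    a2 = bim["a2"].to_numpy()
    # strictly > 0.5 flips; at exactly 0.5 keep the lexicographically
    # smaller allele as the counted (minor) one
    flip = (freq > 0.5) | ((freq == 0.5) & (a1 > a2))
    dosages = np.where(flip, 2.0 - a1_dosage, a1_dosage)
    snps = pd.DataFrame(
        {
            "snp_id": bim["snp_id"].to_numpy(),
            "chrom": bim["chrom"].to_numpy(),
            "pos": bim["pos"].to_numpy(),
            "allele_minor": np.where(flip, a2, a1),
            "allele_major": np.where(flip, a1, a2),
            "maf": np.where(flip, 1.0 - freq, freq),
        }
    )
    return dosages, snps


def write_plink(
    G: GenotypeMatrix,
    prefix: str | Path,
    pedigree: pd.DataFrame | None = None,
) -> None:
    """Write a PLINK bed/bim/fam triplet (A1 = minor allele as stored).

    ``pedigree`` may supply fam columns (iid, father, mother, sex); absent
    entries default to founders of unknown sex in one family per sample.
    """
    prefix = Path(prefix)
    n, m = G.n_samples, G.n_snps
    dos = G.dosages
    # map dosage of A1(minor) to 2-bit codes
    code = np.full((m, n), 0b01, dtype=np.uint8)  # missing
    d = dos.T
    code[d == 2.0] = 0b00
    code[d == 1.0] = 0b10
    code[d == 0.0] = 0b11
    bytes_per_snp = (n + 3) // 4
    padded = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
    padded[:, :n] = code
    packed = np.zeros((m, bytes_per_snp), dtype=np.uint8)
    for shift in range(4):
        packed |= padded[:, shift::4] << (2 * shift)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())

    bim = pd.DataFrame(
        {
            "chrom": G.snps["chrom"],
            "snp_id": G.snps["snp_id"],
            "cm": 0,
            "pos": G.snps["pos"],
            "a1": G.snps["allele_minor"],
            "a2": G.snps["allele_major"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    if pedigree is not None:
        ped = pedigree.set_index("iid").reindex(G.samples)
        fam = pd.DataFrame(
            {
                "fid": ped.get("family", pd.Series("1", index=ped.index)).fillna("1"),
                "iid": ped.index,
                "father": ped.get("father", pd.Series("0", index=ped.index)).fillna("0"),
                "mother": ped.get("mother", pd.Series("0", index=ped.index)).fillna("0"),
                "sex": ped.get("sex", pd.Series(0, index=ped.index)).fillna(0),
                "pheno": -9,
            }
        )
    else:
        fam = pd.DataFrame(
            {
                "fid": G.samples,
                "iid": G.samples,
                "father": "0",
                "mother": "0",
                "sex": 0,
                "pheno": -9,
            }
        )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Phenotype table
# ---------------------------------------------------------------------------

def read_phenotype(path: str | Path, trait: str = "pheno") -> pd.DataFrame:
    """Read the phenotype/covariate TSV (columns: iid, pheno, age, sex)."""
    tab = pd.read_csv(path, sep="\t", dtype={"iid": str})
    required = {"iid", trait, "age", "sex"}
    missing = required - set(tab.columns)
    if missing:
        raise DataError(f"phenotype table lacks column(s) {sorted(missing)}")
    return tab


# ---------------------------------------------------------------------------
# Marker QC
# ---------------------------------------------------------------------------

def filter_maf(G: GenotypeMatrix, threshold: float = 0.01) -> np.ndarray:
    """Indices of SNPs retained by the MAF filter (removal is maf < threshold)."""
    if not 0.0 <= threshold <= 0.5:
        raise ConfigurationError(f"MAF threshold {threshold} outside [0, 0.5]")
    maf = G.compute_maf()
    return np.flatnonzero(maf >= threshold)


def hwe_test(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact two-sided Hardy–Weinberg test by conditional enumeration.

    Enumerates every heterozygote count compatible with the observed allele
    counts and sums the probabilities of all configurations no more likely
    than the observed one (mid-p off). Returns a p-value in (0, 1].
    """
    counts = (n_hom_major, n_het, n_hom_minor)
    if any(c < 0 for c in counts):
        raise DataError("genotype counts must be non-negative")
    n = sum(counts)
    if n < 1:
        raise DataError("HWE test undefined for zero total count")
    n_rare = 2 * min(n_hom_major, n_hom_minor) + n_het
    if n_rare == 0:
        return 1.0
    # heterozygote count shares the parity of the rare-allele count
    hets = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    rare_hom = (n_rare - hets) // 2
    common_hom = n - hets - rare_hom
    # log P(het = h | allele counts) up to a common constant
    logp = (
        hets * np.log(2.0)
        - gammaln(hets + 1)
        - gammaln(rare_hom + 1)
        - gammaln(common_hom + 1)
    )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    obs = prob[hets == n_het][0]
    p = prob[prob <= obs * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


def hwe_test_genotypes(dosage: np.ndarray) -> float:
    """HWE exact test from one SNP's dosage vector (missing ignored)."""
    d = dosage[~np.isnan(dosage)]
    return hwe_test(int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum()))


def run_qc(
    G: GenotypeMatrix, maf_min: float = 0.01, hwe_p_min: float = 1e-6
) -> tuple[GenotypeMatrix, QcReport]:
    """MAF filter, then exact HWE on the MAF-passing SNPs.

    The HWE test is only evaluated on SNPs that survive the MAF filter, so
    the two removal counts partition the input. Returns the retained
    genotypes (with refreshed ``maf`` metadata) and the bookkeeping report.
    """
    keep_maf = filter_maf(G, maf_min)
    n_removed_maf = G.n_snps - keep_maf.size
    hwe_p = np.array(
        [hwe_test_genotypes(G.dosages[:, j]) for j in keep_maf]
    )
    keep = keep_maf[hwe_p >= hwe_p_min]
    n_removed_hwe = keep_maf.size - keep.size
    out = G.subset_snps(keep)
    out.snps["maf"] = out.compute_maf()
    report = QcReport(
        n_input=G.n_snps,
        n_removed_maf=int(n_removed_maf),
        n_removed_hwe=int(n_removed_hwe),
        n_retained=int(keep.size),
    )
    return out, report


# ---------------------------------------------------------------------------
# Trait transformation
# ---------------------------------------------------------------------------

def int_transform(y: Sequence[float], offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse normal transformation (Blom offset by default).

    Maps each observation through ``probit((rank - c) / (n - 2c + 1))``
    with ``c = offset``; ties get the average rank, missing values are
    excluded from ranking and reinserted as ``NaN``.
    """
    y = np.asarray(y, dtype=float)
    out = np.full(y.shape, np.nan)
    mask = ~np.isnan(y)
    vals = y[mask]
    n = vals.size
    if n < 2:
        raise DataError("INT requires at least two non-missing observations")
    if np.all(vals == vals[0]):
        raise DataError("INT undefined: all observations identical")
    ranks = stats.rankdata(vals, method="average")
    out[mask] = stats.norm.ppf((ranks - offset) / (n - 2.0 * offset + 1.0))
    return out
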