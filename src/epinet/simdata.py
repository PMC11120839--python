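"""Pedigree-structured genotype and phenotype simulator.

Generates multi-generation families by gene dropping (founder genotypes
binomial in the founder allele frequency, one allele transmitted from each
parent, SNPs unlinked unless an LD block mode is requested), the exact
pedigree kinship expected under Mendelian transmission, and a quantitative
trait built from age/sex covariate effects, a polygenic component whose
covariance is proportional to kinship, and planted main and pairwise
SNP x SNP interaction effects. Everything is driven by one seeded
generator so a run is reproducible bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix
from .errors import ConfigurationError, PedigreeError
from . import genotype_io


@dataclass
class PedigreeSpec:
    """Family structure of the simulated cohort.

    Each family starts from a founder couple; every later generation adds
    ``offspring_per_couple`` children of the current couple, the eldest of
    whom marries a new (unrelated) founder to form the next couple. With
    ``generations = g`` and ``offspring_per_couple = c`` a family therefore
    has ``2 + (g - 1) * (c + 1) - [g > 1]`` members... in practice use
    :meth:`family_size` rather than arithmetic.
    """

    n_families: int = 200
    generations: int = 2
    offspring_per_couple: int = 3
    founder_maf_range: tuple[float, float] = (0.05, 0.5)

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ConfigurationError("need at least one family")
        if self.generations < 1:
            raise ConfigurationError("generations must be >= 1")
        if self.generations > 1 and self.offspring_per_couple < 1:
            raise ConfigurationError("multi-generation families need offspring")
        lo, hi = self.founder_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError("founder_maf_range must satisfy 0 < lo <= hi <= 0.5")

    def family_size(self) -> int:
        if self.generations == 1:
            return 2
        # couple + per extra generation: c offspring, plus a married-in
        # founder for every generation that itself reproduces
        size = 2
        for g in range(1, self.generations):
            size += self.offspring_per_couple
            if g < self.generations - 1:
                size += 1
        return size


@dataclass
class TraitModel:
    """Generative model of the quantitative trait.

    ``y = mu + beta_age*age + beta_sex*sex + planted mains + planted
    pairwise products + g + e`` with ``g ~ N(0, sigma_g2 * K)`` and
    ``e ~ N(0, sigma_e2 * I)``. SNP dosages enter the planted terms
    exactly as coded (0/1/2), so a pairwise product carries both a
    marginal and a purely epistatic component.
    """

    beta_age: float = 0.0
    beta_sex: float = 0.0
    sigma_g2: float = 0.0
    sigma_e2: float = 1.0
    mu: float = 0.0
    planted_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    planted_mains: list[tuple[int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sigma_g2 < 0:
            raise ConfigurationError("sigma_g2 must be >= 0")
        if self.sigma_e2 <= 0:
            raise ConfigurationError("sigma_e2 must be > 0")
        for i, j, _ in self.planted_pairs:
            if i == j:
                raise ConfigurationError(f"planted pair ({i}, {j}) is not two distinct SNPs")


def simulate_pedigree_genotypes(
    spec: PedigreeSpec,
    n_snps: int,
    seed: int,
    *,
    missing_rate: float = 0.0,
    ld_flip_prob: float | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Gene-drop genotypes through ``spec`` pedigrees.

    Founder allele counts are binomial in a per-SNP founder frequency drawn
    uniformly from ``spec.founder_maf_range``; each non-founder receives one
    allele from each parent per SNP, independently across SNPs. With
    ``ld_flip_prob`` set, founder haplotypes are instead generated as
    copy-with-flip chains along adjacent SNPs, which induces LD blocks for
    the pruning stage to chew on.

    Returns the genotype matrix (SNPs placed on chromosomes 1..22 in equal
    contiguous stretches) and the pedigree table
    (iid, father, mother, sex, family, founder).
    """
    if n_snps < 1:
        raise ConfigurationError("n_snps must be >= 1")
    if not 0.0 <= missing_rate < 1.0:
        raise ConfigurationError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    lo, hi = spec.founder_maf_range
    maf = rng.uniform(lo, hi, size=n_snps)

    rows: list[dict] = []
    hap_a: list[np.ndarray] = []  # haplotypes as 0/1 arrays per individual
    hap_b: list[np.ndarray] = []
    idx_of: dict[str, int] = {}

    def founder_haplotype() -> np.ndarray:
        if ld_flip_prob is None:
            return (rng.random(n_snps) < maf).astype(np.int8)
        # Markov chain along the map: copy previous allele state's
        # frequency-rank with probability 1-ld_flip_prob
        h = np.empty(n_snps, dtype=np.int8)
        h[0] = rng.random() < maf[0]
        u = rng.random(n_snps)
        flip = rng.random(n_snps) < ld_flip_prob
        for k in range(1, n_snps):
            h[k] = (u[k] < maf[k]) if flip[k] else h[k - 1]
        return h

    def add(iid: str, father: str, mother: str, sex: int, fam: str) -> None:
        idx_of[iid] = len(rows)
        rows.append(
            {
                "iid": iid,
                "father": father,
                "mother": mother,
                "sex": sex,
                "family": fam,
                "founder": father == "0",
            }
        )
        if father == "0":
            hap_a.append(founder_haplotype())
            hap_b.append(founder_haplotype())
        else:
            fa, fb = hap_a[idx_of[father]], hap_b[idx_of[father]]
            ma, mb = hap_a[idx_of[mother]], hap_b[idx_of[mother]]
            pick_f = rng.integers(0, 2, size=n_snps)
            pick_m = rng.integers(0, 2, size=n_snps)
            hap_a.append(np.where(pick_f, fa, fb).astype(np.int8))
            hap_b.append(np.where(pick_m, ma, mb).astype(np.int8))

    for f in range(spec.n_families):
        fam = f"F{f + 1}"
        father, mother = f"{fam}_G1_F", f"{fam}_G1_M"
        add(father, "0", "0", 1, fam)
        add(mother, "0", "0", 2, fam)
        for g in range(2, spec.generations + 1):
            kids = []
            for c in range(spec.offspring_per_couple):
                kid = f"{fam}_G{g}_C{c + 1}"
                sex = 1 + int(rng.random() < 0.5)
                add(kid, father, mother, sex, fam)
                kids.append((kid, sex))
            if g < spec.generations:
                heir, heir_sex = kids[0]
                spouse = f"{fam}_G{g}_S"
                spouse_sex = 2 if heir_sex == 1 else 1
                add(spouse, "0", "0", spouse_sex, fam)
                father, mother = (heir, spouse) if heir_sex == 1 else (spouse, heir)

    pedigree = pd.DataFrame(rows)
    dosages = (np.array(hap_a) + np.array(hap_b)).astype(float)
    if missing_rate > 0:
        miss = rng.random(dosages.shape) < missing_rate
        dosages[miss] = np.nan
    # orient each SNP to its realized in-sample minor allele, so the
    # stored 0/1/2 coding matches what a reader would recompute
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(dosages, axis=0) / 2.0
    flip = freq > 0.5
    dosages[:, flip] = 2.0 - dosages[:, flip]

    n = len(pedigree)
    chrom = np.repeat(np.arange(1, 23), int(np.ceil(n_snps / 22)))[:n_snps]
    pos = np.empty(n_snps, dtype=int)
    for c in np.unique(chrom):
        m = chrom == c
        pos[m] = 10_000 * (1 + np.arange(m.sum()))
    snps = pd.DataFrame(
        {
            "snp_id": [f"snp{j + 1}" for j in range(n_snps)],
            "chrom": chrom.astype(str),
            "pos": pos,
            "allele_minor": np.where(flip, "G", "A"),
            "allele_major": np.where(flip, "A", "G"),
            "maf": maf,
        }
    )
    G = GenotypeMatrix(dosages, snps, pd.Index(pedigree["iid"]))
    G.snps["maf"] = G.compute_maf()
    return G, pedigree


def expected_kinship(pedigree: pd.DataFrame) -> np.ndarray:
    """Numerator relationship matrix (2x kinship) from the pedigree.

    Standard tabular method: individuals are processed parents-first;
    ``A[i, j] = (A[father_i, j] + A[mother_i, j]) / 2`` and
    ``A[i, i] = 1 + A[father_i, mother_i] / 2``. Founders are unrelated
    and non-inbred, so the diagonal is 1 for them.
    """
    iids = pedigree["iid"].tolist()
    pos = {iid: k for k, iid in enumerate(iids)}
    fathers = pedigree["father"].tolist()
    mothers = pedigree["mother"].tolist()
    n = len(iids)
    for k, (fa, mo) in enumerate(zip(fathers, mothers)):
        for parent in (fa, mo):
            if parent != "0":
                if parent not in pos:
                    raise PedigreeError(f"unknown parent {parent!r}")
                if pos[parent] >= k:
                    raise PedigreeError(
                        f"parent {parent!r} listed after offspring {iids[k]!r}"
                    )
    A = np.zeros((n, n))
    for k in range(n):
        fa, mo = fathers[k], mothers[k]
        if fa == "0" and mo == "0":
            A[k, k] = 1.0
            continue
        fi, mi = pos[fa], pos[mo]
        A[k, :k] = 0.5 * (A[fi, :k] + A[mi, :k])
        A[:k, k] = A[k, :k]
        A[k, k] = 1.0 + 0.5 * A[fi, mi]
    return A


def simulate_phenotype(
    G: GenotypeMatrix,
    K: np.ndarray,
    model: TraitModel,
    covariates: pd.DataFrame,
    seed: int,
) -> pd.DataFrame:
    """Draw the trait under :class:`TraitModel` for the samples of ``G``.

    ``covariates`` must carry ``age`` and ``sex`` aligned to ``G.samples``.
    Returns a phenotype table (iid, pheno, age, sex).
    """
    n = G.n_samples
    if K.shape != (n, n):
        raise ConfigurationError("kinship not aligned to genotype samples")
    for i, j, _ in model.planted_pairs:
        if not (0 <= i < G.n_snps and 0 <= j < G.n_snps):
            raise ConfigurationError(f"planted pair ({i}, {j}) out of SNP range")
    for i, _ in model.planted_mains:
        if not 0 <= i < G.n_snps:
            raise ConfigurationError(f"planted main {i} out of SNP range")
    rng = np.random.default_rng(seed)
    age = covariates["age"].to_numpy(dtype=float)
    sex = covariates["sex"].to_numpy(dtype=float)
    y = model.mu + model.beta_age * age + model.beta_sex * sex
    dos = G.imputed()
    for i, beta in model.planted_mains:
        y = y + beta * dos[:, i]
    for i, j, beta in model.planted_pairs:
        y = y + beta * dos[:, i] * dos[:, j]
    if model.sigma_g2 > 0:
        s, U = np.linalg.eigh(K)
        s = np.clip(s, 0.0, None)
        y = y + U @ (np.sqrt(model.sigma_g2 * s) * rng.standard_normal(n))
    y = y + rng.normal(0.0, np.sqrt(model.sigma_e2), size=n)
    return pd.DataFrame(
        {"iid": G.samples, "pheno": y, "age": age, "sex": sex}
    ).reset_index(drop=True)


def simulate_covariates(
    n: int, seed: int, age_range: tuple[float, float] = (60.0, 100.0)
) -> pd.DataFrame:
    """Age uniform on ``age_range``, sex Bernoulli(0.5) coded 1/2."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "age": rng.uniform(*age_range, size=n),
            "sex": 1 + (rng.random(n) < 0.5).astype(int),
        }
    )


def planted_module(
    G: GenotypeMatrix,
    snp_indices: np.ndarray,
    interaction_var_frac: float,
    base_model: TraitModel,
    seed: int,
) -> TraitModel:
    """Plant a fully interacting SNP module with a target variance share.

    Every pair within ``snp_indices`` receives an interaction coefficient
    of common magnitude and random sign (drawn from ``seed``), scaled so
    the planted component's sample variance is ``interaction_var_frac`` of
    the total genetic-plus-residual trait variance (covariate effects
    excluded, since association testing adjusts them out). Random signs
    keep the component genuinely interactive: with a shared sign the raw
    dosage products add up coherently into a dominant additive term, and
    the module would be an additive signal wearing an epistatic costume.
    """
    rng = np.random.default_rng(seed)
    snp_indices = np.asarray(snp_indices)
    if snp_indices.size < 2:
        raise ConfigurationError("a planted module needs at least two SNPs")
    if not 0.0 < interaction_var_frac < 1.0:
        raise ConfigurationError("interaction_var_frac must be in (0, 1)")
    dos = G.imputed()[:, snp_indices]
    component = np.zeros(G.n_samples)
    pairs = []
    signs = []
    for a in range(snp_indices.size):
        for b in range(a + 1, snp_indices.size):
            sign = 1.0 if rng.random() < 0.5 else -1.0
            component += sign * dos[:, a] * dos[:, b]
            pairs.append((int(snp_indices[a]), int(snp_indices[b])))
            signs.append(sign)
    var_unit = component.var()
    if var_unit <= 0:
        raise ConfigurationError("planted module SNPs are constant")
    var_rest = base_model.sigma_g2 + base_model.sigma_e2
    target = interaction_var_frac / (1.0 - interaction_var_frac) * var_rest
    beta = float(np.sqrt(target / var_unit))
    return TraitModel(
        beta_age=base_model.beta_age,
        beta_sex=base_model.beta_sex,
        sigma_g2=base_model.sigma_g2,
        sigma_e2=base_model.sigma_e2,
        mu=base_model.mu,
        planted_pairs=[(i, j, s * beta) for (i, j), s in zip(pairs, signs)],
        planted_mains=list(base_model.planted_mains),
    )


def write_simulated_cohort(
    outdir: str | Path,
    G: GenotypeMatrix,
    pedigree: pd.DataFrame,
    phenotype: pd.DataFrame,
    model: TraitModel,
    seed: int,
    prefix: str = "cohort",
) -> dict:
    """Write PLINK bed/bim/fam, phenotype TSV, pedigree TSV, and truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genotype_io.write_plink(G, outdir / prefix, pedigree)
    phenotype.to_csv(outdir / f"{prefix}.pheno.tsv", sep="\t", index=False)
    pedigree[["iid", "father", "mother", "sex"]].to_csv(
        outdir / f"{prefix}.ped.tsv", sep="\t", index=False
    )
    truth = {
        "seed": seed,
        "mu": model.mu,
        "beta_age": model.beta_age,
        "beta_sex": model.beta_sex,
        "sigma_g2": model.sigma_g2,
        "sigma_e2": model.sigma_e2,
        "planted_mains": [[int(i), float(b)] for i, b in model.planted_mains],
        "planted_pairs": [
            [int(i), int(j), float(b)] for i, j, b in model.planted_pairs
        ],
    }
    with open(outdir / f"{prefix}.truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
    return truth
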