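"""Simulation experiments that exercise the pipeline end to end.

Each function generates a pedigree cohort with known ground truth, runs
the relevant pipeline stages at a desk-scale problem size, and returns
the measured operating characteristics (inflation factors, error rates,
variance-component recovery, planted-module recovery and replication).
They are used both by the test suite and by the reproducibility script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import episnet, genotype_io, relatedness_glmm, replication, simdata


def _seed_for(seed: int, salt: int) -> int:
    return int(np.random.SeedSequence([seed, salt]).generate_state(1)[0] % (2**31))


def simulate_cohort(
    seed: int,
    n_families: int = 200,
    n_snps: int = 2000,
    sigma_g2: float = 0.4,
    sigma_e2: float = 0.6,
    planted_module_size: int = 0,
    interaction_var_frac: float = 0.0,
    generations: int = 2,
    offspring_per_couple: int = 3,
):
    """One pedigree cohort; optionally with a planted interacting module.

    Returns (G, pedigree, kinship, phenotype frame, model, planted SNP
    indices). The planted module occupies the first ``planted_module_size``
    SNPs of chromosome 1 and all its pairs interact with one calibrated
    positive coefficient (see :func:`epinet.simdata.planted_module`).
    """
    spec = simdata.PedigreeSpec(
        n_families=n_families,
        generations=generations,
        offspring_per_couple=offspring_per_couple,
    )
    G, ped = simdata.simulate_pedigree_genotypes(spec, n_snps, _seed_for(seed, 1))
    K = simdata.expected_kinship(ped)
    cov = simdata.simulate_covariates(G.n_samples, _seed_for(seed, 2))
    base = simdata.TraitModel(
        beta_age=-0.01, beta_sex=0.1, sigma_g2=sigma_g2, sigma_e2=sigma_e2
    )
    planted = np.array([], dtype=int)
    model = base
    if planted_module_size:
        planted = np.arange(planted_module_size)
        model = simdata.planted_module(
            G, planted, interaction_var_frac, base, _seed_for(seed, 3)
        )
    pheno = simdata.simulate_phenotype(G, K, model, cov, _seed_for(seed, 4))
    return G, ped, K, pheno, model, planted


def gwas_calibration(
    seed: int, n_families: int = 200, n_snps: int = 5000, h2: float = 0.4
) -> dict:
    """Null GWAS on a related cohort: GLMM vs naive regression calibration.

    Simulates a polygenic trait with no per-SNP fixed effects on a
    200-family pedigree, fits the kinship GLMM with the empirical GRM, and
    score-tests every SNP. Returns lambda_GC and empirical type-I error at
    alpha = 0.05 for the GLMM, and lambda_GC for covariate-only ordinary
    regression that ignores relatedness.
    """
    G, ped, K, pheno, _, _ = simulate_cohort(
        seed, n_families=n_families, n_snps=n_snps,
        sigma_g2=h2, sigma_e2=1.0 - h2,
    )
    y = genotype_io.int_transform(pheno["pheno"])
    X = np.column_stack([np.ones(G.n_samples), pheno["age"], pheno["sex"]])
    grm = relatedness_glmm.compute_grm(G)
    null = relatedness_glmm.fit_null(y, X, grm)
    gwas = relatedness_glmm.score_test_many(null, G)
    p_glmm = gwas["p"].to_numpy()
    p_naive = relatedness_glmm.ols_score_tests(y, X, G)
    return {
        "n_samples": G.n_samples,
        "n_snps": n_snps,
        "h2_hat": null.h2_hat,
        "lambda_glmm": relatedness_glmm.genomic_inflation(p_glmm),
        "lambda_naive": relatedness_glmm.genomic_inflation(p_naive),
        "type_i_error": float((p_glmm < 0.05).mean()),
    }


def h2_recovery(
    seed: int,
    n_seeds: int = 20,
    h2: float = 0.5,
    n_families: int = 100,
    n_snps: int = 200,
) -> dict:
    """Repeated REML variance-component recovery on one pedigree layout.

    The pedigree (and hence the expected kinship and its eigendecomposition)
    is fixed; each replicate draws a fresh polygenic trait with the given
    heritability and refits the null model against the true kinship.
    """
    spec = simdata.PedigreeSpec(n_families=n_families, generations=2,
                                offspring_per_couple=3)
    G, ped = simdata.simulate_pedigree_genotypes(spec, n_snps, _seed_for(seed, 10))
    K = simdata.expected_kinship(ped)
    eig = np.linalg.eigh(K)
    n = G.n_samples
    model = simdata.TraitModel(beta_age=-0.01, beta_sex=0.1,
                               sigma_g2=h2, sigma_e2=1.0 - h2)
    estimates = []
    for r in range(n_seeds):
        cov = simdata.simulate_covariates(n, _seed_for(seed, 100 + r))
        pheno = simdata.simulate_phenotype(G, K, model, cov, _seed_for(seed, 200 + r))
        y = genotype_io.int_transform(pheno["pheno"])
        X = np.column_stack([np.ones(n), pheno["age"], pheno["sex"]])
        null = relatedness_glmm.fit_null(y, X, K, eig=eig, compute_P=False)
        estimates.append(null.h2_hat)
    return {
        "n_samples": n,
        "h2_true": h2,
        "h2_estimates": estimates,
        "h2_mean": float(np.mean(estimates)),
    }


def module_recovery(
    seed: int,
    n_families: int = 200,
    n_snps: int = 2000,
    module_size: int = 30,
    interaction_var_frac: float = 0.05,
    soft_power: int | None = None,
    min_module_size: int = 30,
) -> dict:
    """Planted-module discovery + replication, one seed.

    Discovery: simulate a cohort with a planted all-pairs interacting
    module, scan every SNP pair on the covariate-residualized INT trait,
    build the interaction network, detect modules, and test each module
    eigengene in the kinship GLMM. The top module is the non-grey module
    with the smallest association p.

    Replication: an independent cohort drawn from the same generative
    truth, a fresh GLMM GWAS, and the rank-based set test of the top
    module's SNPs.

    Returns the fraction of planted SNPs captured by the top module, the
    top module's eigengene p, and the replication set-test p.
    """
    G, ped, K, pheno, model, planted = simulate_cohort(
        seed, n_families=n_families, n_snps=n_snps,
        sigma_g2=0.3, sigma_e2=0.7,
        planted_module_size=module_size,
        interaction_var_frac=interaction_var_frac,
    )
    n = G.n_samples
    y = genotype_io.int_transform(pheno["pheno"])
    cov = np.column_stack([pheno["age"], pheno["sex"]])

    keep = episnet.ld_prune(G, dprime_min=0.9, max_block=1000)
    Gp = G.subset_snps(keep)
    y_adj = episnet.residualize_covariates(y, cov)
    scan = episnet.pairwise_scan(Gp, y_adj)
    _, TOM, power = episnet.build_network(scan, soft_power=soft_power)
    labels = episnet.detect_modules(1.0 - TOM, min_module_size=min_module_size)
    grm = relatedness_glmm.compute_grm(G)
    eig = np.linalg.eigh(grm)
    modules = episnet.build_module_set(Gp, labels, y, cov, grm, eig=eig)

    planted_ids = set(G.snps["snp_id"].iloc[planted])
    if len(modules.assoc):
        top = modules.assoc.iloc[0]
        top_ids = set(modules.members(top["module"]))
        recovery = len(top_ids & planted_ids) / len(planted_ids)
        me_p = float(top["p"])
    else:
        top_ids, recovery, me_p = set(), 0.0, 1.0

    # independent cohort from the same generative truth
    G2, ped2, K2, pheno2, _, _ = simulate_cohort(
        _seed_for(seed, 77), n_families=n_families, n_snps=n_snps,
        sigma_g2=0.3, sigma_e2=0.7,
    )
    pheno2 = simdata.simulate_phenotype(
        G2, K2, model, pheno2[["age", "sex"]], _seed_for(seed, 78)
    )
    y2 = genotype_io.int_transform(pheno2["pheno"])
    X2 = np.column_stack([np.ones(G2.n_samples), pheno2["age"], pheno2["sex"]])
    grm2 = relatedness_glmm.compute_grm(G2)
    null2 = relatedness_glmm.fit_null(y2, X2, grm2)
    gwas2 = relatedness_glmm.score_test_many(null2, G2)
    if top_ids:
        lab = pd.Series("grey", index=G.snps["snp_id"].to_numpy(), name="module")
        lab.loc[list(top_ids)] = "top"
        rep = replication.replicate_modules(lab, gwas2, modules=["top"])
        repl_p = float(rep["p"].iloc[0]) if rep["testable"].iloc[0] else 1.0
    else:
        repl_p = 1.0
    return {
        "n_samples": n,
        "n_snps_pruned": int(len(keep)),
        "soft_power": power,
        "recovery": float(recovery),
        "module_p": me_p,
        "replication_p": repl_p,
        "top_module_size": len(top_ids),
    }


def interaction_null_uniformity(seed: int, n_snps: int = 150,
                                n_families: int = 200) -> dict:
    """KS uniformity of pairwise interaction p under a permuted phenotype.

    Uses a founders-only cohort: each pair's p-value is uniform under the
    permuted trait regardless of relatedness (exchangeability), but family
    structure correlates genotypes across pairs, and the KS comparison
    assumes its ~1e4 draws are independent.
    """
    G, ped, K, pheno, _, _ = simulate_cohort(
        seed, n_families=n_families, n_snps=n_snps, sigma_g2=0.3, sigma_e2=0.7,
        generations=1,
    )
    rng = np.random.default_rng(_seed_for(seed, 5))
    y = genotype_io.int_transform(pheno["pheno"])
    y_perm = rng.permutation(y)
    y_adj = episnet.residualize_covariates(
        y_perm, np.column_stack([pheno["age"], pheno["sex"]])
    )
    scan = episnet.pairwise_scan(G, y_adj)
    p = scan.p[scan.estimable]
    ks = stats.kstest(p, "uniform")
    return {"n_pairs": int(p.size), "ks_p": float(ks.pvalue)}


def gene_set_null_uniformity(seed: int, n_draws: int = 1000,
                             universe: int = 1000, set_size: int = 20) -> dict:
    """KS uniformity of the set-test p over random SNP subsets."""
    rng = np.random.default_rng(_seed_for(seed, 6))
    all_stats = rng.standard_normal(universe)
    ps = []
    for _ in range(n_draws):
        idx = rng.choice(universe, size=set_size, replace=False)
        ps.append(replication.gene_set_test(all_stats[idx], all_stats, "mixed"))
    ks = stats.kstest(np.asarray(ps), "uniform")
    return {"n_draws": n_draws, "ks_p": float(ks.pvalue)}
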