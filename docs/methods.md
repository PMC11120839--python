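# Methods

This note documents the statistical models, the numerical choices, the
synthetic-data generator, and the known limits of the `epinet` pipeline.

## Trait preparation

The raw trait is transformed by the rank-based inverse normal
transformation: z_i = Φ⁻¹((r_i − c)/(n − 2c + 1)) with the Blom offset
c = 3/8 (config `int_offset`), average ranks for ties, and missing values
excluded from ranking and reinserted as missing. The transform depends
only on ranks, so any monotone rescaling of the raw scale is immaterial.
Degenerate inputs (all values equal, n < 2) are errors rather than
silently propagated constants.

## Marker QC

SNPs are oriented to the empirically minor allele (ties broken toward the
lexicographically smaller allele); file A1/A2 designations are never
trusted. The MAF filter removes maf < 0.01 (strict; a SNP at exactly the
threshold is retained). Hardy–Weinberg testing uses the exact conditional
test — full enumeration of heterozygote counts given the allele counts,
two-sided by summing configurations no more likely than the observed one,
mid-p off — evaluated only on MAF-passing SNPs, so the removal counts
partition the input. The exact test rather than χ² because it is the
field standard for low-MAF markers and is deterministic at any count; the
two agree within |Δp| < 0.01 for large balanced counts. Missing genotypes
are kept as missing in storage and mean-imputed per SNP only at the point
of GRM/regression computation, so QC statistics see the real data.

## Mixed-model GWAS

The GRM is the centered estimator K = WWᵀ/m, W the mean-imputed dosages
centered by 2p̂ per column; its diagonal averages the mean 2pq over
markers rather than 1 (a standardized variant is not needed by any
downstream stage and was left out). The null GLMM y = Xβ + g + e,
g ~ N(0, σ²g K), is fit by REML: one eigendecomposition of K, then the
profile likelihood of h² = σ²g/(σ²g + σ²e) is maximized by bounded scalar
search (Brent, tolerance 1e-8) with total variance profiled out in closed
form; the h² = 0 boundary is checked explicitly. Per-variant score tests
use U = gᵀPy and Var(U) = gᵀPg with P = V⁻¹ − V⁻¹X(XᵀV⁻¹X)⁻¹XᵀV⁻¹; a
variant constant after projection is reported at p = 1 with a flag. The
sign of U is reported: positive means the minor allele increases the
transformed trait. λ_GC is the median test χ² over 0.4549.

On simulated 200-family pedigrees (n = 1000, h² = 0.4, 5000 null SNPs)
the score test's measured λ_GC is within [0.95, 1.05] with type-I error
at α = 0.05 of ~0.052, while covariate-only ordinary regression on the
same data inflates to λ ≈ 1.35 — the quantitative case for carrying the
kinship term. These numbers are recomputed by `scripts/acceptance.py`,
not quoted from anywhere.

## Interaction scan

Pairs are screened from GWAS-prefiltered (p < 0.01 by default) and
LD-pruned SNPs. Pruning is greedy and position-ordered within chromosome:
a block grows while the candidate's D′ with the block's *first* member
(the tag) stays ≥ 0.9 and the block holds < 1000 SNPs; tags survive. D′
comes from the standard two-locus EM on unphased dosages (only the double
heterozygote is phase-ambiguous; 200 iterations, tolerance 1e-8;
non-convergence is treated as unlinked). The scan itself fits the
four-parameter OLS interaction model to every unordered pair of the
covariate-residualized INT trait. Residualizing age and sex before the
scan (config `scan_residualize`) keeps the screen consistent with the
covariate-adjusted module test. Family structure is deliberately *not*
modeled inside the O(k²) scan — only in the module-level GLMM — trading
per-pair exactness for a tractable screen; the permutation-null KS checks
confirm the per-pair p-values are uniform under exchangeable traits.

All pair-level cross products are assembled from a handful of k×k matrix
products and the normal equations are solved in vectorized batches, so a
2000-SNP scan (~2×10⁶ pairs, n = 1000) runs in seconds. Singular designs
(constant SNP, collinear product) are flagged non-estimable with p = 1.

## Network and modules

Similarity is the interaction −log₁₀ p, truncated at a ceiling (default
8.0) and divided by the maximum so it lies in [0, 1]; |t| is available as
a config alternative. The ceiling matters: evidence beyond genome-wide
strength carries no extra ranking information, and without it a single
extreme pair rescales every other true edge toward zero and no module can
coalesce. Adjacency is the soft-thresholded similarity s^β with β the
smallest power in 1..20 whose scale-free fit reaches R² ≥ 0.8 (negative
slope required; fallback 6), and the topological overlap
TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i, k_j) + 1 − a_ij) defines the
dissimilarity 1 − TOM. Modules come from average-linkage hierarchical
clustering cut at a fixed fraction (0.99) of the maximum merge height;
clusters below `min_module_size` (30) become "grey". This static cut is a
simplified stand-in for adaptive branch-cutting procedures; on
block-structured similarity it recovers planted blocks exactly, and it is
deterministic. Modules are named by decreasing size along the
conventional color sequence (largest = turquoise).

Each module eigengene is the first left singular vector of the module's
standardized dosage matrix, unit norm, sign-fixed to correlate positively
with the module's mean standardized dosage (so an allele-orientation flip
of every SNP negates it deterministically). The eigengene is tested as a
fixed effect in the kinship GLMM (Wald, normal reference, variance
components refit with the eigengene in the design); with K = I this is
ordinary regression.

**A structural caveat.** For centered genotypes of unlinked loci, a purely
epistatic component Σ β_ij (g_i − μ_i)(g_j − μ_j) is uncorrelated with
*every* linear combination of the dosages — including the module
eigengene. The ME test therefore detects a module only through whatever
marginal (additive) effects its interaction terms induce, not through the
epistasis itself. In the worked example the module is recovered perfectly
and replicates at p ~ 1e-9, yet its ME p is only 0.07. This is an
inherent property of eigengene association for interactive signals, not
an implementation artifact.

## Replication

The set test asks whether a module's SNPs are collectively extreme among
the replication GWAS score statistics: Wilcoxon rank-sum of the module
SNPs against all remaining SNPs, on |score| for the default "mixed"
alternative (module effects need not share direction; "up", "down",
"either" use signed values), exact enumeration for sets of ≤ 10, normal
approximation with continuity correction otherwise (the two agree within
|Δp| < 0.005 at n_set = 10 in a universe of 100). SNPs are matched by
identifier; a module with under half its SNPs present in the replication
panel is marked untestable rather than failed. Replication is declared at
p < 0.01, strict.

## Gene-level tests

SNPs map to a gene when within 50 kb of its span (boundaries inclusive;
BED input is converted from 0-based half-open to 1-based inclusive; 'chr'
prefixes are normalized). The gene statistic is Σ qchisq(p_i, 1),
referred to χ²(n) under independence, or — the default when genotypes are
available — to a Monte-Carlo null: ≥ 1e5 seeded multivariate-normal draws
with the observed genotype correlation, p = (exceedances + 1)/(draws + 1),
which collapses to the single-SNP p under perfect LD and matches the
closed form under identity LD. Zero p-values are clipped to the smallest
positive float with a warning. Enrichment of significant genes (p < 0.01)
against user-supplied gene sets is the one-sided hypergeometric upper
tail with Benjamini–Hochberg correction across the sets of one call. No
annotation database is bundled; coordinates come from the caller's BED.

## The synthetic cohorts

The generator emulates a family study: couples of founders, a fixed
number of offspring per couple, and (for deeper pedigrees) a married-in
founder per generation; founder genotypes are binomial in per-SNP founder
frequencies drawn from a configurable range (default 0.05–0.5), and
non-founders receive one allele from each parent per SNP (unlinked SNPs;
an optional copy-with-flip mode generates LD blocks for the pruning
stage). Age is uniform on 60–100 and sex Bernoulli(1/2), mirroring an
elderly family-study covariate spread. The trait adds covariate effects,
planted main effects and raw-product pairwise interactions, a polygenic
term with covariance σ²g·K (K the exact pedigree relationship matrix),
and Gaussian noise; everything runs off one seeded generator and the seed
lands in the truth JSON.

`planted_module` plants all pairs of a chosen SNP set with a common
coefficient magnitude and **random signs**, scaled so the component's
realized variance hits a target fraction of the genetic-plus-residual
variance. Random signs are essential: with a shared sign the raw products
add coherently into a dominant additive component (~94% of the planted
variance for a dense 10-SNP module at maf ≈ 0.3), and the "epistatic"
module would really be an additive one.

What the simulations do not emulate: realistic human LD maps, allele
frequency spectra, genotyping error, informative missingness, assortative
mating, or X-chromosome inheritance. Passing tests therefore demonstrate
the statistical machinery under clean Mendelian sampling, not robustness
to the full messiness of array data.

## Problem sizes and detectability

The bundled experiments run at desk scale: calibration on n = 1000 with
5000 SNPs; heritability recovery over 20 replicates at n = 500;
module-recovery at n = 1000 with 2000 candidate SNPs and a planted
30-SNP module at a 5% interaction-variance share, ten seeds; the worked
example uses a 5-SNP module at a 50% share. The 30-SNP/5% setting is an
instructive negative control: its variance spreads over 435 pairs, giving
per-pair noncentralities ≪ 1, while standing out among the ~2×10⁶ null
pairs of a 2000-SNP scan requires roughly −log₁₀ p > 6.5 (ncp ≈ 25) —
even concentrating the entire 5% in one pair falls short. No similarity
construction or clustering method can recover a module whose every edge
is below the noise ceiling; detection at that signal size needs on the
order of tenfold more variance or sample. The measured recovery rate (0
of 10 seeds) is reported honestly by the acceptance script.

## Determinism

All randomness flows through seeded `numpy` generators; stage seeds are
derived from the run seed via `SeedSequence`. A pipeline re-run with the
same config and seed is byte-identical, which the test suite and the
acceptance script verify by hashing every output.
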