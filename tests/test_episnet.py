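"""Interaction scan, LD pruning, network construction, and module detection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epinet import episnet, genotype_io, simdata
from epinet.containers import GenotypeMatrix
from epinet.errors import ConfigurationError, DataError, NumericalError


def _matrix(columns, chrom=None, pos=None):
    cols = [np.asarray(c, dtype=float) for c in columns]
    dos = np.column_stack(cols)
    k = len(cols)
    snps = pd.DataFrame(
        {
            "snp_id": [f"s{i}" for i in range(k)],
            "chrom": chrom if chrom is not None else ["1"] * k,
            "pos": pos if pos is not None else np.arange(1, k + 1) * 1000,
            "allele_minor": "A",
            "allele_major": "G",
            "maf": 0.0,
        }
    )
    return GenotypeMatrix(dos, snps, pd.Index([f"i{j}" for j in range(dos.shape[0])]))


def _fake_result(k, p, estimable=None):
    p = np.asarray(p, dtype=float)
    est = np.ones(p.size, bool) if estimable is None else estimable
    return episnet.InteractionResult(
        n_snps=k, beta=np.zeros(p.size), tstat=np.zeros(p.size), p=p,
        estimable=est, snp_ids=np.array([f"s{i}" for i in range(k)]),
    )


class TestGwasFilter:
    def test_selects_exactly_sub_threshold_snps(self):
        gwas = pd.DataFrame({"p": [0.5, 0.005, 0.02, 1e-6]})
        assert list(episnet.filter_by_gwas(gwas, 0.01)) == [1, 3]

    def test_empty_selection_is_an_error(self):
        gwas = pd.DataFrame({"p": [0.5, 0.5]})
        with pytest.raises(DataError):
            episnet.filter_by_gwas(gwas)


class TestDprime:
    def test_identical_snps_full_ld(self):
        rng = np.random.default_rng(1)
        g = rng.binomial(2, 0.3, 400).astype(float)
        assert episnet.estimate_dprime(g, g) == pytest.approx(1.0, abs=1e-9)

    def test_independent_snps_near_zero(self):
        rng = np.random.default_rng(2)
        g1 = rng.binomial(2, 0.4, 2000).astype(float)
        g2 = rng.binomial(2, 0.35, 2000).astype(float)
        assert episnet.estimate_dprime(g1, g2) < 0.1

    def test_em_matches_direct_count_without_double_hets(self):
        """With no phase-ambiguous individuals EM equals haplotype counting."""
        rng = np.random.default_rng(3)
        hap_freq = {(1, 1): 0.2, (1, 0): 0.1, (0, 1): 0.25, (0, 0): 0.45}
        haps = list(hap_freq)
        probs = np.array(list(hap_freq.values()))
        while True:
            pick = rng.choice(4, size=(500, 2), p=probs)
            h1 = np.array([haps[i] for i in pick[:, 0]])
            h2 = np.array([haps[i] for i in pick[:, 1]])
            g1 = (h1[:, 0] + h2[:, 0]).astype(float)
            g2 = (h1[:, 1] + h2[:, 1]).astype(float)
            keep = ~((g1 == 1) & (g2 == 1))  # drop double hets: phase known
            if keep.sum() > 300:
                break
        g1, g2 = g1[keep], g2[keep]
        h_all = np.concatenate([h1[keep], h2[keep]])
        p11_direct = np.mean((h_all[:, 0] == 1) & (h_all[:, 1] == 1))
        p11_em, pA, pB, conv = episnet.em_haplotype_freq(g1, g2)
        assert conv
        assert p11_em == pytest.approx(p11_direct, abs=1e-6)

    def test_monomorphic_rejected(self):
        with pytest.raises(DataError):
            episnet.estimate_dprime(np.zeros(10), np.ones(10))


class TestLdPrune:
    def test_duplicate_snp_removed(self):
        rng = np.random.default_rng(4)
        g = rng.binomial(2, 0.3, 300).astype(float)
        h = rng.binomial(2, 0.4, 300).astype(float)
        G = _matrix([g, g, h])
        assert list(episnet.ld_prune(G)) == [0, 2]

    def test_independent_snps_all_retained(self):
        rng = np.random.default_rng(5)
        G = _matrix([rng.binomial(2, 0.3, 500) for _ in range(6)])
        assert list(episnet.ld_prune(G)) == list(range(6))

    def test_matches_bruteforce_greedy_oracle(self):
        """20 SNPs with a planted 5-SNP perfect-LD block: compare against an
        independent implementation of the same greedy rule."""
        rng = np.random.default_rng(6)
        cols = [rng.binomial(2, rng.uniform(0.1, 0.5), 400).astype(float)
                for _ in range(20)]
        for j in range(8, 12):  # near-perfect LD block tagged by SNP 7
            flip = rng.random(400) < 0.01
            cols[j] = np.where(flip, rng.binomial(2, 0.3, 400), cols[7])
        G = _matrix(cols)

        def oracle(G, dmin=0.9, max_block=1000):
            tags, tag, size = [], None, 0
            for j in range(G.n_snps):
                if tag is None:
                    tags.append(j); tag, size = j, 1
                    continue
                try:
                    dp = episnet.estimate_dprime(G.dosages[:, tag], G.dosages[:, j])
                except DataError:
                    dp = 0.0
                if dp >= dmin and size < max_block:
                    size += 1
                else:
                    tags.append(j); tag, size = j, 1
            return tags

        assert list(episnet.ld_prune(G)) == oracle(G)

    def test_idempotence(self):
        rng = np.random.default_rng(7)
        cols = [rng.binomial(2, 0.3, 300).astype(float) for _ in range(10)]
        cols[4] = cols[3]
        G = _matrix(cols)
        once = episnet.ld_prune(G)
        again = episnet.ld_prune(G.subset_snps(once))
        assert list(again) == list(range(len(once)))

    def test_max_block_size_limits_pruning(self):
        rng = np.random.default_rng(8)
        g = rng.binomial(2, 0.4, 300).astype(float)
        G = _matrix([g] * 5)
        kept = episnet.ld_prune(G, max_block=2)
        assert list(kept) == [0, 2, 4]

    def test_unsorted_positions_rejected(self):
        rng = np.random.default_rng(9)
        G = _matrix([rng.binomial(2, 0.3, 100) for _ in range(3)],
                    pos=[300, 100, 200])
        with pytest.raises(DataError):
            episnet.ld_prune(G)


class TestPairwiseScan:
    def test_pair_count_is_k_choose_2(self):
        rng = np.random.default_rng(10)
        G = _matrix([rng.binomial(2, 0.3, 50) for _ in range(9)])
        res = episnet.pairwise_scan(G, rng.standard_normal(50))
        assert res.n_pairs == 36

    def test_constant_snp_flagged_non_estimable(self):
        rng = np.random.default_rng(11)
        G = _matrix([rng.binomial(2, 0.3, 60), np.full(60, 1.0)])
        res = episnet.pairwise_scan(G, rng.standard_normal(60))
        assert not res.estimable[0]
        assert res.p[0] == 1.0

    def test_planted_interaction_coefficient_recovered(self):
        rng = np.random.default_rng(12)
        n = 2000
        g1 = rng.binomial(2, 0.4, n).astype(float)
        g2 = rng.binomial(2, 0.4, n).astype(float)
        g3 = rng.binomial(2, 0.3, n).astype(float)
        y = g1 * g2 + rng.normal(0, 0.5, n)
        G = _matrix([g1, g2, g3])
        res = episnet.pairwise_scan(G, y)
        assert res.beta[0] == pytest.approx(1.0, abs=0.1)
        assert res.p[0] < 1e-10

    def test_matches_statsmodels_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(13)
        n = 150
        cols = [rng.binomial(2, 0.35, n).astype(float) for _ in range(5)]
        y = rng.standard_normal(n)
        G = _matrix(cols)
        res = episnet.pairwise_scan(G, y)
        ii, jj = res.pair_indices()
        for idx in [0, 4, 9]:
            i, j = ii[idx], jj[idx]
            X = np.column_stack([np.ones(n), cols[i], cols[j], cols[i] * cols[j]])
            fit = sm.OLS(y, X).fit()
            assert res.beta[idx] == pytest.approx(fit.params[3], rel=1e-8)
            assert res.tstat[idx] == pytest.approx(fit.tvalues[3], rel=1e-8)
            assert res.p[idx] == pytest.approx(fit.pvalues[3], rel=1e-8)

    def test_too_few_samples_rejected(self):
        G = _matrix([[0, 1, 2, 1], [1, 1, 0, 2]])
        with pytest.raises(DataError):
            episnet.pairwise_scan(G, np.zeros(4))


class TestHotspotsAndTotals:
    def test_single_populated_cell_is_one(self):
        res = _fake_result(2, [0.01])
        mat = episnet.interaction_hotspots(res, np.array(["1", "2"]))
        assert mat[0, 1] == 1.0 and mat[1, 0] == 1.0
        assert np.isnan(mat[2, 2])

    def test_degenerate_rescale_documented_constant(self):
        res = _fake_result(3, [0.05, 0.05, 0.05])
        mat = episnet.interaction_hotspots(res, np.array(["1", "1", "2"]))
        vals = mat[np.isfinite(mat)]
        assert np.all(vals == 1.0)

    def test_planted_enrichment_cell_is_maximum(self):
        rng = np.random.default_rng(14)
        k = 40
        chrom = np.array(["1"] * 10 + ["2"] * 10 + ["3"] * 10 + ["4"] * 10)
        i, j = np.triu_indices(k, 1)
        p = rng.uniform(0.05, 1.0, i.size)
        strong = (chrom[i] == "3") & (chrom[j] == "4")
        p[strong] = 1e-8
        res = _fake_result(k, p)
        mat = episnet.interaction_hotspots(res, chrom)
        assert mat[2, 3] == np.nanmax(mat) == 1.0

    def test_totals_double_counting_identity(self):
        rng = np.random.default_rng(15)
        res = _fake_result(8, rng.uniform(size=28))
        totals = episnet.sum_effect_sizes(res)
        assert totals.sum() == pytest.approx(2 * res.neglog10p().sum())

    def test_hub_snp_ranks_first_and_isolated_is_zero(self):
        k = 12
        i, j = np.triu_indices(k, 1)
        p = np.full(i.size, 0.9)
        est = np.ones(i.size, bool)
        est[(i == 5) | (j == 5)] = False  # SNP 5 never estimable
        hub = (i == 0) | (j == 0)
        p[hub] = 1e-6
        res = _fake_result(k, p, est)
        totals = episnet.sum_effect_sizes(res)
        assert totals.argmax() == 0
        assert totals[5] == 0.0


class TestNetwork:
    def test_shared_partners_give_high_tom(self):
        """Two SNPs strongly tied to every third SNP overlap topologically."""
        k = 10
        i, j = np.triu_indices(k, 1)
        p = np.full(i.size, 0.99)
        both = (i < 2) | (j < 2)
        p[both] = 1e-8
        res = _fake_result(k, p)
        _, TOM, _ = episnet.build_network(res, soft_power=6)
        assert TOM[0, 1] > 0.9

    def test_isolated_pair_with_unit_similarity(self):
        """Power 1, a single s = 1 edge between two otherwise isolated SNPs."""
        k = 4
        i, j = np.triu_indices(k, 1)
        p = np.ones(i.size)
        est = np.zeros(i.size, bool)
        edge = (i == 0) & (j == 1)
        p[edge] = 1e-4
        est[edge] = True
        res = _fake_result(k, p, est)
        A, TOM, _ = episnet.build_network(res, soft_power=1)
        assert A[0, 1] == pytest.approx(1.0)
        assert TOM[0, 1] == pytest.approx(1.0)

    def test_symmetry_and_unit_bounds(self):
        rng = np.random.default_rng(16)
        res = _fake_result(30, rng.uniform(size=435))
        A, TOM, _ = episnet.build_network(res, soft_power=6)
        for M in (A, TOM):
            assert np.allclose(M, M.T)
            assert M.min() >= 0.0 and M.max() <= 1.0

    def test_power_selection_returns_fallback_on_noise(self):
        rng = np.random.default_rng(17)
        res = _fake_result(60, rng.uniform(size=60 * 59 // 2))
        S = episnet.similarity_matrix(res)
        power, table = episnet.pick_soft_power(S)
        assert 1 <= power <= 20
        assert len(table) == 20

    def test_all_zero_similarity_is_an_error(self):
        res = _fake_result(5, np.ones(10), np.zeros(10, bool))
        with pytest.raises(NumericalError):
            episnet.build_network(res, soft_power=6)


class TestModules:
    def _two_block_result(self, rng, k=120, block=50):
        i, j = np.triu_indices(k, 1)
        p = rng.uniform(size=i.size)
        for lo in (0, block):
            m = (i >= lo) & (i < lo + block) & (j >= lo) & (j < lo + block)
            p[m] = 10 ** (-rng.uniform(4, 8, m.sum()))
        return _fake_result(k, p)

    def test_two_planted_blocks_recovered(self):
        rng = np.random.default_rng(18)
        res = self._two_block_result(rng)
        _, TOM, _ = episnet.build_network(res, soft_power=6)
        labels = episnet.detect_modules(1.0 - TOM, min_module_size=30)
        non_grey = [m for m in pd.unique(labels) if m != "grey"]
        assert len(non_grey) == 2
        for lo in (0, 50):
            block_labels = labels[lo:lo + 50]
            top = pd.Series(block_labels).mode()[0]
            assert (block_labels == top).mean() >= 0.95

    def test_largest_module_is_turquoise(self):
        rng = np.random.default_rng(19)
        k, i_j = 130, np.triu_indices(130, 1)
        i, j = i_j
        p = rng.uniform(size=i.size)
        blocks = [(0, 60), (60, 100)]  # sizes 60 and 40
        for lo, hi in blocks:
            m = (i >= lo) & (i < hi) & (j >= lo) & (j < hi)
            p[m] = 10 ** (-rng.uniform(4, 8, m.sum()))
        res = _fake_result(k, p)
        _, TOM, _ = episnet.build_network(res, soft_power=6)
        labels = episnet.detect_modules(1.0 - TOM, min_module_size=30)
        sizes = pd.Series(labels)[lambda s: s != "grey"].value_counts()
        assert sizes.index[0] == "turquoise"
        assert set(sizes.index) == {"turquoise", "blue"}

    def test_uniform_noise_mostly_grey(self):
        rng = np.random.default_rng(20)
        res = _fake_result(100, rng.uniform(size=4950))
        _, TOM, _ = episnet.build_network(res, soft_power=6)
        labels = episnet.detect_modules(1.0 - TOM, min_module_size=30)
        assert (labels == "grey").mean() > 0.5


class TestEigengene:
    def _module_matrix(self, rng, n=200):
        base = rng.binomial(2, 0.4, n).astype(float)
        cols = [base, base, base, rng.binomial(2, 0.3, n).astype(float)]
        return _matrix(cols)

    def test_identical_columns_give_standardized_column(self):
        rng = np.random.default_rng(21)
        G = self._module_matrix(rng)
        labels = np.array(["turquoise"] * 3 + ["grey"])
        me = episnet.module_eigengene(G, labels)["turquoise"].to_numpy()
        z = G.dosages[:, 0] - G.dosages[:, 0].mean()
        z = z / np.linalg.norm(z)
        assert np.allclose(np.abs(me), np.abs(z), atol=1e-8)
        assert me @ z > 0  # sign convention: along the mean dosage

    def test_first_pc_maximizes_explained_variance(self):
        rng = np.random.default_rng(22)
        G = _matrix([rng.binomial(2, 0.4, 150) for _ in range(6)])
        labels = np.array(["turquoise"] * 6)
        me = episnet.module_eigengene(G, labels)["turquoise"].to_numpy()
        Z = G.dosages - G.dosages.mean(0)
        Z = Z / Z.std(0)
        sv = np.linalg.svd(Z, compute_uv=False)
        assert np.linalg.norm(Z.T @ me) == pytest.approx(sv[0], rel=1e-8)

    def test_allele_flip_negates_eigengene_deterministically(self):
        rng = np.random.default_rng(23)
        G = _matrix([rng.binomial(2, 0.35, 120) for _ in range(5)])
        labels = np.array(["turquoise"] * 5)
        me = episnet.module_eigengene(G, labels)["turquoise"].to_numpy()
        flipped = _matrix([2.0 - G.dosages[:, j] for j in range(5)])
        me_f = episnet.module_eigengene(flipped, labels)["turquoise"].to_numpy()
        assert np.allclose(me_f, -me, atol=1e-8)

    def test_singleton_module_is_standardized_dosage(self):
        rng = np.random.default_rng(24)
        G = _matrix([rng.binomial(2, 0.4, 80)])
        me = episnet.module_eigengene(G, np.array(["turquoise"]))["turquoise"]
        z = G.dosages[:, 0] - G.dosages[:, 0].mean()
        z = z / np.linalg.norm(z)
        assert np.allclose(np.abs(me), np.abs(z), atol=1e-8)


class TestModuleAssociation:
    def test_identity_kinship_matches_ols(self):
        rng = np.random.default_rng(25)
        n = 300
        me = rng.standard_normal(n)
        cov = np.column_stack([rng.uniform(60, 100, n), rng.integers(1, 3, n)])
        y = 0.3 * me + rng.standard_normal(n)
        coef, p = episnet.module_association(me, y, cov, np.eye(n))
        X = np.column_stack([np.ones(n), cov, me])
        b_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert coef == pytest.approx(b_ols[-1], abs=1e-8)
        assert p < 0.01

    def test_permuted_eigengene_is_null(self):
        rng = np.random.default_rng(26)
        n = 250
        me = rng.standard_normal(n)
        cov = np.column_stack([rng.uniform(60, 100, n), rng.integers(1, 3, n)])
        y = rng.standard_normal(n)
        eye = np.eye(n)
        eig = (np.ones(n), eye)
        ps = [
            episnet.module_association(rng.permutation(me), y, cov, eye, eig=eig)[1]
            for _ in range(120)
        ]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_collinear_eigengene_rejected(self):
        n = 100
        rng = np.random.default_rng(27)
        cov = np.column_stack([rng.uniform(60, 100, n), np.ones(n)])
        with pytest.raises(DataError):
            episnet.module_association(cov[:, 0], rng.standard_normal(n),
                                       cov, np.eye(n))
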