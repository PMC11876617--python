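"""Genotype QC, windows, kinship, REML heritability and permutation nulls."""

import numpy as np
import pandas as pd
import pytest

from pleionet import genetics as gen
from pleionet import simulate
from pleionet.simulate import GenotypeMatrix


def _panel(dosage, positions=None, chrom="1"):
    dosage = np.asarray(dosage, dtype=float)
    m = dosage.shape[1]
    pos = positions if positions is not None else 1 + np.arange(m) * 100
    snps = pd.DataFrame(
        {"chrom": chrom, "pos": pos, "id": [f"s{i}" for i in range(m)],
         "ref": "A", "alt": "T"}
    )
    return GenotypeMatrix(dosage=dosage, snps=snps,
                          individuals=[f"i{k}" for k in range(dosage.shape[0])])


class TestMafFilter:
    def test_boundary_is_strict_below(self):
        # col0: MAF 0.005 (1 alt allele in 200 haplotypes) -> removed
        # col1: MAF exactly 0.01 (2 alt alleles) -> retained
        d = np.zeros((100, 2))
        d[0, 0] = 1.0
        d[0, 1] = 1.0
        d[1, 1] = 1.0
        panel = _panel(d)
        kept = gen.maf_filter(panel, maf_min=0.01)
        assert list(kept.snps["id"]) == ["s1"]

    def test_matches_bruteforce_frequencies(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, size=(40, 30)).astype(float)
        panel = _panel(d)
        kept = gen.maf_filter(panel, maf_min=0.1)
        expected = []
        for j in range(30):
            p = d[:, j].mean() / 2
            if min(p, 1 - p) >= 0.1:
                expected.append(f"s{j}")
        assert list(kept.snps["id"]) == expected


class TestLd:
    def test_r2_identical_and_complementary(self):
        x = np.array([0.0, 1, 2, 0, 2, 1])
        assert np.isclose(gen.ld_r2(x, x), 1.0)
        assert np.isclose(gen.ld_r2(x, 2 - x), 1.0)

    def test_r2_constant_is_nan(self):
        assert np.isnan(gen.ld_r2(np.ones(5), np.arange(5.0)))

    def test_prune_drops_later_duplicate(self):
        x = np.random.default_rng(1).integers(0, 3, 20).astype(float)
        panel = _panel(np.column_stack([x, x, 2 - x]))
        kept = gen.ld_prune(panel, r2_max=0.7)
        assert list(kept) == [0]

    def test_prune_keeps_independent_snps(self):
        rng = np.random.default_rng(2)
        d = rng.integers(0, 3, size=(200, 20)).astype(float)
        panel = _panel(d)
        kept = gen.ld_prune(panel, r2_max=0.95)
        assert len(kept) == 20

    def test_prune_matches_exhaustive_greedy_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            d = rng.integers(0, 3, size=(60, 15)).astype(float)
            # plant some LD by copying columns with noise flips
            for j in range(1, 15, 3):
                d[:, j] = d[:, j - 1]
                flip = rng.random(60) < 0.1
                d[flip, j] = rng.integers(0, 3, flip.sum())
            panel = _panel(d)
            kept = gen.ld_prune(panel, r2_max=0.7, window=15, step=15)
            # oracle: single full-window pass of the same greedy rule
            keep = np.ones(15, dtype=bool)
            for a in range(15):
                if not keep[a]:
                    continue
                for b in range(a + 1, 15):
                    if keep[b]:
                        r2 = gen.ld_r2(d[:, a], d[:, b])
                        if not np.isnan(r2) and r2 >= 0.7:
                            keep[b] = False
            assert list(kept) == list(np.where(keep)[0])

    def test_prune_deterministic_and_label_free(self):
        rng = np.random.default_rng(4)
        d = rng.integers(0, 3, size=(80, 40)).astype(float)
        a = gen.ld_prune(_panel(d))
        panel2 = _panel(d)
        panel2.snps["id"] = [f"renamed{i}" for i in range(40)]
        b = gen.ld_prune(panel2)
        assert list(a) == list(b)


class TestImputation:
    def test_duplicate_column_fills_from_twin(self):
        x = np.array([0.0, 1, 2, 0, 2, 1, 0, 2])
        d = np.column_stack([x, x]).astype(float)
        d[3, 1] = np.nan
        out = gen.impute_nn_ld(_panel(d))
        assert out.dosage[3, 1] == x[3]

    def test_no_ld_falls_back_to_mode(self):
        rng = np.random.default_rng(5)
        d = rng.integers(0, 3, size=(30, 5)).astype(float)
        d[:, 2] = 2.0
        d[4, 2] = np.nan
        d[0, 2] = 0.0  # keep the column non-constant
        out = gen.impute_nn_ld(_panel(d), min_r2=0.99)
        assert out.dosage[4, 2] == 2.0

    def test_recovery_on_ld_panel(self):
        cfg = simulate.GenoPhenoSimConfig(
            n_individuals=150, n_snps=100, ld_rho=0.95, seed=6
        )
        geno = simulate.gen_genotypes(cfg)
        truth = geno.dosage.copy()
        rng = np.random.default_rng(7)
        mask = rng.random(truth.shape) < 0.05
        geno.dosage[mask] = np.nan
        out = gen.impute_nn_ld(geno)
        recovered = (out.dosage[mask] == truth[mask]).mean()
        assert recovered >= 0.9

    def test_all_missing_column_rejected(self):
        d = np.ones((5, 2))
        d[:, 1] = np.nan
        with pytest.raises(ValueError):
            gen.impute_nn_ld(_panel(d))


class TestDiversity:
    def test_two_differing_lines(self):
        panel = _panel([[0.0], [2.0]])
        assert gen.nucleotide_diversity(panel).iloc[0] == 1.0

    def test_four_lines_at_half_frequency(self):
        panel = _panel([[0.0], [0.0], [2.0], [2.0]])
        assert np.isclose(gen.nucleotide_diversity(panel).iloc[0], 4 / 6)

    def test_monomorphic_site_zero(self):
        panel = _panel([[2.0], [2.0], [2.0]])
        assert gen.nucleotide_diversity(panel).iloc[0] == 0.0


class TestWindows:
    def test_plus_strand_arithmetic_and_boundary(self):
        models = pd.DataFrame(
            {"id": ["g"], "chrom": ["1"], "start": [5000], "end": [7000],
             "strand": ["+"]}
        )
        w = gen.gene_windows(models, up=2000, down=2000)
        assert (w.window_start[0], w.window_end[0]) == (3000, 9000)
        panel = _panel(np.zeros((3, 2)), positions=[2999, 3000])
        idx = gen.assign_snps_to_partition(panel, w)
        assert list(idx) == [1]

    def test_minus_strand_swaps_up_and_down(self):
        models = pd.DataFrame(
            {"id": ["g"], "chrom": ["1"], "start": [5000], "end": [7000],
             "strand": ["-"]}
        )
        w = gen.gene_windows(models, up=2000, down=500)
        assert (w.window_start[0], w.window_end[0]) == (4500, 9000)

    def test_clamped_at_chromosome_start(self):
        models = pd.DataFrame(
            {"id": ["g"], "chrom": ["1"], "start": [500], "end": [900],
             "strand": ["+"]}
        )
        w = gen.gene_windows(models, up=2000, down=2000)
        assert w.window_start[0] == 1

    def test_overlapping_windows_count_snp_once(self):
        models = pd.DataFrame(
            {"id": ["g1", "g2"], "chrom": "1", "start": [100, 150],
             "end": [300, 350], "strand": "+"}
        )
        w = gen.gene_windows(models, up=50, down=50)
        panel = _panel(np.zeros((2, 3)), positions=[200, 250, 10_000])
        idx = gen.assign_snps_to_partition(panel, w)
        assert list(idx) == [0, 1]

    def test_chromosome_mismatch_rejected(self):
        models = pd.DataFrame(
            {"id": ["g"], "chrom": ["chr9"], "start": [100], "end": [200],
             "strand": ["+"]}
        )
        w = gen.gene_windows(models)
        panel = _panel(np.zeros((2, 2)))
        with pytest.raises(ValueError, match="chr9"):
            gen.assign_snps_to_partition(panel, w)

    def test_assignment_matches_bruteforce_scan(self, gene_models):
        rng = np.random.default_rng(8)
        panel = _panel(
            rng.integers(0, 3, size=(10, 200)).astype(float),
            positions=np.sort(rng.choice(60_000, 200, replace=False)) + 1,
        )
        w = gen.gene_windows(gene_models, up=500, down=500)
        idx = set(gen.assign_snps_to_partition(panel, w))
        brute = set()
        for j, pos in enumerate(panel.snps["pos"]):
            for rec in w.itertuples(index=False):
                if rec.window_start <= pos <= rec.window_end:
                    brute.add(j)
        assert idx == brute


class TestKinship:
    def test_two_by_two_hand_computation(self):
        # dosages [[2,0],[0,2]]: p = 0.5 per SNP, scale sqrt(2*0.5*0.5),
        # so X = sqrt(2) * [[1,-1],[-1,1]] and K = XX'/2 = [[2,-2],[-2,2]]
        d = np.array([[2.0, 0.0], [0.0, 2.0]])
        km = gen.kinship(_panel(d))
        expected = np.array([[2.0, -2.0], [-2.0, 2.0]])
        assert np.allclose(km.K, expected)

    def test_duplicated_individual_offdiagonal(self):
        rng = np.random.default_rng(9)
        row = rng.integers(0, 3, 50).astype(float)
        other = rng.integers(0, 3, 50).astype(float)
        km = gen.kinship(_panel(np.vstack([row, row, other])))
        assert np.isclose(km.K[0, 1], km.K[0, 0])

    def test_matches_direct_formula_and_psd(self):
        rng = np.random.default_rng(10)
        d = rng.integers(0, 3, size=(30, 100)).astype(float)
        km = gen.kinship(_panel(d))
        p = d.mean(axis=0) / 2
        ok = (p > 0) & (p < 1)
        X = (d[:, ok] - 2 * p[ok]) / np.sqrt(2 * p[ok] * (1 - p[ok]))
        assert np.allclose(km.K, X @ X.T / ok.sum())
        assert np.linalg.eigvalsh(km.K).min() >= -1e-8

    def test_monomorphic_snps_dropped_with_warning(self):
        d = np.column_stack([np.zeros(10), np.random.default_rng(0).integers(0, 3, 10)])
        with pytest.warns(UserWarning, match="monomorphic"):
            km = gen.kinship(_panel(d.astype(float)))
        assert km.n_snps == 1

    def test_missing_panel_rejected(self):
        d = np.ones((5, 3))
        d[0, 0] = np.nan
        with pytest.raises(ValueError, match="impute"):
            gen.kinship(_panel(d))


class TestReml:
    def test_scaling_invariance(self, geno_pheno):
        _, geno, pheno = geno_pheno
        km = gen.kinship(geno)
        y = pheno.line_values["trait_1"].to_numpy()
        a = gen.reml_h2(y, km)
        b = gen.reml_h2(10.0 * y, km)
        assert abs(a.h2 - b.h2) < 1e-6

    def test_recovers_planted_h2(self, geno_pheno):
        _, geno, pheno = geno_pheno
        km = gen.kinship(geno)
        est = gen.reml_h2(pheno.line_values["trait_1"].to_numpy(), km)
        assert abs(est.h2 - 0.5) < 0.15  # single replicate; ensemble in acceptance

    def test_eigenvector_phenotype_hits_upper_boundary(self, geno_pheno):
        _, geno, _ = geno_pheno
        km = gen.kinship(geno)
        s, U = np.linalg.eigh(km.K)
        y = U[:, -1] * np.sqrt(max(s[-1], 1.0))
        est = gen.reml_h2(y, km)
        assert est.h2 > 0.95

    def test_constant_phenotype_rejected(self, geno_pheno):
        _, geno, _ = geno_pheno
        km = gen.kinship(geno)
        with pytest.raises(ValueError):
            gen.reml_h2(np.ones(geno.n_individuals), km)

    def test_non_psd_kinship_rejected(self):
        K = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        with pytest.raises(ValueError, match="PSD"):
            gen.reml_h2(np.array([0.1, 0.9]), K)


@pytest.fixture(scope="module")
def small_panel():
    cfg = simulate.GenoPhenoSimConfig(
        n_individuals=120, n_snps=400, ld_rho=0.2,
        causal_windows=[(1, 8000)], seed=5,
    )
    geno = simulate.gen_genotypes(cfg)
    pheno = simulate.gen_phenotypes(geno, cfg)
    models = pd.DataFrame(
        {"id": [f"g{i}" for i in range(80)], "chrom": "1",
         "start": np.arange(80) * 500 + 1, "end": np.arange(80) * 500 + 300,
         "strand": "+"}
    )
    return geno, pheno, models


class TestPartitionNull:
    def test_causal_partition_beats_null(self, small_panel):
        geno, pheno, models = small_panel
        causal_genes = [f"g{i}" for i in range(16)]  # cover the causal window
        pn = gen.empirical_null_h2(
            pheno.line_values["trait_1"].to_numpy(), geno, models,
            causal_genes, n_perm=30, seed=0,
        )
        assert pn.percentile >= 95.0
        assert pn.observed_h2 > pn.null_mean

    def test_same_seed_identical_null(self, small_panel):
        geno, pheno, models = small_panel
        genes = [f"g{i}" for i in range(10)]
        y = pheno.line_values["trait_1"].to_numpy()
        a = gen.empirical_null_h2(y, geno, models, genes, n_perm=10, seed=3)
        b = gen.empirical_null_h2(y, geno, models, genes, n_perm=10, seed=3)
        assert np.array_equal(a.null_h2, b.null_h2)

    def test_universe_too_small_rejected(self, small_panel):
        geno, pheno, models = small_panel
        with pytest.raises(ValueError):
            gen.empirical_null_h2(
                pheno.line_values["trait_1"].to_numpy(), geno,
                models.head(5), [f"g{i}" for i in range(5)], n_perm=2, seed=0,
            )


class TestSelectModules:
    def test_truth_table(self):
        stats_df = pd.DataFrame(
            {
                "module": ["pass", "fail_p", "fail_null", "fail_share"],
                "trait_p": [0.01, 0.5, 0.01, 0.01],
                "observed_h2": [0.45, 0.45, 0.20, 0.30],
                "null_mean": [0.25, 0.25, 0.25, 0.25],
            }
        )
        out = gen.select_modules(stats_df, genomewide_h2=0.5, share_threshold=0.8)
        assert out == ["pass"]

    def test_no_passing_module_returns_empty(self):
        stats_df = pd.DataFrame(
            {"module": ["m"], "trait_p": [0.9], "observed_h2": [0.1],
             "null_mean": [0.3]}
        )
        assert gen.select_modules(stats_df, genomewide_h2=0.5) == []

    def test_missing_statistic_skipped_with_warning(self):
        stats_df = pd.DataFrame(
            {"module": ["m"], "trait_p": [np.nan], "observed_h2": [0.5],
             "null_mean": [0.2]}
        )
        with pytest.warns(UserWarning):
            assert gen.select_modules(stats_df, genomewide_h2=0.5) == []
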