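"""BLUPs, phenotypic PCs, GBLUP, association scans and epistasis."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pleionet import association as assoc
from pleionet import genetics as gen
from pleionet import simulate


def _records(line_values, years=2, blocks=2, plants=3, noise=0.1, seed=0,
             year_sd=0.0, block_sd=0.0):
    rng = np.random.default_rng(seed)
    rows = []
    for j in range(years):
        ye = rng.normal(0, year_sd) if year_sd else 0.0
        for k in range(blocks):
            be = rng.normal(0, block_sd) if block_sd else 0.0
            for s in range(plants):
                for g, v in line_values.items():
                    rows.append([g, 2018 + j, f"b{k}", s + 1,
                                 v + ye + be + rng.normal(0, noise)])
    return pd.DataFrame(rows, columns=["genotype", "year", "block", "plant", "y"])


class TestBlups:
    def test_vanishing_noise_blups_equal_genotype_deviations(self):
        vals = {f"g{i}": float(i) for i in range(6)}
        rec = _records(vals, noise=1e-4, seed=1)
        out = assoc.fit_blups(rec, "y")
        dev = pd.Series(vals) - np.mean(list(vals.values()))
        assert np.allclose(out.blups.sort_index(), dev.sort_index(), atol=0.01)

    def test_no_genotype_signal_shrinks_to_zero(self):
        vals = {f"g{i}": 0.0 for i in range(8)}
        rec = _records(vals, noise=1.0, seed=2, block_sd=0.5)
        out = assoc.fit_blups(rec, "y")
        assert out.blups.abs().max() < 0.5
        assert out.sigma_g2 < 0.2

    def test_recovers_simulated_genotype_effects(self):
        rng = np.random.default_rng(3)
        vals = {f"g{i:02d}": float(v) for i, v in enumerate(rng.normal(0, 1, 40))}
        rec = _records(vals, years=2, blocks=2, plants=3, noise=0.8, seed=4,
                       year_sd=0.4, block_sd=0.3)
        out = assoc.fit_blups(rec, "y")
        truth = pd.Series(vals)
        r = np.corrcoef(out.blups.sort_index(), truth.sort_index())[0, 1]
        assert r >= 0.9
        assert out.converged

    def test_single_genotype_rejected(self):
        rec = _records({"g0": 1.0})
        with pytest.raises(ValueError):
            assoc.fit_blups(rec, "y")


class TestPhpc:
    def test_uncorrelated_traits_split_evenly(self):
        rng = np.random.default_rng(5)
        z1, z2 = rng.normal(size=3000), rng.normal(size=3000)
        out = assoc.phpc(pd.DataFrame({"a": z1, "b": z2}))
        assert abs(out.percent_variance[0] - 50.0) < 3.0

    def test_closed_form_share_from_sample_correlation(self):
        # for two standardized traits the PhPC1 share is exactly (1+|r|)/2
        rng = np.random.default_rng(6)
        z1 = rng.normal(size=500)
        z2 = 0.3 * z1 + rng.normal(size=500)
        tb = pd.DataFrame({"a": z1, "b": z2})
        out = assoc.phpc(tb)
        r = np.corrcoef(z1, z2)[0, 1]
        assert np.isclose(out.percent_variance[0], (1 + abs(r)) / 2 * 100)

    def test_loadings_orthonormal_and_percents_sum_to_100(self):
        rng = np.random.default_rng(7)
        tb = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        out = assoc.phpc(tb)
        L = out.loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(3), atol=1e-8)
        assert np.isclose(out.percent_variance.sum(), 100.0)

    def test_constant_trait_rejected(self):
        tb = pd.DataFrame({"a": [1.0, 2, 3], "b": [5.0, 5, 5]})
        with pytest.raises(ValueError):
            assoc.phpc(tb)


class TestGblup:
    def test_zero_genetic_variance_gives_zero_gebvs(self):
        cfg = simulate.GenoPhenoSimConfig(
            n_individuals=100, n_snps=300, causal_windows=[(1, 5000)],
            h2_targets=(0.0, 0.0), seed=8,
        )
        geno = simulate.gen_genotypes(cfg)
        pheno = simulate.gen_phenotypes(geno, cfg)
        km = gen.kinship(geno)
        with pytest.warns(UserWarning):
            out = assoc.gblup(pheno.line_values["trait_1"], km)
        assert (out.gebv == 0).all()

    def test_heritable_trait_predicts_held_out_lines(self, geno_pheno):
        _, geno, pheno = geno_pheno
        km = gen.kinship(geno)
        ids = list(pheno.line_values.index)
        train, test = ids[:240], ids[240:]
        out = assoc.gblup(pheno.line_values.loc[train, "trait_1"], km,
                          test, pheno.line_values["trait_1"])
        # bounded above by sqrt(h2) ~ 0.71; must clear zero decisively
        assert out.accuracy is not None and 0.1 < out.accuracy < 0.85

    def test_train_equals_test_without_noise_ranks_perfectly(self, geno_pheno):
        _, geno, pheno = geno_pheno
        km = gen.kinship(geno)
        g = pheno.genetic_values["trait_1"]
        out = assoc.gblup(g, km, list(g.index), g)
        rho = stats.spearmanr(out.gebv.loc[g.index], g).statistic
        assert rho > 0.99


class TestBicSelection:
    def test_structured_phenotype_needs_pcs(self):
        rng = np.random.default_rng(9)
        pcs = rng.normal(size=(200, 5))
        y = 2.0 * pcs[:, 0] + rng.normal(size=200)
        assert assoc.bic_select_pcs(y, pcs, k_max=5) >= 1

    def test_unstructured_phenotype_selects_zero_most_of_the_time(self):
        rng = np.random.default_rng(10)
        hits = 0
        for _ in range(50):
            pcs = rng.normal(size=(100, 5))
            y = rng.normal(size=100)
            if assoc.bic_select_pcs(y, pcs, k_max=5) == 0:
                hits += 1
        assert hits >= 40

    def test_bic_values_match_direct_computation(self):
        rng = np.random.default_rng(11)
        pcs = rng.normal(size=(80, 3))
        y = pcs[:, 0] + rng.normal(size=80)
        n = 80
        bics = []
        for k in range(4):
            X = np.column_stack([np.ones(n), pcs[:, :k]])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss = float(((y - X @ beta) ** 2).sum())
            bics.append(n * np.log(rss / n) + (k + 1) * np.log(n))
        assert assoc.bic_select_pcs(y, pcs, k_max=3) == int(np.argmin(bics))


class TestGlm:
    def test_two_group_f_statistic_closed_form(self):
        out = assoc.glm_association(
            np.array([1.0, 2, 3, 4]), np.array([0.0, 0, 1, 1])
        )
        assert np.isclose(out["stat"][0], 8.0)
        assert np.isclose(out["p"][0], stats.f.sf(8.0, 1, 2))
        assert np.isclose(out["effect"][0], 2.0)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(12)
        pvals = []
        for _ in range(300):
            y = rng.normal(size=100)
            snp = rng.integers(0, 3, 100).astype(float)
            pvals.append(assoc.glm_association(y, snp)["p"][0])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_constant_snp_flagged(self):
        out = assoc.glm_association(np.arange(6.0), np.ones(6))
        assert np.isnan(out["p"][0])


@pytest.fixture(scope="module")
def structured_panel():
    cfg = simulate.GenoPhenoSimConfig(
        n_individuals=200, n_snps=600, n_subpops=3, fst=0.2,
        causal_windows=[(1, 5000)], seed=13,
    )
    geno = simulate.gen_genotypes(cfg)
    km = gen.kinship(geno)
    s, U = np.linalg.eigh(km.K)
    s = np.clip(s, 0, None)
    return geno, km, (s, U)


class TestMlm:
    def test_reduces_to_glm_without_genetic_variance(self):
        rng = np.random.default_rng(14)
        y = rng.normal(size=120)
        snp = rng.integers(0, 3, 120).astype(float)
        p_mlm = assoc.mlm_association(y, snp, None, 1e-9 * np.eye(120))["p"][0]
        p_glm = assoc.glm_association(y, snp)["p"][0]
        assert abs(p_mlm - p_glm) < 1e-6

    def test_null_calibration_under_structure(self, structured_panel):
        _, km, eig = structured_panel
        s, U = eig
        L = U @ np.diag(np.sqrt(s))
        rng = np.random.default_rng(15)
        pvals = []
        for _ in range(300):
            y = L @ rng.normal(size=200) * 0.7 + rng.normal(size=200) * 0.7
            snp = rng.integers(0, 3, 200).astype(float)
            pvals.append(assoc.mlm_association(y, snp, None, km, eig=eig)["p"][0])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_power_for_planted_effect(self, structured_panel):
        geno, km, eig = structured_panel
        s, U = eig
        L = U @ np.diag(np.sqrt(s))
        rng = np.random.default_rng(16)
        hits = 0
        n_reps = 40
        for _ in range(n_reps):
            snp = geno.dosage[:, rng.integers(geno.n_snps)].copy()
            if np.std(snp) == 0:
                continue
            y = 0.5 * (snp - snp.mean()) / snp.std()
            y += L @ rng.normal(size=200) * 0.5 + rng.normal(size=200) * 0.7
            p = assoc.mlm_association(y, snp, None, km, eig=eig)["p"][0]
            hits += p < 0.05
        assert hits / n_reps > 0.8


class TestMultitrait:
    def test_reduces_to_single_trait_lrt_at_t_one(self):
        rng = np.random.default_rng(17)
        y = rng.normal(size=100)
        snp = rng.integers(0, 3, 100).astype(float)
        p_multi = assoc.multitrait_lrt(y[:, None], snp)["p"][0]
        # direct single-trait LRT
        X0 = np.ones((100, 1))
        X1 = np.column_stack([X0, snp])
        b0, *_ = np.linalg.lstsq(X0, y, rcond=None)
        b1, *_ = np.linalg.lstsq(X1, y, rcond=None)
        rss0 = ((y - X0 @ b0) ** 2).sum()
        rss1 = ((y - X1 @ b1) ** 2).sum()
        lrt = 100 * np.log(rss0 / rss1)
        assert np.isclose(p_multi, stats.chi2.sf(lrt, 1))

    def test_null_calibration(self, structured_panel):
        _, km, eig = structured_panel
        s, U = eig
        L = U @ np.diag(np.sqrt(s))
        rng = np.random.default_rng(18)
        pvals = []
        for _ in range(300):
            Y = np.column_stack(
                [L @ rng.normal(size=200) * 0.7 + rng.normal(size=200) * 0.7
                 for _ in range(2)]
            )
            snp = rng.integers(0, 3, 200).astype(float)
            pvals.append(assoc.multitrait_lrt(Y, snp, None, km, eig=eig)["p"][0])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_joint_effect_detected_more_often_than_single_trait(self):
        rng = np.random.default_rng(19)
        multi_hits = single_hits = 0
        n, effect = 150, 0.25
        for _ in range(100):
            snp = rng.integers(0, 3, n).astype(float)
            sz = (snp - snp.mean()) / snp.std()
            Y = np.column_stack(
                [effect * sz + rng.normal(size=n),
                 effect * sz + rng.normal(size=n)]
            )
            p_multi = assoc.multitrait_lrt(Y, snp)["p"][0]
            p_single = assoc.glm_association(Y[:, 0], snp)["p"][0]
            multi_hits += p_multi < 0.05
            single_hits += p_single < 0.05
        assert multi_hits > single_hits


class TestLocoKinship:
    def test_held_out_chromosome_excluded(self):
        cfg = simulate.GenoPhenoSimConfig(n_individuals=60, n_snps=100, seed=20)
        geno = simulate.gen_genotypes(cfg)
        geno.snps.loc[:49, "chrom"] = "1"
        geno.snps.loc[50:, "chrom"] = "2"
        km = assoc.leave_one_chrom_kinship(geno, "1")
        assert km.n_snps <= 50

    def test_single_chromosome_rejected(self):
        cfg = simulate.GenoPhenoSimConfig(n_individuals=30, n_snps=40, seed=21)
        geno = simulate.gen_genotypes(cfg)
        with pytest.raises(ValueError):
            assoc.leave_one_chrom_kinship(geno, "1")

    def test_balanced_chromosomes_preserve_kinship(self):
        # relatedness signal (subpopulations) must dominate the sampling
        # noise of halving the marker set for LOCO ~ full to hold
        cfg = simulate.GenoPhenoSimConfig(
            n_individuals=100, n_snps=800, n_subpops=4, fst=0.3, seed=22
        )
        geno = simulate.gen_genotypes(cfg)
        geno.snps.loc[:399, "chrom"] = "1"
        geno.snps.loc[400:, "chrom"] = "2"
        k_full = gen.kinship(geno).K
        k_loco = assoc.leave_one_chrom_kinship(geno, "2").K
        iu = np.triu_indices(100, k=1)
        assert np.corrcoef(k_full[iu], k_loco[iu])[0, 1] > 0.9


class TestMultiplicity:
    def test_bh_step_up_example(self):
        q = assoc.bh_fdr(np.array([0.01, 0.02, 0.03, 0.5]))
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.5])

    def test_bh_monotone_and_order_invariant(self):
        rng = np.random.default_rng(23)
        p = rng.uniform(size=50)
        q = assoc.bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        perm = rng.permutation(50)
        assert np.allclose(assoc.bh_fdr(p[perm]), q[perm])

    def test_bonferroni_threshold(self):
        thr, flags = assoc.bonferroni(np.full(100, 0.01), alpha=0.05)
        assert np.isclose(thr, 5e-4)
        assert not flags.any()

    def test_empty_inputs(self):
        assert assoc.bh_fdr(np.array([])).size == 0
        thr, flags = assoc.bonferroni(np.array([]))
        assert flags.size == 0


class TestEpistasis:
    def test_peak_snp_and_collinear_skipped(self):
        rng = np.random.default_rng(24)
        n = 100
        s1 = rng.integers(0, 2, n).astype(float)
        y = rng.normal(size=n)
        snps = np.column_stack([s1, s1 * 2.0])
        out = assoc.epistasis_scan(y, s1, snps, None, np.eye(n) * 1e-9)
        assert out["status"][0] == "peak"
        assert out["status"][1] == "collinear"

    def test_interaction_effect_recovered(self):
        rng = np.random.default_rng(25)
        n = 400
        estimates = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            s1 = r.integers(0, 3, n).astype(float)
            s2 = r.integers(0, 3, n).astype(float)
            inter = s1 * s2
            y = 0.3 * s1 + 0.2 * s2 + 0.5 * inter + r.normal(size=n)
            out = assoc.epistasis_scan(y, s1, s2, None, np.eye(n) * 1e-9)
            estimates.append(out["beta"][0])
        assert abs(np.mean(estimates) - 0.5) < 0.1

    def test_null_interaction_pvalues_uniform(self):
        rng = np.random.default_rng(26)
        n = 150
        pvals = []
        for _ in range(200):
            s1 = rng.integers(0, 3, n).astype(float)
            s2 = rng.integers(0, 3, n).astype(float)
            y = 0.3 * s1 + 0.2 * s2 + rng.normal(size=n)
            out = assoc.epistasis_scan(y, s1, s2, None, np.eye(n) * 1e-9)
            pvals.append(out["p_beta"][0])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_gls_reduces_to_ols_without_kinship(self):
        rng = np.random.default_rng(27)
        n = 80
        s1 = rng.integers(0, 3, n).astype(float)
        s2 = rng.integers(0, 3, n).astype(float)
        y = rng.normal(size=n)
        out = assoc.epistasis_scan(y, s1, s2, None, np.eye(n) * 1e-9)
        X = np.column_stack([np.ones(n), s1, s2, s1 * s2])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.allclose(
            [out["alpha1"][0], out["alpha2"][0], out["beta"][0]],
            beta[1:], atol=1e-6,
        )
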