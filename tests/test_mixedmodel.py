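"""Mixed-model association: REML components, scans, local eQTL logic."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bonenet import mixedmodel, synth
from bonenet.datatypes import ExpressionMatrix, GenomeSpec, GenotypeData


def _iid_genotypes(n_snps, n_strains, seed, chrom="chr1", spacing=100_000):
    rng = np.random.default_rng(seed)
    G = rng.integers(0, 2, size=(n_snps, n_strains))
    # keep polymorphic
    G[G.sum(axis=1) == 0, 0] = 1
    G[G.sum(axis=1) == n_strains, 0] = 0
    snps = [f"{chrom}_s{i}" for i in range(n_snps)]
    geno = pd.DataFrame(G.astype(np.int8), index=snps,
                        columns=[f"s{j}" for j in range(n_strains)])
    smap = pd.DataFrame({"chr": chrom,
                         "bp": np.arange(1, n_snps + 1) * spacing}, index=snps)
    return GenotypeData(genotypes=geno, snp_map=smap)


class TestKinship:
    def test_identical_and_complementary_strains(self):
        g = pd.DataFrame({"a": [0, 1, 0, 1], "b": [0, 1, 0, 1],
                          "c": [1, 0, 1, 0]},
                         index=[f"s{i}" for i in range(4)])
        geno = GenotypeData(genotypes=g,
                            snp_map=pd.DataFrame({"chr": "chr1",
                                                  "bp": [1, 2, 3, 4]},
                                                 index=g.index))
        K = mixedmodel.kinship_matrix(geno)
        assert K.loc["a", "b"] == 1.0
        assert K.loc["a", "c"] == 0.0


class TestReml:
    def test_heritability_recovery(self, small_genotypes):
        K = mixedmodel.kinship_matrix(small_genotypes).to_numpy()
        w, U = np.linalg.eigh(K)
        w = np.maximum(w, 0)
        ests = []
        for s in range(100):
            rng = np.random.default_rng(900 + s)
            u = U @ (np.sqrt(w) * rng.standard_normal(96))  # u ~ N(0, K)
            y = u + rng.standard_normal(96)  # sigma_g2 = sigma_e2 = 1
            vc = mixedmodel.reml_variance_components(y, np.ones((96, 1)), K)
            ests.append(vc.pseudo_heritability)
        assert np.mean(ests) == pytest.approx(0.5, abs=0.1)

    def test_null_heritability_near_zero(self, small_genotypes):
        K = mixedmodel.kinship_matrix(small_genotypes).to_numpy()
        ests = []
        for s in range(60):
            y = np.random.default_rng(200 + s).standard_normal(96)
            vc = mixedmodel.reml_variance_components(y, np.ones((96, 1)), K)
            ests.append(vc.pseudo_heritability)
        assert np.mean(ests) < 0.15

    def test_optimum_dominates_grid(self, small_genotypes):
        K = mixedmodel.kinship_matrix(small_genotypes).to_numpy()
        y = np.random.default_rng(1).standard_normal(96)
        vc = mixedmodel.reml_variance_components(y, np.ones((96, 1)), K)
        spec = mixedmodel._spectral_null(K, np.ones((96, 1)))
        eta2 = (spec.U.T @ y) ** 2
        grid_ll = [mixedmodel._reml_loglik(g, spec.xis, eta2)
                   for g in np.linspace(-10, 10, 100)]
        assert vc.reml_loglik >= max(grid_ll) - 1e-9

    def test_rejects_nan_response(self, small_genotypes):
        K = mixedmodel.kinship_matrix(small_genotypes).to_numpy()
        y = np.full(96, np.nan)
        with pytest.raises(ValueError):
            mixedmodel.reml_variance_components(y, np.ones((96, 1)), K)


class TestAssociationScan:
    def test_identity_kinship_equals_ols(self):
        geno = _iid_genotypes(80, 50, seed=0)
        y = np.random.default_rng(5).standard_normal(50)
        scan = mixedmodel.association_scan(y, geno, K=None)
        G = geno.genotypes.to_numpy(dtype=float)
        for j in range(80):
            assert scan["p"].iloc[j] == pytest.approx(
                stats.linregress(G[j], y).pvalue, abs=1e-8)

    def test_strain_permutation_invariance(self):
        geno = _iid_genotypes(40, 50, seed=1)
        rng = np.random.default_rng(2)
        y = rng.standard_normal(50)
        K = mixedmodel.kinship_matrix(geno)
        scan = mixedmodel.association_scan(y, geno, K)
        perm = rng.permutation(50)
        geno_p = GenotypeData(genotypes=geno.genotypes.iloc[:, perm],
                              snp_map=geno.snp_map)
        Kp = K.iloc[perm, perm]
        scan_p = mixedmodel.association_scan(y[perm], geno_p, Kp)
        assert np.allclose(scan["p"], scan_p["p"], atol=1e-8)

    def test_zero_variance_snp_flagged(self):
        geno = _iid_genotypes(5, 30, seed=3)
        geno.genotypes.iloc[2] = 1
        y = np.random.default_rng(0).standard_normal(30)
        scan = mixedmodel.association_scan(y, geno, K=None)
        assert scan["p"].iloc[2] == 1.0
        assert bool(scan["zero_variance"].iloc[2])

    def test_rotation_identity_large_delta_matches_ols(self, small_genotypes):
        # as delta -> inf the GLS fit converges to OLS
        K = mixedmodel.kinship_matrix(small_genotypes).to_numpy()
        y = np.random.default_rng(4).standard_normal(96)
        vc = mixedmodel.VarianceComponents(sigma_g2=1.0, sigma_e2=1e8,
                                           delta=1e8, reml_loglik=0.0,
                                           pseudo_heritability=0.0,
                                           boundary=True)
        scan = mixedmodel.association_scan(y, small_genotypes, K, vc=vc)
        ols = mixedmodel.association_scan(y, small_genotypes, K=None)
        assert np.allclose(scan["p"], ols["p"], atol=1e-5)

    def test_planted_qtl_power(self, small_genome):
        hits = 0
        n_seeds = 20
        for s in range(n_seeds):
            geno = synth.simulate_genotypes(96, 8, small_genome, seed=700 + s)
            rng = np.random.default_rng(800 + s)
            G = geno.genotypes.to_numpy(dtype=float)
            j = int(rng.integers(geno.n_snps))
            g = G[j]
            if g.var() == 0:
                continue
            beta = np.sqrt(0.4 / (0.6 * g.var()))  # 40% of phenotype variance
            y = beta * g + rng.standard_normal(96)
            K = mixedmodel.kinship_matrix(geno)
            scan = mixedmodel.association_scan(y, geno, K)
            best = int(np.argmin(scan["p"].to_numpy()))
            r = abs(np.corrcoef(G[j], G[best])[0, 1])
            hits += (best == j) or (r > 0.8)
        assert hits / n_seeds >= 0.95

    def test_type_one_error_calibrated(self, small_genome):
        # pooled rejection rate over simulated null panels
        rates = []
        for panel in range(5):
            geno = synth.simulate_genotypes(96, 8, small_genome,
                                            seed=1500 + panel)
            K = mixedmodel.kinship_matrix(geno)
            for rep in range(10):
                y = np.random.default_rng(1600 + 10 * panel + rep).standard_normal(96)
                scan = mixedmodel.association_scan(y, geno, K)
                rates.append((scan["p"] < 0.05).mean())
        assert np.mean(rates) == pytest.approx(0.05, abs=0.025)


class TestEqtlScan:
    def test_cis_driver_best_snp(self, small_genome):
        hits = 0
        n_seeds = 20
        for s in range(n_seeds):
            geno = synth.simulate_genotypes(96, 8, small_genome, seed=2000 + s)
            truth = synth.make_planted_truth(geno, small_genome, seed=2100 + s,
                                             n_genes=60, n_modules=1,
                                             module_size_range=(25, 30))
            expr = synth.simulate_expression(geno, truth, seed=2200 + s)
            K = mixedmodel.kinship_matrix(geno)
            scan = mixedmodel.eqtl_scan(expr, geno, K,
                                        probes=[truth.driver_gene])
            hits += scan.loc[scan["p"].idxmin(), "snp"] == truth.driver_cis_snp
        assert hits / n_seeds >= 0.95

    def test_trans_signal_concentrates_on_module(self, small_genotypes,
                                                 small_truth, small_expression):
        from bonenet import hotspots

        K = mixedmodel.kinship_matrix(small_genotypes)
        genome = GenomeSpec(chromosomes=[("chr1", 60_000_000),
                                         ("chr2", 60_000_000)], snp_count=150)
        bins = hotspots.bin_genome(genome)
        minima = mixedmodel.eqtl_bin_minima(small_expression, small_genotypes,
                                            K, bins)
        cis = small_genotypes.snp_map.loc[small_truth.driver_cis_snp]
        bin_idx = [b for b, r in bins.iterrows()
                   if str(r.chr) == str(cis.chr) and r.start <= cis.bp < r.end][0]
        labels = small_truth.module_labels(small_expression.probes)
        module = (labels == small_truth.target_module).to_numpy()
        neglogp = -np.log10(minima[bin_idx].to_numpy(dtype=float))
        mod_rate = (neglogp[module] >= 4).mean()
        bg_rate = max((neglogp[labels.to_numpy() == 0] >= 4).mean(),
                      1.0 / (labels == 0).sum())
        assert mod_rate / bg_rate >= 5

    def test_null_probe_min_p_distribution(self):
        # with independent SNPs, the per-probe minimum p behaves like the
        # minimum of m uniforms: F(p) = 1 - (1 - p)^m
        m, n_seeds = 150, 300
        u = []
        for s in range(n_seeds):
            geno = _iid_genotypes(m, 60, seed=3000 + s)
            y = np.random.default_rng(4000 + s).standard_normal(60)
            scan = mixedmodel.association_scan(y, geno, K=None)
            pmin = scan["p"].min()
            u.append(1 - (1 - pmin) ** m)
        assert stats.kstest(u, "uniform").pvalue > 0.01

    def test_streaming_matches_full_scan(self, small_genotypes, small_truth):
        from bonenet import hotspots

        expr = synth.simulate_expression(small_genotypes, small_truth, seed=77)
        sub = ExpressionMatrix(values=expr.values.iloc[:10],
                               annotation=expr.annotation.iloc[:10])
        K = mixedmodel.kinship_matrix(small_genotypes)
        genome = GenomeSpec(chromosomes=[("chr1", 60_000_000),
                                         ("chr2", 60_000_000)], snp_count=150)
        bins = hotspots.bin_genome(genome)
        minima = mixedmodel.eqtl_bin_minima(sub, small_genotypes, K, bins)
        full = mixedmodel.eqtl_scan(sub, small_genotypes, K)
        snp_bin = mixedmodel.assign_snps_to_bins(small_genotypes.snp_map, bins)
        for probe in sub.values.index:
            probe_scan = full[full["response"] == probe]
            for b in range(len(bins)):
                sel = probe_scan[snp_bin == b]
                if len(sel):
                    assert minima.loc[probe].iloc[b] == pytest.approx(
                        sel["p"].min(), rel=1e-12)
                else:
                    assert np.isnan(minima.loc[probe].iloc[b])


class TestLocalEqtl:
    def test_region_threshold_and_probe_selection(self, small_genotypes,
                                                  small_truth):
        expr = synth.simulate_expression(small_genotypes, small_truth, seed=55)
        # duplicate the driver probe so its gene has two probes, one noisier
        ann = expr.annotation.copy()
        vals = expr.values.copy()
        dg = small_truth.driver_gene
        noisy = vals.loc[dg] + np.random.default_rng(0).standard_normal(96) * 5
        vals.loc["dup_probe"] = noisy
        ann.loc["dup_probe"] = ann.loc[dg]
        expr2 = ExpressionMatrix(values=vals, annotation=ann)
        cis = small_genotypes.snp_map.loc[small_truth.driver_cis_snp]
        region = (cis.chr, max(1, cis.bp - 5_000_000), cis.bp + 5_000_000)
        K = mixedmodel.kinship_matrix(small_genotypes)
        table = mixedmodel.local_eqtl_table(expr2, small_genotypes, K, region)
        n_genes = table["n_genes_region"].iloc[0]
        assert table["threshold"].iloc[0] == pytest.approx(0.05 / n_genes)
        row = table[table["gene"] == dg].iloc[0]
        assert row["probe"] == dg  # cleaner probe retained by the max rule
        assert row["significant"]

    def test_empty_region(self, small_genotypes, small_truth):
        expr = synth.simulate_expression(small_genotypes, small_truth, seed=55)
        K = mixedmodel.kinship_matrix(small_genotypes)
        table = mixedmodel.local_eqtl_table(expr, small_genotypes, K,
                                            ("chr9", 1, 2))
        assert len(table) == 0

    def test_bonferroni_formula_matches_gene_count(self):
        # a region holding 137 unique genes yields 0.05 / 137 ~= 3.6e-4
        rng = np.random.default_rng(9)
        n_genes, n = 137, 40
        genes = [f"g{i}" for i in range(n_genes)]
        values = pd.DataFrame(rng.standard_normal((n_genes, n)), index=genes,
                              columns=[f"s{j}" for j in range(n)])
        ann = pd.DataFrame({"gene": genes, "chr": "chr8",
                            "bp": np.linspace(20e6, 30e6, n_genes, dtype=int)},
                           index=genes)
        expr = ExpressionMatrix(values=values, annotation=ann)
        geno = _iid_genotypes(5, n, seed=10, chrom="chr8", spacing=2_000_000)
        geno.snp_map["bp"] += 20_000_000
        K = np.eye(n)
        table = mixedmodel.local_eqtl_table(expr, geno, K,
                                            ("chr8", 20_000_000, 30_000_000))
        assert table["n_genes_region"].iloc[0] == 137
        assert table["threshold"].iloc[0] == pytest.approx(3.65e-4, abs=5e-6)
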