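"""Network construction: correlations, soft threshold, TOM, modules, kME."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bonenet import netbuild
from conftest import pearson_oracle, random_expression


class TestCorrelationMatrix:
    def test_textbook_example_and_trivials(self):
        df = pd.DataFrame({"a": [1, 2, 3, 4], "b": [2, 1, 4, 3],
                           "dup": [1, 2, 3, 4], "neg": [-1, -2, -3, -4]}).T
        cor = netbuild.correlation_matrix(df)
        assert cor.loc["a", "b"] == pytest.approx(pearson_oracle([1, 2, 3, 4],
                                                                 [2, 1, 4, 3]))
        assert cor.loc["a", "b"] == pytest.approx(0.6)
        assert cor.loc["a", "dup"] == pytest.approx(1.0)
        assert cor.loc["a", "neg"] == pytest.approx(-1.0)
        assert np.allclose(np.diag(cor), 1.0)

    def test_zero_variance_gene_recorded_as_zero(self, caplog):
        df = random_expression(5, 10, seed=0)
        df.iloc[2] = 3.14
        with caplog.at_level("WARNING"):
            cor = netbuild.correlation_matrix(df)
        assert (cor.iloc[2].drop(df.index[2]) == 0).all()
        assert cor.iloc[2, 2] == 1.0
        assert "zero-variance" in caplog.text

    def test_requires_three_strains(self):
        with pytest.raises(ValueError):
            netbuild.correlation_matrix(random_expression(5, 2, seed=0))


class TestAdjacency:
    @pytest.mark.parametrize("r, beta, expected", [
        (0.5, 8, 0.00390625), (-0.5, 8, 0.00390625), (1.0, 3, 1.0),
        (1.0, 12, 1.0), (0.25, 2, 0.0625),
    ])
    def test_unsigned_power(self, r, beta, expected):
        cor = pd.DataFrame([[1.0, r], [r, 1.0]])
        adj = netbuild.adjacency(cor, beta)
        assert adj.iloc[0, 1] == pytest.approx(expected, rel=1e-12)

    def test_rejects_nonpositive_beta(self):
        with pytest.raises(ValueError):
            netbuild.adjacency(pd.DataFrame(np.eye(2)), 0)


class TestTom:
    def test_hand_examples(self):
        ones = pd.DataFrame(np.ones((3, 3)))
        assert np.allclose(netbuild.tom_similarity(ones), 1.0)
        eye = pd.DataFrame(np.eye(3))
        tom = netbuild.tom_similarity(eye).to_numpy()
        assert np.allclose(tom - np.eye(3), 0.0)
        half = pd.DataFrame(np.full((3, 3), 0.5))
        np.fill_diagonal(half.values, 1.0)
        tom = netbuild.tom_similarity(half).to_numpy()
        # l = 0.25, k = 1, omega = (0.25 + 0.5) / (1 + 1 - 0.5) = 0.5
        assert np.allclose(tom[np.triu_indices(3, 1)], 0.5)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            n = int(rng.integers(4, 30))
            A = rng.random((n, n))
            A = (A + A.T) / 2
            np.fill_diagonal(A, 1.0)
            fast = netbuild.tom_similarity(pd.DataFrame(A)).to_numpy()
            slow = netbuild.tom_similarity_bruteforce(A)
            assert np.abs(fast - slow).max() < 1e-10

    def test_bounds_and_neighbor_monotonicity(self):
        rng = np.random.default_rng(8)
        A = rng.random((12, 12)) * 0.5
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        tom = netbuild.tom_similarity(pd.DataFrame(A)).to_numpy()
        assert (tom >= 0).all() and (tom <= 1).all()
        # raising a_uv for u,v not in {i,j} never decreases l_ij
        i, j, u, v = 0, 1, 5, 7
        A2 = A.copy()
        A2[u, v] = A2[v, u] = min(1.0, A2[u, v] + 0.3)
        def l_ij(M):
            Mi = M.copy(); np.fill_diagonal(Mi, 0.0)
            return sum(Mi[i, w] * Mi[w, j] for w in range(12) if w not in (i, j))
        assert l_ij(A2) >= l_ij(A)


class TestSoftThreshold:
    def test_planted_hub_structure_reaches_target(self, small_network):
        soft = small_network["soft"]
        assert soft.satisfied, "module-structured data should admit a scale-free fit"
        row = soft.fits[soft.fits.power == soft.beta].iloc[0]
        assert row.r2 >= 0.8 and row.slope < 0
        # independent regression oracle on the chosen power's connectivity bins
        A = np.abs(small_network["cor"].to_numpy()) ** soft.beta
        np.fill_diagonal(A, 0.0)
        k = A.sum(axis=1)
        edges = np.linspace(k.min(), k.max(), 11)
        which = np.clip(np.digitize(k, edges[1:-1]), 0, 9)
        xs, ys = [], []
        for b in range(10):
            sel = which == b
            if sel.sum():
                xs.append(np.log10(k[sel].mean()))
                ys.append(np.log10(sel.mean()))
        lr = stats.linregress(xs, ys)
        assert lr.rvalue**2 == pytest.approx(row.r2, abs=1e-8)
        assert lr.slope == pytest.approx(row.slope, abs=1e-8)

    def test_pure_noise_low_fit_at_beta_one(self):
        noise = random_expression(300, 60, seed=1)
        cor = netbuild.correlation_matrix(noise)
        soft = netbuild.pick_soft_threshold(cor, candidate_powers=(1, 2, 4, 6))
        fit_at_1 = soft.fits[soft.fits.power == 1].iloc[0]
        assert fit_at_1.r2 < 0.8
        assert soft.beta > 1

    def test_all_zero_correlation_rejected(self):
        with pytest.raises(ValueError):
            netbuild.pick_soft_threshold(pd.DataFrame(np.zeros((60, 60))))


def _planted_blocks(n_blocks=3, size=50, n_noise=50, r=0.8, n=80, seed=0):
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    lam = np.sqrt(r)
    for b in range(n_blocks):
        f = rng.standard_normal(n)
        for _ in range(size):
            rows.append(lam * f + np.sqrt(1 - lam**2) * rng.standard_normal(n))
            labels.append(b + 1)
    for _ in range(n_noise):
        rows.append(rng.standard_normal(n))
        labels.append(0)
    df = pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))])
    return df, pd.Series(labels, index=df.index)


class TestDetectModules:
    def test_recovers_planted_blocks(self):
        from sklearn.metrics import adjusted_rand_score

        df, truth = _planted_blocks(seed=2)
        cor = netbuild.correlation_matrix(df)
        tom = netbuild.tom_similarity(netbuild.adjacency(cor, 6))
        part = netbuild.detect_modules(df, tom)
        assert adjusted_rand_score(truth, part.labels) >= 0.95
        # labels renumbered by descending size
        sizes = part.module_sizes
        assert list(sizes.values) == sorted(sizes.values, reverse=True)

    def test_pure_noise_mostly_unassigned(self):
        df = random_expression(400, 96, seed=3)
        cor = netbuild.correlation_matrix(df)
        tom = netbuild.tom_similarity(netbuild.adjacency(cor, 6))
        part = netbuild.detect_modules(df, tom)
        assert (part.labels == 0).mean() >= 0.9

    def test_small_block_dissolved(self):
        df, truth = _planted_blocks(n_blocks=1, size=19, n_noise=150, seed=4)
        cor = netbuild.correlation_matrix(df)
        tom = netbuild.tom_similarity(netbuild.adjacency(cor, 6))
        part = netbuild.detect_modules(df, tom, min_module_size=20)
        assert (part.labels[truth == 1] == 0).all()

    def test_determinism(self):
        df, _ = _planted_blocks(seed=5)
        cor = netbuild.correlation_matrix(df)
        tom = netbuild.tom_similarity(netbuild.adjacency(cor, 6))
        a = netbuild.detect_modules(df, tom)
        b = netbuild.detect_modules(df, tom)
        assert (a.labels == b.labels).all()


class TestEigengenes:
    def test_identical_genes_rank_one(self):
        rng = np.random.default_rng(0)
        profile = rng.standard_normal(30)
        df = pd.DataFrame([profile] * 5, index=[f"g{i}" for i in range(5)])
        labels = pd.Series(1, index=df.index)
        eig, ve = netbuild.module_eigengenes(df, labels)
        z = (profile - profile.mean()) / profile.std(ddof=1)
        assert np.allclose(eig.loc[1].to_numpy(), z, atol=1e-8)
        assert ve.loc[1] == pytest.approx(1.0)

    def test_antipodal_pair_variance_explained(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(40)
        df = pd.DataFrame([x, -x], index=["g0", "g1"])
        eig, ve = netbuild.module_eigengenes(df, pd.Series(1, index=df.index))
        assert ve.loc[1] == pytest.approx(1.0)
        # documented tie-break: orientation follows the first member
        r0 = np.corrcoef(df.loc["g0"], eig.loc[1])[0, 1]
        assert r0 > 0

    def test_planted_factor_recovered(self, small_expression, small_truth):
        labels = small_truth.module_labels(small_expression.probes)
        eig, _ = netbuild.module_eigengenes(small_expression, labels)
        # target module factor is recoverable at default noise
        members = labels[labels == 2].index
        f_proxy = small_expression.values.loc[members].mean(axis=0)
        r = np.corrcoef(eig.loc[2], f_proxy)[0, 1]
        assert abs(r) >= 0.95

    def test_gene_order_invariance(self, small_expression, small_truth):
        labels = small_truth.module_labels(small_expression.probes)
        eig1, _ = netbuild.module_eigengenes(small_expression, labels)
        perm = small_expression.values.sample(frac=1, random_state=0)
        eig2, _ = netbuild.module_eigengenes(perm, labels.loc[perm.index])
        for mod in eig1.index:
            r = np.corrcoef(eig1.loc[mod], eig2.loc[mod])[0, 1]
            assert abs(r) == pytest.approx(1.0, abs=1e-8)


class TestKme:
    def test_gene_equal_to_eigengene(self):
        rng = np.random.default_rng(2)
        e = rng.standard_normal(30)
        df = pd.DataFrame([e, e * 2 + 1], index=["g0", "g1"])
        eig = pd.DataFrame([e], index=pd.Index([1], name="module"),
                           columns=df.columns)
        kme = netbuild.intramodular_connectivity(df, eig)
        assert kme.loc["g0", 1] == pytest.approx(1.0)
        assert kme.loc["g1", 1] == pytest.approx(1.0)

    def test_noise_gene_kme_small(self):
        rng = np.random.default_rng(3)
        r_crit = 0.2006  # 5% two-sided at n = 96
        hits = 0
        e = rng.standard_normal(96)
        eig = pd.DataFrame([e], index=pd.Index([1], name="module"))
        for s in range(100):
            g = rng.standard_normal(96)
            kme = netbuild.intramodular_connectivity(
                pd.DataFrame([g], index=["g"], columns=eig.columns), eig)
            hits += abs(kme.iloc[0, 0]) < r_crit
        assert hits >= 90

    def test_factor_model_closed_form(self):
        # kme ~= lambda / sqrt(lambda^2 + sigma^2) for x = lambda f + sigma e
        lam, sigma, n = 0.8, 1.0, 96
        expected = lam / np.sqrt(lam**2 + sigma**2)
        vals = []
        for s in range(80):
            rng = np.random.default_rng(100 + s)
            f = rng.standard_normal(n)
            X = np.array([lam * f + sigma * rng.standard_normal(n)
                          for _ in range(30)])
            df = pd.DataFrame(X, index=[f"g{i}" for i in range(30)])
            eig, _ = netbuild.module_eigengenes(df, pd.Series(1, index=df.index))
            kme = netbuild.intramodular_connectivity(df, eig)
            vals.append(kme[1].mean())
        assert np.mean(vals) == pytest.approx(expected, abs=0.05)
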