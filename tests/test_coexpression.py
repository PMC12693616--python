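import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import rand_score

from corestress.coexpression import CoexpressionNetwork, build_adjacency, topological_overlap


def _block_matrix(seed=3, n_samples=50, block_sizes=(30, 30), n_noise=100, noise_sd=0.23):
    """Planted co-expression blocks (within-block cor ~ 0.95) plus noise genes."""
    rng = np.random.default_rng(seed)
    rows, names, labels = [], [], []
    for b, size in enumerate(block_sizes):
        latent = rng.normal(size=n_samples)
        for i in range(size):
            rows.append(latent + rng.normal(0, noise_sd, n_samples))
            names.append(f"b{b}_{i}")
            labels.append(b)
    for i in range(n_noise):
        rows.append(rng.normal(size=n_samples))
        names.append(f"noise_{i}")
        labels.append(-1)
    return pd.DataFrame(rows, index=names), np.array(labels)


class TestAdjacency:
    def test_perfect_and_zero_correlation(self):
        t = np.linspace(0, 1, 8)
        m = pd.DataFrame(
            [t, 2 * t + 1, -t, np.array([1, -1] * 4, dtype=float)],
            index=["a", "b", "c", "d"],
        )
        adj = build_adjacency(m, power=9)
        assert adj.at["a", "b"] == pytest.approx(1.0)  # cor +1
        assert adj.at["a", "c"] == pytest.approx(1.0)  # cor -1, unsigned
        assert np.allclose(np.diag(adj.to_numpy()), 1.0)
        assert adj.to_numpy().min() >= 0 and adj.to_numpy().max() <= 1

    def test_power_one_unsigned_equals_abs_pearson(self, toy_matrix):
        adj = build_adjacency(toy_matrix, power=1).to_numpy()
        # brute-force Pearson, pair by pair
        X = toy_matrix.to_numpy()
        for i in range(len(X)):
            for j in range(len(X)):
                if i == j:
                    continue
                xi, xj = X[i], X[j]
                r = np.sum((xi - xi.mean()) * (xj - xj.mean())) / (
                    np.sqrt(np.sum((xi - xi.mean()) ** 2) * np.sum((xj - xj.mean()) ** 2))
                )
                assert adj[i, j] == pytest.approx(abs(r), abs=1e-12)

    def test_signed_formula(self, toy_matrix):
        unsigned1 = build_adjacency(toy_matrix, power=1).to_numpy()
        signed1 = build_adjacency(toy_matrix, power=1, network_type="signed").to_numpy()
        cor = np.corrcoef(toy_matrix.to_numpy())
        off = ~np.eye(len(cor), dtype=bool)
        np.testing.assert_allclose(signed1[off], ((1 + cor[off]) / 2), atol=1e-12)
        assert (signed1[off] <= unsigned1[off] / 2 + 0.5 + 1e-12).all()

    def test_symmetry(self, toy_matrix):
        adj = build_adjacency(toy_matrix).to_numpy()
        np.testing.assert_allclose(adj, adj.T, atol=1e-12)

    def test_zero_variance_gene_rejected(self):
        m = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [3.0, 1.0, 2.0]], index=list("abc"))
        with pytest.raises(ValueError, match="zero-variance"):
            build_adjacency(m)

    def test_tom_in_unit_interval(self, toy_matrix):
        tom = topological_overlap(build_adjacency(toy_matrix)).to_numpy()
        assert tom.min() >= 0 and tom.max() <= 1 + 1e-12


class TestModules:
    def test_two_planted_blocks_recovered(self):
        m, labels = _block_matrix()
        net = CoexpressionNetwork().fit(m)
        assert net.n_modules_ == 2
        block_genes = labels >= 0
        found = pd.factorize(net.modules_[block_genes])[0]
        assert rand_score(labels[block_genes], found) >= 0.95

    def test_noise_genes_mostly_unassigned(self):
        rng = np.random.default_rng(9)
        m = pd.DataFrame(rng.normal(size=(100, 40)), index=[f"n{i}" for i in range(100)])
        net = CoexpressionNetwork(min_module_size=20).fit(m)
        assert (net.modules_ == "M0").mean() >= 0.8

    def test_labels_partition_genes(self):
        m, _ = _block_matrix(seed=5)
        net = CoexpressionNetwork().fit(m)
        assert set(net.modules_.index) == set(m.index)
        assert net.modules_.notna().all()

    def test_too_few_genes_all_background(self):
        m, _ = _block_matrix(seed=1, block_sizes=(5,), n_noise=0)
        net = CoexpressionNetwork(min_module_size=20)
        with pytest.warns(UserWarning, match="min_module_size"):
            modules = net.detect_modules(build_adjacency(m))
        assert (modules == "M0").all()


class TestEigengenesAndKME:
    def test_identical_genes_eigengene_correlates_perfectly(self):
        rng = np.random.default_rng(0)
        profile = rng.normal(size=30)
        m = pd.DataFrame([profile] * 5 + [rng.normal(size=30)], index=[f"g{i}" for i in range(6)])
        net = CoexpressionNetwork(min_module_size=2)
        modules = pd.Series(["M1"] * 5 + ["M0"], index=m.index)
        eig = net.module_eigengenes(m, modules)
        assert abs(np.corrcoef(eig.loc["M1"], profile)[0, 1]) == pytest.approx(1.0)
        kme = net.compute_kme(m, eig)
        assert kme.at["g0", "M1"] == pytest.approx(1.0)

    def test_orientation_invariant_to_sign_flips(self):
        m, _ = _block_matrix(seed=7, block_sizes=(20,), n_noise=10)
        net = CoexpressionNetwork(min_module_size=10)
        modules = pd.Series(
            ["M1"] * 20 + ["M0"] * 10, index=m.index
        )
        eig1 = net.module_eigengenes(m, modules)
        flipped = m.copy()
        flipped.iloc[:20] = -flipped.iloc[:20]
        eig2 = net.module_eigengenes(flipped, modules)
        # orientation rule re-aligns the eigengene with the module mean
        assert abs(np.corrcoef(eig1.loc["M1"], eig2.loc["M1"])[0, 1]) == pytest.approx(1.0)

    def test_kme_matches_brute_force_pearson(self):
        m, _ = _block_matrix(seed=11, block_sizes=(15, 15), n_noise=5, n_samples=25)
        net = CoexpressionNetwork(min_module_size=5).fit(m)
        for g in list(m.index)[:10]:
            for mod in net.eigengenes_.index:
                expected = np.corrcoef(m.loc[g], net.eigengenes_.loc[mod])[0, 1]
                assert net.kme_.at[g, mod] == pytest.approx(expected, abs=1e-10)

    def test_orthogonal_gene_kme_near_zero(self):
        n = 40
        base = np.sin(np.linspace(0, 4 * np.pi, n))
        ortho = np.cos(np.linspace(0, 4 * np.pi, n))
        assert abs(np.corrcoef(base, ortho)[0, 1]) < 0.05
        m = pd.DataFrame([base] * 4 + [ortho], index=[f"g{i}" for i in range(5)])
        net = CoexpressionNetwork(min_module_size=2)
        modules = pd.Series(["M1"] * 4 + ["M0"], index=m.index)
        eig = net.module_eigengenes(m, modules)
        kme = net.compute_kme(m, eig)
        assert abs(kme.at["g4", "M1"]) < 0.05


class TestHubGenes:
    def test_threshold_equals_brute_force_quantile(self):
        m, _ = _block_matrix(seed=13)
        net = CoexpressionNetwork().fit(m)
        assigned = net.modules_.index[net.modules_ != "M0"]
        own = sorted(abs(net.kme_.at[g, net.modules_[g]]) for g in assigned)
        assert net.hub_threshold_ == pytest.approx(np.quantile(own, 0.95), abs=1e-10)

    def test_hub_fraction_near_five_percent(self):
        m, _ = _block_matrix(seed=17, block_sizes=(40, 40), n_noise=40)
        net = CoexpressionNetwork().fit(m)
        assigned = (net.modules_ != "M0").sum()
        assert len(net.hub_genes_) <= 0.05 * assigned + 1
        assert len(net.hub_genes_) >= 1

    def test_all_tied_kme_yields_no_hubs(self):
        net = CoexpressionNetwork()
        kme = pd.DataFrame({"M1": [0.9, 0.9, 0.9]}, index=list("abc"))
        modules = pd.Series(["M1", "M1", "M1"], index=list("abc"))
        hubs, threshold = net.hub_genes(kme, modules)
        assert hubs == set()
        assert threshold == pytest.approx(0.9)


class TestModuleSetEnrichment:
    def test_module_equal_to_set_is_most_significant(self):
        m, _ = _block_matrix(seed=19)
        net = CoexpressionNetwork().fit(m)
        target_module = "M1"
        gene_set = set(net.modules_.index[net.modules_ == target_module])
        table = net.module_set_enrichment(net.modules_, gene_set)
        best = table.loc[table["p"].idxmin(), "module"]
        assert best == target_module
        assert table.loc[table["module"] == target_module, "q"].iloc[0] < 0.05

    def test_counts_sum_to_universe(self):
        m, _ = _block_matrix(seed=23, block_sizes=(15,), n_noise=20, n_samples=30)
        net = CoexpressionNetwork(min_module_size=10).fit(m)
        table = net.module_set_enrichment(net.modules_, set(list(m.index)[:7]))
        sums = table[["a", "b", "c", "d"]].sum(axis=1)
        assert (sums == len(m.index)).all()
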