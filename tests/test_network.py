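"""Coexpression network construction, modules, eigengenes, connectivity."""

import numpy as np
import pandas as pd
import pytest

from holoseq import network
from holoseq.simulate import SimulationConfig, default_design, gen_counts


def _block_expr(rng, n_blocks=2, block_size=100, n_noise=0, n_samples=20,
                within=0.95):
    """Expression with independent latent factors per block."""
    rows = []
    truth = []
    for b in range(n_blocks):
        f = rng.normal(size=n_samples)
        for _ in range(block_size):
            rows.append(within * f + np.sqrt(1 - within ** 2)
                        * rng.normal(size=n_samples))
            truth.append(b + 1)
    for _ in range(n_noise):
        rows.append(rng.normal(size=n_samples))
        truth.append(0)
    idx = [f"g{i}" for i in range(len(rows))]
    return pd.DataFrame(rows, index=idx), pd.Series(truth, index=idx)


class TestFilterFpkm:
    def test_boundary(self):
        fpkm = pd.DataFrame([[1, 1, 1, 0], [1, 1, 0.5, 0.2]],
                            index=["keep", "drop"], columns=list("abcd"))
        assert network.filter_fpkm(fpkm) == ["keep"]

    def test_zero_floor_keeps_all(self):
        fpkm = pd.DataFrame([[0.0, 0, 0]], index=["g"], columns=list("abc"))
        assert network.filter_fpkm(fpkm, min_value=0) == ["g"]


class TestAdjacency:
    def test_perfect_correlation(self, rng):
        x = rng.normal(size=10)
        expr = pd.DataFrame([x, 2 * x + 1], index=["a", "b"])
        adj = network.adjacency(expr, beta=7)
        assert adj.loc["a", "b"] == pytest.approx(1.0)

    def test_power_arithmetic(self):
        # r = 0.5 at beta 14 -> 0.5^14
        n = 16
        x = np.concatenate([np.ones(n // 2), -np.ones(n // 2)])
        y = np.concatenate([np.ones(n // 4), -np.ones(n // 4)] * 2)
        z = (x + np.sqrt(3) * y) / 2  # cor(x, z) = 0.5 exactly
        expr = pd.DataFrame([x, z], index=["a", "b"])
        adj = network.adjacency(expr, beta=14)
        assert adj.loc["a", "b"] == pytest.approx(0.5 ** 14)

    def test_symmetric_unit_interval(self, rng):
        expr = pd.DataFrame(rng.normal(size=(30, 12)))
        adj = network.adjacency(expr, beta=6).to_numpy()
        assert np.allclose(adj, adj.T)
        assert adj.min() >= 0 and adj.max() <= 1

    def test_zero_variance_gene_rejected(self, rng):
        expr = pd.DataFrame([np.ones(8), rng.normal(size=8)])
        with pytest.raises(ValueError):
            network.adjacency(expr, beta=2)


class TestTom:
    def test_isolated_pair_full_overlap(self):
        adj = pd.DataFrame([[1.0, 1.0], [1.0, 1.0]])
        tom = network.tom_similarity(adj)
        assert tom.iloc[0, 1] == pytest.approx(1.0)

    def test_unconnected_no_shared_neighbors(self):
        adj = pd.DataFrame(np.eye(3))
        tom = network.tom_similarity(adj)
        assert tom.iloc[0, 1] == 0.0

    def test_matches_brute_force(self, rng):
        n = 20
        a = rng.uniform(0, 1, size=(n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        tom = network.tom_similarity(pd.DataFrame(a)).to_numpy()
        # triple-loop oracle
        a0 = a.copy()
        np.fill_diagonal(a0, 0.0)
        k = a0.sum(axis=1)
        for i in range(n):
            for j in range(n):
                if i == j:
                    assert tom[i, j] == 1.0
                    continue
                shared = sum(a0[i, u] * a0[u, j] for u in range(n))
                expect = (shared + a0[i, j]) / (min(k[i], k[j]) + 1 - a0[i, j])
                assert tom[i, j] == pytest.approx(expect)


class TestSoftThreshold:
    def test_exact_power_law_degree_sequence_fits_one(self):
        # frequencies exactly proportional to k^-1 across log-spaced k:
        # the log-log regression is exactly linear
        ks, counts = [], []
        for j in range(8):
            k = 2.0 ** j
            ks.append(k)
            counts.append(int(2 ** (10 - j)))
        k_seq = np.repeat(ks, counts)
        assert network.scale_free_fit(k_seq) >= 0.95

    def test_noise_mean_connectivity_decreases_in_beta(self, rng):
        expr = pd.DataFrame(rng.normal(size=(120, 16)))
        _, table = network.pick_soft_threshold(expr, candidates=range(1, 10),
                                               target=2.0)
        mk = table["mean_k"].to_numpy()
        assert (np.diff(mk) < 0).all()

    def test_unreachable_target_warns_and_returns_argmax(self, rng):
        expr = pd.DataFrame(rng.normal(size=(60, 10)))
        with pytest.warns(UserWarning):
            beta, table = network.pick_soft_threshold(
                expr, candidates=range(1, 6), target=2.0)
        assert beta == int(table.loc[table["fit_index"].idxmax(), "beta"])


class TestModules:
    def test_two_planted_blocks_recovered(self, rng):
        expr, truth = _block_expr(rng, n_blocks=2, block_size=100)
        adj = network.adjacency(expr, beta=6)
        tom = network.tom_similarity(adj)
        assign = network.detect_modules(tom, expr=expr)
        assert set(assign.unique()) == {1, 2}
        # label-permutation match
        tab = pd.crosstab(truth, assign)
        assert tab.max(axis=1).sum() == len(expr)

    def test_pure_noise_mostly_unassigned(self):
        fracs = []
        for seed in range(10):
            gen = np.random.default_rng(seed)
            expr = pd.DataFrame(gen.normal(size=(200, 20)),
                                index=[f"g{i}" for i in range(200)])
            adj = network.adjacency(expr, beta=6)
            tom = network.tom_similarity(adj)
            assign = network.detect_modules(tom, expr=expr)
            fracs.append((assign == 0).mean())
        assert np.mean(fracs) >= 0.8

    def test_min_size_larger_than_blocks_gives_all_grey(self, rng):
        expr, _ = _block_expr(rng, n_blocks=2, block_size=20)
        adj = network.adjacency(expr, beta=6)
        tom = network.tom_similarity(adj)
        assign = network.detect_modules(tom, min_module_size=50, expr=expr)
        assert (assign == 0).all()


class TestEigengene:
    def test_identical_profiles_explain_everything(self, rng):
        v = rng.normal(size=8)
        expr = pd.DataFrame([v, 2 * v, -v + 3], index=["a", "b", "c"])
        scores, ve = network.module_eigengene(expr, ["a", "b"])
        assert ve == pytest.approx(1.0)
        vz = (v - v.mean()) / v.std()
        assert np.allclose(np.abs(scores), np.abs(vz / np.sqrt(len(v))), atol=1e-8)

    def test_svd_oracle_on_fixed_matrix(self):
        expr = pd.DataFrame(
            [[1.0, 2, 3, 4], [2, 4, 6, 8], [4, 3, 2, 1],
             [9, 7, 5, 3], [1, 3, 2, 4], [5, 5, 6, 4]],
            index=list("abcdef"), columns=list("wxyz"))
        scores, ve = network.module_eigengene(expr, list("abcdef"))
        z = expr.to_numpy()
        z = (z - z.mean(1, keepdims=True)) / z.std(1, ddof=0, keepdims=True)
        s = np.linalg.svd(z, compute_uv=False)
        assert ve == pytest.approx(s[0] ** 2 / (s ** 2).sum())
        # deterministic sign: positive correlation with the mean profile
        assert np.dot(scores, z.mean(0)) > 0

    def test_gene_order_irrelevant(self, rng):
        expr, _ = _block_expr(rng, n_blocks=1, block_size=10)
        s1, _ = network.module_eigengene(expr, list(expr.index))
        s2, _ = network.module_eigengene(expr, list(expr.index)[::-1])
        assert np.allclose(s1, s2)


class TestModuleTrait:
    def test_eigengene_equal_to_trait(self):
        trait = pd.Series([0.0, 0, 0, 1, 1, 1], index=list("abcdef"))
        eig = pd.DataFrame({"M1": trait.to_numpy()}, index=trait.index)
        res = network.module_trait_association(eig, trait)
        assert res["r_squared"].iloc[0] == pytest.approx(1.0)
        assert res["p"].iloc[0] < 1e-6

    def test_orthogonal_trait(self):
        trait = pd.Series([0.0, 1, 0, 1], index=list("abcd"))
        eig = pd.DataFrame({"M1": [1.0, 1, -1, -1]}, index=trait.index)
        res = network.module_trait_association(eig, trait)
        assert res["r_squared"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_constant_trait_rejected(self):
        eig = pd.DataFrame({"M1": [0.1, 0.2, 0.3]}, index=list("abc"))
        with pytest.raises(ValueError):
            network.module_trait_association(eig, pd.Series([1.0, 1, 1],
                                                            index=list("abc")))

    def test_planted_trait_module_recovered(self):
        hits = 0
        for seed in range(20):
            cfg = SimulationConfig(seed=400 + seed, n_genes=250, n_deg_site=0,
                                   n_deg_clade=0,
                                   module_spec=((60, 0.8), (60, 0.8)),
                                   module_traits=("clade", None))
            design = default_design(cfg)
            _, fpkm, truth = gen_counts(cfg, design)
            expr = network.log_fpkm(fpkm)
            expr = expr[expr.std(axis=1) > 0]
            adj = network.adjacency(expr, beta=6)
            tom = network.tom_similarity(adj)
            assign = network.detect_modules(tom, expr=expr)
            if assign.max() < 1:
                continue
            mods = network.build_module_set(expr, adj, assign)
            trait = (design["clade"] == "D").astype(float)
            res = network.module_trait_association(mods.eigengenes, trait)
            if (res["fdr"] < 0.05).any():
                hits += 1
        assert hits >= 18


class TestConnectivity:
    def test_star_graph(self):
        n = 6
        a = np.zeros((n, n))
        a[0, 1:] = a[1:, 0] = 1.0
        np.fill_diagonal(a, 1.0)
        adj = pd.DataFrame(a, index=list("cabdef"), columns=list("cabdef"))
        assign = pd.Series(1, index=adj.index)
        k_total, k_within, _ = network.connectivity(adj, assign)
        assert k_total.iloc[0] == pytest.approx(5.0)
        assert (k_within <= k_total + 1e-12).all()

    def test_matches_brute_force(self, rng):
        n = 15
        a = rng.uniform(0, 1, size=(n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        idx = [f"g{i}" for i in range(n)]
        adj = pd.DataFrame(a, index=idx, columns=idx)
        assign = pd.Series(rng.integers(0, 3, size=n), index=idx)
        k_total, k_within, _ = network.connectivity(adj, assign)
        for i in range(n):
            kt = sum(a[i, j] for j in range(n) if j != i)
            kw = sum(a[i, j] for j in range(n)
                     if j != i and assign.iloc[j] == assign.iloc[i])
            assert k_total.iloc[i] == pytest.approx(kt)
            if assign.iloc[i] != 0:
                assert k_within.iloc[i] == pytest.approx(kw)


def test_planted_module_eigengene_tracks_latent_factor():
    cfg = SimulationConfig(seed=77, n_genes=300, n_deg_site=0, n_deg_clade=0,
                           module_spec=((80, 0.8),))
    design = default_design(cfg)
    _, fpkm, truth = gen_counts(cfg, design)
    expr = network.log_fpkm(fpkm)
    genes = [g for g, m in truth.module_labels.items() if m == 1]
    scores, _ = network.module_eigengene(expr, genes)
    # the eigengene must track the module's shared signal: correlate it
    # with the mean standardized profile of the module genes
    sub = expr.loc[genes].to_numpy()
    z = (sub - sub.mean(1, keepdims=True)) / sub.std(1, keepdims=True)
    r = np.corrcoef(scores, z.mean(axis=0))[0, 1]
    assert abs(r) >= 0.9
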