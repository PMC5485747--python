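"""Adjacency, scale-free power selection, TOM, module detection, eigengenes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import planted_blocks
from emtint.coexpression import (
    DEFAULT_BETA_GRID,
    TomModuleDetector,
    adjacency,
    detect_modules,
    module_eigengene,
    pick_beta,
    regress_out_phenotype,
    tom,
)
from emtint.io import EPITHELIAL, MESENCHYMAL


def tom_bruteforce(adj):
    """Naive triple-loop TOM evaluation; independent oracle."""
    a = np.asarray(adj, float).copy()
    np.fill_diagonal(a, 0.0)
    n = a.shape[0]
    out = np.eye(n)
    k = a.sum(axis=1)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, l] * a[l, j] for l in range(n) if l not in (i, j))
            denom = min(k[i], k[j]) + 1.0 - a[i, j]
            out[i, j] = (shared + a[i, j]) / denom if denom else 0.0
    return out


def random_adjacency(rng, n):
    m = rng.uniform(0, 1, size=(n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return m


class TestRegressOutPhenotype:
    def test_exact_fit_and_group_mean_subtraction(self):
        values = np.array([[2.0, 2.0, 4.0, 4.0], [1.0, 3.0, 5.0, 9.0]])
        pheno = [EPITHELIAL, EPITHELIAL, MESENCHYMAL, MESENCHYMAL]
        resid = regress_out_phenotype(values, pheno)
        np.testing.assert_allclose(resid[0], 0.0, atol=1e-12)
        np.testing.assert_allclose(resid[1], [-1.0, 1.0, -2.0, 2.0], atol=1e-12)

    def test_residual_group_means_zero_unbalanced(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(10, 7))
        pheno = [EPITHELIAL] * 3 + [MESENCHYMAL] * 4
        resid = regress_out_phenotype(values, pheno)
        np.testing.assert_allclose(resid[:, :3].mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(resid[:, 3:].mean(axis=1), 0.0, atol=1e-12)


class TestAdjacency:
    def test_power_examples(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        values = np.vstack([x, -0.5 * x + np.array([0.0, 1.5, 1.0, 2.5])])
        corr = np.corrcoef(values)[0, 1]
        adj = adjacency(values, 2.0)
        assert adj[0, 1] == pytest.approx(abs(corr) ** 2)

    def test_perfect_correlation_saturates(self):
        x = np.array([1.0, 2.0, 3.0])
        values = np.vstack([x, 2 * x, -x])
        for beta in (1.0, 4.0, 9.5):
            adj = adjacency(values, beta)
            assert adj[0, 1] == pytest.approx(1.0)
            assert adj[0, 2] == pytest.approx(1.0)

    def test_beta_one_is_absolute_correlation(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=(6, 20))
        np.testing.assert_allclose(
            adjacency(values, 1.0) + np.eye(6), np.abs(np.corrcoef(values)) , atol=1e-12
        )

    def test_monotone_in_beta(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=(8, 15))
        low, high = adjacency(values, 2.0), adjacency(values, 8.0)
        off = ~np.eye(8, dtype=bool)
        assert (high[off] <= low[off] + 1e-12).all()

    def test_zero_variance_gene_rejected(self):
        values = np.vstack([np.ones(5), np.arange(5.0)])
        with pytest.raises(ValueError, match="zero-variance"):
            adjacency(values, 2.0)


class TestPickBeta:
    def test_default_grid_has_half_steps(self):
        assert 5.5 in DEFAULT_BETA_GRID
        assert DEFAULT_BETA_GRID[0] == 1.0 and DEFAULT_BETA_GRID[-1] == 12.0

    def test_preferential_attachment_degrees_fit_power_law(self):
        """A preferential-attachment degree sequence scores signed R^2 >= 0.8."""
        import networkx as nx

        from emtint.coexpression import scale_free_fit

        g = nx.barabasi_albert_graph(1000, 2, seed=7)
        degrees = np.array([d for _, d in g.degree()], dtype=float)
        signed_r2, slope = scale_free_fit(degrees)
        assert signed_r2 >= 0.8
        assert slope < 0

    def test_threshold_and_argmax_rules_consistent_with_fit_table(self):
        rng = np.random.default_rng(12)
        profiles = planted_blocks(rng, [15, 15, 20], 0.6, 30)
        beta_thr, table = pick_beta(profiles, grid=[1, 2, 3, 4], target_r2=0.8)
        reaching = table[table["signed_r2"] >= 0.8]
        if not reaching.empty:
            assert beta_thr == reaching.iloc[0]["beta"]
        else:
            assert beta_thr == table.loc[table["signed_r2"].idxmax(), "beta"]
        beta_max, table2 = pick_beta(profiles, grid=[1, 2, 3, 4], rule="argmax")
        assert beta_max == table2.loc[table2["signed_r2"].idxmax(), "beta"]

    def test_two_gene_input_rejected(self):
        with pytest.raises(ValueError, match="3 genes"):
            pick_beta(np.random.default_rng(0).normal(size=(2, 10)))


class TestTom:
    def test_two_gene_closed_form(self):
        for a12 in (0.0, 0.3, 0.9):
            adj = np.array([[0.0, a12], [a12, 0.0]])
            assert tom(adj)[0, 1] == pytest.approx(a12, abs=1e-15)

    def test_complete_graph_all_ones(self):
        for n in (3, 5, 8):
            adj = np.ones((n, n)) - np.eye(n)
            np.testing.assert_allclose(tom(adj), 1.0, atol=1e-15)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = int(rng.integers(3, 11))
            adj = random_adjacency(rng, n)
            np.testing.assert_allclose(tom(adj), tom_bruteforce(adj), atol=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 10_000), st.integers(3, 9))
    def test_tom_bounded_in_unit_interval(self, seed, n):
        adj = random_adjacency(np.random.default_rng(seed), n)
        t = tom(adj)
        assert (t >= -1e-12).all() and (t <= 1 + 1e-12).all()
        np.testing.assert_allclose(t, t.T, atol=1e-12)


class TestDetectModules:
    def test_planted_blocks_recovered_and_small_block_suppressed(self):
        rng = np.random.default_rng(7)
        X = planted_blocks(rng, [20, 20, 10], 0.8, 40)
        labels = detect_modules(1 - tom(adjacency(X, 6.0)), min_module_size=15)
        modules = sorted(set(labels) - {0})
        assert len(modules) == 2
        # block members co-assigned; the size-10 block yields no module
        assert len(set(labels[:20])) == 1 and labels[0] != 0
        assert len(set(labels[20:40])) == 1 and labels[20] != 0
        assert labels[0] != labels[20]
        assert (labels[40:] == 0).all()

    def test_noise_yields_no_modules(self):
        zero_runs = 0
        for seed in range(30):
            noise = np.random.default_rng(seed).normal(size=(50, 40))
            labels = detect_modules(1 - tom(adjacency(noise, 6.0)), min_module_size=15)
            zero_runs += (labels == 0).all()
        assert zero_runs >= 27  # >= 90% of seeded runs

    def test_fewer_genes_than_min_size(self):
        rng = np.random.default_rng(5)
        labels = detect_modules(1 - tom(random_adjacency(rng, 8)), min_module_size=15)
        assert (labels == 0).all()

    def test_pipeline_deterministic(self):
        rng = np.random.default_rng(11)
        X = planted_blocks(rng, [20, 20], 0.7, 30)
        d1 = TomModuleDetector(beta=6).fit(X)
        d2 = TomModuleDetector(beta=6).fit(X)
        np.testing.assert_array_equal(d1.labels_, d2.labels_)
        np.testing.assert_allclose(d1.tom_, d2.tom_)


class TestModuleEigengene:
    def test_identical_genes_give_unit_correlation(self):
        x = np.linspace(0, 1, 12)
        values = pd.DataFrame(np.tile(x, (5, 1)))
        table, varexp = module_eigengene(values, [1] * 5)
        r = np.corrcoef(table.loc[1], x)[0, 1]
        assert abs(r) == pytest.approx(1.0)
        assert varexp[1] == pytest.approx(1.0)

    def test_planted_module_tracks_mean_profile(self):
        rng = np.random.default_rng(8)
        X = planted_blocks(rng, [25], 0.7, 40)
        values = pd.DataFrame(X)
        table, varexp = module_eigengene(values, [1] * 25)
        z = (X - X.mean(1, keepdims=True)) / X.std(1, ddof=1, keepdims=True)
        r = np.corrcoef(table.loc[1], z.mean(axis=0))[0, 1]
        assert r >= 0.9
        assert np.linalg.norm(table.loc[1]) == pytest.approx(1.0)

    def test_sign_orientation_stable_under_global_flip(self):
        rng = np.random.default_rng(9)
        X = planted_blocks(rng, [10], 0.8, 20)
        e1, _ = module_eigengene(pd.DataFrame(X), [1] * 10)
        e2, _ = module_eigengene(pd.DataFrame(-X), [1] * 10)
        # flipping all genes flips the standardized profiles; orientation follows
        np.testing.assert_allclose(e1.loc[1].to_numpy(), -e2.loc[1].to_numpy(), atol=1e-10)

    def test_single_gene_module(self):
        x = np.array([[1.0, 2.0, 4.0, 3.0]])
        table, _ = module_eigengene(pd.DataFrame(x), [1])
        z = (x[0] - x[0].mean()) / x[0].std(ddof=1)
        np.testing.assert_allclose(table.loc[1], z / np.linalg.norm(z), atol=1e-12)
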