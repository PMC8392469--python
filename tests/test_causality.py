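"""Conditional-independence tests, PC, variable-lag methods, aggregation."""

import numpy as np
import pandas as pd
import pytest

from meiomove.causality import (AdjacencyStack, PCAlgorithm, adjust_pvalues,
                                aggregate_adjacency, causality_scan, ci_test,
                                export_graph, pc_algorithm, vl_granger,
                                vl_transfer_entropy)


class TestCITest:
    def test_exactly_uncorrelated_pair(self):
        x = np.array([1.0, -1, 1, -1, 1, -1, 1, -1])
        y = np.array([1.0, 1, -1, -1, 1, 1, -1, -1])
        res = ci_test(np.column_stack([x, y]), 0, 1)
        assert res.partial_corr == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_strong_dependence(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=500)
        y = x + rng.normal(0, 0.1, 500)
        res = ci_test(np.column_stack([x, y]), 0, 1)
        assert res.p_value < 1e-10

    def test_type_one_error_rate(self):
        rej = 0
        alpha = 0.05
        for seed in range(500):
            rng = np.random.default_rng(seed)
            data = rng.normal(size=(1000, 2))
            rej += ci_test(data, 0, 1).p_value < alpha
        rate = rej / 500
        assert abs(rate - alpha) < 2.5 * np.sqrt(alpha * (1 - alpha) / 500)

    def test_conditioning_removes_common_cause(self):
        rng = np.random.default_rng(1)
        z = rng.normal(size=1000)
        x = z + rng.normal(0, 0.5, 1000)
        y = z + rng.normal(0, 0.5, 1000)
        marginal = ci_test(np.column_stack([x, y, z]), 0, 1)
        conditional = ci_test(np.column_stack([x, y, z]), 0, 1, (2,))
        assert marginal.p_value < 1e-10
        assert conditional.p_value > 0.01


class TestPCAlgorithm:
    def test_independent_variables_empty_graph(self):
        data = np.random.default_rng(0).normal(size=(500, 4))
        g, A = pc_algorithm(data, 0.01)
        assert len(g.edges) == 0 and A.sum() == 0

    def test_chain_skeleton(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=1000)
        y = 0.8 * x + rng.normal(size=1000)
        z = 0.8 * y + rng.normal(size=1000)
        g, A = pc_algorithm(np.column_stack([x, y, z]), 0.01, ["X", "Y", "Z"])
        undirected = {frozenset(e) for e in g.edges}
        assert undirected == {frozenset({"X", "Y"}), frozenset({"Y", "Z"})}
        assert A.sum() == 0  # a chain is not orientable from observational data

    def test_collider_oriented(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=1000)
        y = rng.normal(size=1000)
        z = 0.8 * x + 0.8 * y + rng.normal(size=1000)
        g, A = pc_algorithm(np.column_stack([x, y, z]), 0.01, ["X", "Y", "Z"])
        assert set(g.edges) == {("X", "Z"), ("Y", "Z")}
        assert A[0, 2] == 1 and A[1, 2] == 1 and A.sum() == 2

    def test_variable_order_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=800)
        y = rng.normal(size=800)
        z = 0.7 * x + 0.7 * y + rng.normal(size=800)
        w = 0.5 * z + rng.normal(size=800)
        data = np.column_stack([x, y, z, w])
        names = ["x", "y", "z", "w"]
        base = pc_algorithm(data, 0.01, names)[0]
        perm = [2, 0, 3, 1]
        permuted = pc_algorithm(data[:, perm], 0.01, [names[i] for i in perm])[0]
        assert set(base.edges) == set(permuted.edges)


class TestVLGranger:
    def test_null_calibrated(self):
        nonsig = 0
        n_seeds = 60
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            res = vl_granger(rng.normal(size=180), rng.normal(size=180),
                             max_lag=10, n_perm=100, seed=seed)
            nonsig += res.p_value >= 0.01
        assert nonsig >= int(0.95 * n_seeds)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_planted_fixed_lag_detected(self, seed):
        rng = np.random.default_rng(100 + seed)
        x = rng.normal(size=190)
        y = np.roll(x, 5) + rng.normal(0, 0.1, 190)
        res = vl_granger(x[10:], y[10:], max_lag=10, n_perm=200, seed=seed)
        assert res.p_value < 0.01
        assert res.median_lag == pytest.approx(5, abs=1)
        assert res.direction

    @pytest.mark.parametrize("seed", [0, 1])
    def test_drifting_lag_favours_variable_lag(self, seed):
        rng = np.random.default_rng(200 + seed)
        n = 200
        x = rng.normal(size=n)
        lag = np.clip(3 + (np.arange(n) * 5) // n, 3, 8)
        y = np.array([x[t - lag[t]] for t in range(n)]) + rng.normal(0, 0.4, n)
        res_vl = vl_granger(x, y, max_lag=10, n_perm=100, seed=seed)
        res_fx = vl_granger(x, y, max_lag=10, variable_lag=False, n_perm=0)
        assert res_vl.p_value < 0.01
        assert res_vl.statistic > res_fx.statistic

    def test_constant_series_not_causal(self):
        res = vl_granger(np.zeros(180), np.random.default_rng(0).normal(size=180))
        assert res.p_value == 1.0 and not res.direction


class TestVLTransferEntropy:
    def test_independent_noise_te_near_zero(self):
        tes, ps = [], []
        for seed in range(12):
            rng = np.random.default_rng(seed)
            res = vl_transfer_entropy(rng.uniform(size=180), rng.uniform(size=180),
                                      max_lag=10, bins=3, n_perm=50, seed=seed)
            tes.append(res.statistic)
            ps.append(res.p_value)
        assert np.mean(tes) < 0.2          # far below the ~1.58 bit maximum
        assert 0.2 < np.mean(ps) < 0.8     # permutation p roughly uniform

    def test_noisy_binary_channel_closed_form(self):
        # y(t+1) = x(t) flipped with probability eps: TE -> 1 - H(eps) bits
        eps = 0.1
        rng = np.random.default_rng(9)
        x = rng.integers(0, 2, 5000).astype(float)
        y = np.roll(x, 1).copy()
        flip = rng.random(5000) < eps
        y[flip] = 1 - y[flip]
        res = vl_transfer_entropy(x, y, max_lag=10, bins=2, n_perm=0, seed=0)
        expected = 1 + eps * np.log2(eps) + (1 - eps) * np.log2(1 - eps)
        assert res.statistic == pytest.approx(expected, abs=0.05)

    def test_deterministic_copy_directionality(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=300)
        y = np.roll(x, 1)
        res = vl_transfer_entropy(x[5:], y[5:], max_lag=5, bins=3, n_perm=30, seed=0)
        assert res.statistic > res.reverse_statistic
        assert res.direction

    def test_bins_validation(self):
        with pytest.raises(ValueError, match="bins"):
            vl_transfer_entropy(np.zeros(100), np.zeros(100), bins=1)


class TestAdjustment:
    def test_bonferroni_examples(self):
        P = np.full((3, 3), np.nan)
        P[0, 1], P[1, 0], P[0, 2], P[2, 0], P[1, 2], P[2, 1] = \
            0.004, 0.5, 0.2, 0.3, 0.6, 0.7
        adj = adjust_pvalues(P, "bonferroni")
        assert adj[0, 1] == pytest.approx(0.024)   # m = 6 tested pairs
        assert adj[1, 0] == 1.0                    # capped

    def test_bh_step_up_by_hand(self):
        P = np.full((2, 2), np.nan)
        # three tested p-values via a 1x3 helper matrix: use explicit vector
        vals = np.array([[np.nan, 0.01, 0.02], [0.04, np.nan, np.nan],
                         [np.nan, np.nan, np.nan]])
        adj = adjust_pvalues(vals, "BH")
        assert adj[0, 1] == pytest.approx(0.03)
        assert adj[0, 2] == pytest.approx(0.03)
        assert adj[1, 0] == pytest.approx(0.04)


class TestAggregation:
    def make_stack(self, mats):
        return AdjacencyStack(np.array(mats), ("a", "b"), "vlte")

    def test_unanimous_edge(self):
        stack = self.make_stack([[[0, 1], [0, 0]]] * 4)
        g = aggregate_adjacency(stack, 0.8)
        assert g.a_hat.loc["a", "b"] == 1.0
        assert g.edges.iloc[0].to_dict() == {"source": "a", "target": "b",
                                             "weight": 1.0}

    def test_threshold_semantics(self):
        mats = [[[0, 1], [0, 0]]] * 3 + [[[0, 0], [0, 0]]]
        assert len(aggregate_adjacency(self.make_stack(mats), 0.75).edges) == 1
        assert len(aggregate_adjacency(self.make_stack(mats), 0.8).edges) == 0

    def test_mean_is_exact_and_linear(self):
        rng = np.random.default_rng(0)
        mats = rng.integers(0, 2, size=(10, 3, 3))
        for m in mats:
            np.fill_diagonal(m, 0)
        stack = AdjacencyStack(mats, ("a", "b", "c"), "pc")
        full = aggregate_adjacency(stack, 0.5).a_hat.to_numpy()
        assert np.array_equal(full, mats.mean(axis=0))
        part1 = mats[:4].mean(axis=0)
        part2 = mats[4:].mean(axis=0)
        assert np.allclose((4 * part1 + 6 * part2) / 10, full)

    def test_particle_order_invariance(self):
        rng = np.random.default_rng(1)
        mats = rng.integers(0, 2, size=(8, 2, 2))
        a = aggregate_adjacency(self.make_stack(list(mats)), 0.5).a_hat
        b = aggregate_adjacency(self.make_stack(list(mats[::-1])), 0.5).a_hat
        pd.testing.assert_frame_equal(a, b)

    def test_presence_weight_example(self):
        # an edge present in 62% of cells has a-hat 0.62: below a 0.8 bar
        mats = [[[0, 1], [0, 0]]] * 62 + [[[0, 0], [0, 0]]] * 38
        g = aggregate_adjacency(self.make_stack(mats), 0.8)
        assert g.a_hat.loc["a", "b"] == pytest.approx(0.62)
        assert len(g.edges) == 0


class TestExportGraph:
    def test_round_trip_and_consistency(self, tmp_path):
        mats = [[[0, 1], [0, 0]]] * 3 + [[[0, 0], [1, 0]]]
        stack = AdjacencyStack(np.array(mats), ("u", "v"), "vlgc")
        g = aggregate_adjacency(stack, 0.5)
        paths = export_graph(g, tmp_path)
        mat = pd.read_csv(paths["adjacency"], index_col=0)
        assert np.allclose(mat.to_numpy(), g.a_hat.to_numpy(), atol=1e-6)
        edges = pd.read_csv(paths["edges"])
        for row in edges.itertuples(index=False):
            assert row.weight == pytest.approx(g.a_hat.loc[row.source, row.target])
        import networkx as nx
        gg = nx.read_graphml(paths["graphml"])
        assert set(gg.nodes) == {"u", "v"}

    def test_empty_graph_still_valid(self, tmp_path):
        stack = AdjacencyStack(np.zeros((2, 2, 2), dtype=int), ("u", "v"), "pc")
        g = aggregate_adjacency(stack, 0.8)
        paths = export_graph(g, tmp_path, prefix="empty")
        import networkx as nx
        gg = nx.read_graphml(paths["graphml"])
        assert set(gg.nodes) == {"u", "v"} and len(gg.edges) == 0
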