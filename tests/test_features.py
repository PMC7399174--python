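import numpy as np
import pandas as pd
import pytest

import synlogic as sl
from synlogic.features import FeatureError
from oracles import (betweenness_oracle, efficiency_oracle,
                     harmonic_closeness_oracle, pci_oracle)


def digraph_edges(net):
    return {(s, t) for s, _, t in net.edges}


@pytest.fixture(scope="module")
def random_graphs():
    graphs = []
    for seed in range(30):
        net = sl.gen_network(n_nodes=6 + seed % 5, n_targets=2,
                             n_cycles=seed % 4, seed=seed)
        graphs.append(net)
    return graphs


class TestGlobalEfficiency:
    def test_complete_digraph_is_one(self):
        nodes = ["A", "B", "C"]
        edges = [(u, 1, v) for u in nodes for v in nodes if u != v]
        assert sl.global_efficiency(sl.make_network(edges)) == pytest.approx(1.0)

    def test_edgeless_graph_is_zero(self):
        net = sl.make_network([], extra_nodes=["A", "B", "C"])
        assert sl.global_efficiency(net) == 0.0

    def test_directed_path(self):
        net = sl.make_network([("A", 1, "B"), ("B", 1, "C")])
        assert sl.global_efficiency(net) == pytest.approx((1 + 1 + 0.5) / 6)

    def test_single_node_rejected(self):
        with pytest.raises(FeatureError):
            sl.global_efficiency(sl.make_network([], extra_nodes=["A"]))

    def test_bounds_and_oracle(self, random_graphs):
        for net in random_graphs:
            e = sl.global_efficiency(net)
            assert 0.0 <= e <= 1.0
            assert e == pytest.approx(efficiency_oracle(net.nodes, digraph_edges(net)))


class TestPci:
    def test_path_middle_node_is_total_loss(self):
        net = sl.make_network([("A", 1, "B"), ("B", 1, "C")])
        assert sl.pci(net, "B") == pytest.approx(1.0)

    def test_isolated_node_in_connected_remainder(self):
        net = sl.make_network([("A", 1, "B"), ("B", 1, "A")], extra_nodes=["X"])
        # removing X cannot shorten any remaining path; PCI follows from the
        # denominator change alone: E(G) = 2/6, E(G\X) = 2/2
        assert sl.pci(net, "X") == pytest.approx((2 / 6 - 1.0) / (2 / 6))

    def test_zero_efficiency_rejected(self):
        net = sl.make_network([], extra_nodes=["A", "B", "C"])
        with pytest.raises(FeatureError):
            sl.pci(net, "A")

    def test_matches_brute_force(self, random_graphs):
        for net in random_graphs[:12]:
            edges = digraph_edges(net)
            for node in sorted(net.nodes)[:4]:
                assert sl.pci(net, node) == pytest.approx(
                    pci_oracle(net.nodes, edges, node))


class TestCentralities:
    def test_out_star_hub(self):
        net = sl.make_network([("H", 1, f"L{i}") for i in range(4)])
        table = sl.centralities(net)
        assert table.loc["H", "betweenness"] == 0.0  # no through-paths
        assert table.loc["H", "out_degree"] == 4

    def test_path_middle_covers_single_through_path(self):
        net = sl.make_network([("A", 1, "B"), ("B", 1, "C")])
        table = sl.centralities(net)
        # one A->C shortest path through B, normalized by (n-1)(n-2) = 2
        assert table.loc["B", "betweenness"] == pytest.approx(0.5)

    def test_matches_path_enumeration_oracle(self, random_graphs):
        for net in random_graphs[:12]:
            edges = digraph_edges(net)
            table = sl.centralities(net)
            bet = betweenness_oracle(net.nodes, edges)
            clo = harmonic_closeness_oracle(net.nodes, edges)
            for v in net.nodes:
                assert table.loc[v, "betweenness"] == pytest.approx(bet[v])
                assert table.loc[v, "closeness"] == pytest.approx(clo[v])
                assert table.loc[v, "out_degree"] == len([1 for s, t in edges if s == v])


class TestFeatureTable:
    def test_one_row_per_node_with_label(self, bundle):
        table = sl.node_feature_table(bundle.network,
                                      labels={"M", "C1", "C2"})
        assert len(table) == len(bundle.network.nodes)
        assert set(table.columns) >= {"out_degree", "betweenness", "closeness",
                                      "pci", "label"}
        assert table.loc["M", "label"] == "high"

    def test_annotation_pass_through(self, bundle):
        ann = pd.DataFrame({"oncogene": {n: n.startswith("TGT")
                                         for n in bundle.network.nodes}})
        table = sl.node_feature_table(bundle.network, annotations=ann)
        assert table.loc["TGT1", "oncogene"]


class TestImportanceRanking:
    @staticmethod
    def _planted_table(seed, n=80, n_noise=3):
        rng = np.random.default_rng(seed)
        signal = rng.normal(size=n)
        table = pd.DataFrame({"signal": signal})
        for i in range(n_noise):
            table[f"noise{i}"] = rng.normal(size=n)
        labels = np.where(signal > 0, "high", "low")
        return table, labels

    @pytest.mark.parametrize("seed", range(3))
    def test_planted_signal_ranked_first(self, seed):
        table, labels = self._planted_table(seed)
        ranked = sl.importance_ranking(table, labels, seed=seed, n_repeats=5,
                                       n_estimators=100)
        assert ranked.iloc[0]["feature"] == "signal"
        assert ranked.iloc[0]["importance"] > 2 * ranked.iloc[1]["importance"]

    def test_single_feature_has_importance_one(self):
        table, labels = self._planted_table(0, n_noise=0)
        ranked = sl.importance_ranking(table, labels, seed=0, n_repeats=2,
                                       n_estimators=50)
        assert ranked["importance"].iloc[0] == pytest.approx(1.0)

    def test_duplicated_feature_splits_importance(self):
        table, labels = self._planted_table(1)
        dup = table.copy()
        dup["signal_copy"] = dup["signal"]
        base = sl.importance_ranking(table, labels, seed=2, n_repeats=5)
        split = sl.importance_ranking(dup, labels, seed=2, n_repeats=5)
        orig = float(base.set_index("feature").loc["signal", "importance"])
        pair = float(split.set_index("feature").loc[["signal", "signal_copy"],
                                                    "importance"].sum())
        assert pair == pytest.approx(orig, abs=0.1)

    def test_balanced_mode_runs_and_is_seeded(self):
        table, labels = self._planted_table(3)
        labels = np.where(np.arange(len(labels)) < 15, "high", "low")
        a = sl.importance_ranking(table, labels, balanced=True, seed=5, n_repeats=3)
        b = sl.importance_ranking(table, labels, balanced=True, seed=5, n_repeats=3)
        pd.testing.assert_frame_equal(a, b)

    def test_single_class_rejected(self):
        table, _ = self._planted_table(0)
        with pytest.raises(FeatureError):
            sl.importance_ranking(table, ["high"] * len(table))


class TestFeatureCorrelations:
    def test_self_and_negation(self):
        table = pd.DataFrame({"a": [1.0, 2.0, 3.0, 5.0]})
        table["neg"] = -table["a"]
        corr = sl.feature_correlations(table)
        assert corr.loc["a", "a"] == pytest.approx(1.0)
        assert corr.loc["a", "neg"] == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(4)
        table = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("xyz"))
        corr = sl.feature_correlations(table)
        x, y = table["x"].to_numpy(), table["y"].to_numpy()
        manual = (np.sum((x - x.mean()) * (y - y.mean()))
                  / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)))
        assert corr.loc["x", "y"] == pytest.approx(manual)

    def test_zero_variance_column_is_na(self):
        table = pd.DataFrame({"a": [1.0, 2.0, 3.0], "const": [1.0, 1.0, 1.0]})
        assert np.isnan(sl.feature_correlations(table).loc["a", "const"])

    def test_too_few_rows_rejected(self):
        with pytest.raises(FeatureError):
            sl.feature_correlations(pd.DataFrame({"a": [1.0, 2.0]}))
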