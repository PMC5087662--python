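import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from duxent.entropy import (
    entropy_per_sample,
    entropy_rate,
    local_entropies,
    prepare_network,
    stationary_distribution,
    stochastic_matrix,
)
from duxent.io import ExpressionMatrix, ValidationError
from duxent.simulate import SimulationConfig, simulate_experiment, simulate_network
from oracles import entropy_rate_bruteforce


def uniform_expr(graph):
    return pd.Series(1.0, index=sorted(graph.nodes()))


class TestPrepareNetwork:
    def test_largest_component_kept(self):
        g = nx.Graph()
        nx.add_path(g, ["a", "b", "c", "d", "e"])
        nx.add_path(g, ["x", "y", "z"])
        out = prepare_network(g, ["a", "b", "c", "d", "e", "x", "y", "z"])
        assert set(out.nodes()) == {"a", "b", "c", "d", "e"}
        assert out.graph["n_components_removed"] == 1

    def test_connected_fully_measured_is_identity(self, triangle):
        out = prepare_network(triangle, ["a", "b", "c"])
        assert set(out.edges()) == set(triangle.edges())
        assert out.graph["n_components_removed"] == 0

    def test_unmeasured_genes_dropped(self, triangle):
        g = triangle.copy()
        g.add_edge("c", "d")
        out = prepare_network(g, ["a", "b", "c"])
        assert "d" not in out

    def test_bipartite_survives_with_flag(self):
        square = nx.cycle_graph(4)
        square = nx.relabel_nodes(square, {i: f"n{i}" for i in square})
        out = prepare_network(square, square.nodes())
        assert out.graph["bipartite"] is True

    def test_too_small_component_rejected(self):
        g = nx.Graph([("a", "b")])
        with pytest.raises(ValidationError):
            prepare_network(g, ["a", "b"])


class TestStochasticMatrix:
    def test_uniform_triangle(self, triangle):
        sm = stochastic_matrix(triangle, uniform_expr(triangle))
        expected = np.array([[0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]])
        np.testing.assert_allclose(sm.matrix, expected)

    def test_mass_action_triangle(self, triangle, triangle_expression):
        sm = stochastic_matrix(triangle, triangle_expression)
        expected = np.array(
            [[0, 2 / 5, 3 / 5], [1 / 4, 0, 3 / 4], [1 / 3, 2 / 3, 0]]
        )
        assert sm.nodes == ["a", "b", "c"]
        np.testing.assert_allclose(sm.matrix, expected, atol=1e-15)

    def test_rows_sum_to_one_on_random_instances(self):
        rng = np.random.default_rng(0)
        for i in range(50):
            g = simulate_network(int(rng.integers(3, 40)), 4, seed=int(rng.integers(2**31)))
            e = pd.Series(rng.uniform(0.1, 10, g.number_of_nodes()), index=sorted(g.nodes()))
            sm = stochastic_matrix(g, e)
            np.testing.assert_allclose(sm.matrix.sum(axis=1), 1.0, atol=1e-12)
            # support exactly the adjacency
            adj = nx.to_numpy_array(g, nodelist=sm.nodes) > 0
            assert ((sm.matrix > 0) == adj).all()

    def test_non_positive_expression_rejected(self, triangle):
        with pytest.raises(ValidationError):
            stochastic_matrix(triangle, pd.Series({"a": 1.0, "b": 0.0, "c": 2.0}))


class TestLocalEntropies:
    def test_degree_one_node_deterministic(self):
        path = nx.Graph([("a", "b"), ("b", "c")])
        sm = stochastic_matrix(path, uniform_expr(path))
        s = local_entropies(sm)
        assert s[sm.nodes.index("a")] == 0.0

    def test_uniform_row_maximum_entropy(self):
        k5 = nx.complete_graph(5)
        sm = stochastic_matrix(k5, pd.Series(1.0, index=sorted(k5.nodes())))
        np.testing.assert_allclose(local_entropies(sm), math.log(4))

    def test_worked_example(self):
        s = local_entropies(np.array([[0.4, 0.6]]))
        assert s[0] == pytest.approx(0.67301, abs=1e-5)


class TestStationary:
    def test_uniform_triangle(self, triangle):
        pi = stationary_distribution(triangle, uniform_expr(triangle))
        np.testing.assert_allclose(pi, 1 / 3)

    def test_mass_action_triangle_closed_form_and_fixed_point(self, triangle, triangle_expression):
        pi = stationary_distribution(triangle, triangle_expression)
        np.testing.assert_allclose(pi, [5 / 22, 8 / 22, 9 / 22], atol=1e-12)
        sm = stochastic_matrix(triangle, triangle_expression)
        np.testing.assert_allclose(pi @ sm.matrix, pi, atol=1e-12)

    def test_detailed_balance_on_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            g = simulate_network(int(rng.integers(4, 30)), 4, seed=int(rng.integers(2**31)))
            e = pd.Series(rng.uniform(0.1, 5, g.number_of_nodes()), index=sorted(g.nodes()))
            pi = stationary_distribution(g, e)
            p = stochastic_matrix(g, e).matrix
            np.testing.assert_allclose(pi[:, None] * p, (pi[:, None] * p).T, atol=1e-12)
            assert pi.sum() == pytest.approx(1.0) and (pi > 0).all()

    def test_disconnected_network_rejected(self):
        g = nx.Graph([("a", "b"), ("c", "d")])
        with pytest.raises(ValidationError):
            stationary_distribution(g, pd.Series(1.0, index=["a", "b", "c", "d"]))


class TestEntropyRate:
    def test_regular_graphs_give_log_degree(self):
        ring = nx.relabel_nodes(nx.cycle_graph(10), lambda i: f"n{i}")
        sm = stochastic_matrix(ring, uniform_expr(ring))
        sr = entropy_rate(stationary_distribution(ring, uniform_expr(ring)), local_entropies(sm))
        assert sr == pytest.approx(math.log(2), abs=1e-12)
        k5 = nx.relabel_nodes(nx.complete_graph(5), lambda i: f"n{i}")
        sm5 = stochastic_matrix(k5, uniform_expr(k5))
        sr5 = entropy_rate(stationary_distribution(k5, uniform_expr(k5)), local_entropies(sm5))
        assert sr5 == pytest.approx(math.log(4), abs=1e-12)

    def test_triangle_against_bruteforce_oracle(self, triangle, triangle_expression):
        sr_oracle, _, _ = entropy_rate_bruteforce(triangle, triangle_expression)
        pi = stationary_distribution(triangle, triangle_expression)
        s = local_entropies(stochastic_matrix(triangle, triangle_expression))
        assert entropy_rate(pi, s) == pytest.approx(sr_oracle, abs=1e-10)
        assert entropy_rate(pi, s) == pytest.approx(0.617835, abs=1e-6)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            entropy_rate([0.5, 0.5], [1.0])

    def test_local_entropy_bounds_and_rate_bound(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            g = simulate_network(int(rng.integers(4, 30)), 4, seed=int(rng.integers(2**31)))
            e = pd.Series(rng.uniform(0.1, 5, g.number_of_nodes()), index=sorted(g.nodes()))
            sm = stochastic_matrix(g, e)
            s = local_entropies(sm)
            degrees = np.array([g.degree(n) for n in sm.nodes])
            assert (s >= -1e-12).all()
            assert (s <= np.log(degrees) + 1e-12).all()
            sr = entropy_rate(stationary_distribution(g, e), s)
            assert sr <= s.max() + 1e-12


@pytest.fixture(scope="module")
def sim():
    cfg = SimulationConfig(
        n_genes=300,
        group_sizes={"dux4_up": 30, "dux4_down": 30},
        seed=6,
    )
    matrix, meta, _ = simulate_experiment(cfg)
    network = simulate_network(120, 6, seed=8, gene_ids=matrix.gene_ids)
    return matrix, meta, network


class TestPerSample:

    def test_identical_samples_identical_rate(self, sim):
        matrix, _, network = sim
        df = matrix.data[["control_r1", "control_r1"]].copy()
        df.columns = ["s1", "s2"]
        summary, _ = entropy_per_sample(ExpressionMatrix(df), network)
        assert summary.loc["s1", "entropy_rate"] == summary.loc["s2", "entropy_rate"]

    def test_gene_order_invariance(self, sim):
        matrix, _, network = sim
        shuffled = ExpressionMatrix(matrix.data.sample(frac=1, random_state=0))
        s1, _ = entropy_per_sample(matrix, network)
        s2, _ = entropy_per_sample(shuffled, network)
        np.testing.assert_allclose(s1["entropy_rate"], s2["entropy_rate"], atol=1e-12)

    def test_flattened_profile_raises_entropy(self, sim):
        """Shrinking a sample's expression toward its mean (a flatter, more
        promiscuous profile) must increase its entropy rate."""
        matrix, _, network = sim
        df = matrix.data[["control_r1"]].copy()
        flat = 0.1 * df + 0.9 * df.mean().iloc[0]
        flat.columns = ["flat"]
        both = pd.concat([df, flat], axis=1)
        summary, _ = entropy_per_sample(ExpressionMatrix(both), network)
        assert summary.loc["flat", "entropy_rate"] > summary.loc["control_r1", "entropy_rate"]

    def test_scale_invariance(self, sim):
        matrix, _, network = sim
        base, _ = entropy_per_sample(matrix, network)
        for c in (0.1, 10.0, 1000.0):
            scaled, _ = entropy_per_sample(ExpressionMatrix(matrix.data * c), network)
            np.testing.assert_allclose(
                scaled["entropy_rate"], base["entropy_rate"], rtol=0, atol=1e-12
            )

    def test_bits_and_normalisation(self, sim):
        matrix, _, network = sim
        nats, _ = entropy_per_sample(matrix, network)
        bits, _ = entropy_per_sample(matrix, network, units="bits")
        np.testing.assert_allclose(
            bits["entropy_rate"], nats["entropy_rate"] / math.log(2), atol=1e-12
        )
        normed, _ = entropy_per_sample(matrix, network, normalize=True)
        # max-entropy walk on the same topology bounds the normalised rate
        assert (normed["entropy_rate"] <= 1 + 1e-12).all()

    def test_epsilon_floor_applied(self, sim, caplog):
        matrix, _, network = sim
        df = matrix.data.copy()
        df.iloc[0, 0] = -1.0
        with caplog.at_level("INFO", logger="duxent"):
            summary, _ = entropy_per_sample(ExpressionMatrix(df), network)
        assert np.isfinite(summary["entropy_rate"]).all()
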