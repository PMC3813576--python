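import math

import numpy as np
import pytest

from pollindep.io import CensusRecord
from pollindep.network import (
    BipartiteNetwork,
    build_network,
    closeness_centrality,
    descriptors,
    interaction_diversity,
    linkage_level,
    project_unipartite,
    specialization_table,
)
from tests.conftest import random_network


def net_from(weights, plants=None, pollinators=None):
    weights = np.asarray(weights, float)
    p, a = weights.shape
    return BipartiteNetwork(
        plants or [f"P{i}" for i in range(p)],
        pollinators or [f"I{j}" for j in range(a)],
        weights,
    )


class TestBuildNetwork:
    def test_single_census_frequency(self):
        net = build_network([CensusRecord("A", "x", 6, 2, 3)])
        assert net.weights[0, 0] == pytest.approx(1.0)  # 6 / (2*3)

    def test_pooled_ratio_over_censuses(self):
        # oracle: total visits / total flower-minutes = 6 / (2*3 + 1*3)
        net = build_network(
            [CensusRecord("A", "x", 6, 2, 3), CensusRecord("A", "x", 0, 1, 3)]
        )
        assert net.weights[0, 0] == pytest.approx(6 / 9)

    def test_first_appearance_label_order(self, small_census):
        net = build_network(small_census)
        assert net.plant_labels == ["A", "B"]
        assert net.pollinator_labels == ["x", "y", "z"]
        assert net.weights.shape == (2, 3)

    def test_record_order_invariance(self, small_census):
        a = build_network(small_census)
        b = build_network(small_census[::-1])
        rows = [b.plant_labels.index(p) for p in a.plant_labels]
        cols = [b.pollinator_labels.index(q) for q in a.pollinator_labels]
        np.testing.assert_allclose(a.weights, b.weights[np.ix_(rows, cols)])

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="no interactions"):
            build_network([CensusRecord("A", "x", 0, 2, 3)])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            build_network([])


class TestDescriptors:
    def test_counts_and_mean_links(self):
        net = net_from([[0.5, 0.0, 0.1], [0.0, 0.2, 0.0]])
        d = descriptors(net)
        assert d.S == 6
        assert d.links_total == 3
        assert d.I == pytest.approx(3 / 5)
        assert d.I * (net.n_plants + net.n_pollinators) == pytest.approx(d.links_total)

    def test_uniform_weights_maximal_evenness(self):
        net = net_from(np.full((3, 4), 0.25))
        d = descriptors(net)
        assert d.H2 == pytest.approx(math.log(12))
        assert d.E2 == pytest.approx(1.0)

    def test_single_link_has_no_evenness(self):
        d = descriptors(net_from([[1.0, 0.0]]))
        assert d.E2 is None

    def test_evenness_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            d = descriptors(random_network(rng, 5, 8))
            assert 0 <= d.E2 <= 1 + 1e-12
            assert d.S >= d.links_total


class TestPlantIndices:
    def test_single_partner(self):
        net = net_from([[0.7, 0.0], [0.1, 0.4]])
        assert linkage_level(net, "P0") == 1
        assert interaction_diversity(net, "P0") == 0.0

    def test_equal_partners_log_k(self):
        net = net_from([[0.3, 0.3, 0.3]])
        assert interaction_diversity(net, "P0") == pytest.approx(math.log(3))

    def test_shannon_direct_summation_oracle(self):
        # -(0.5 ln 0.5 + 0.25 ln 0.25 + 0.25 ln 0.25), frozen
        net = net_from([[0.5, 0.25, 0.25]])
        assert interaction_diversity(net, "P0") == pytest.approx(
            1.0397207708399179, abs=1e-12
        )

    def test_shannon_vs_oracle_random(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            net = random_network(rng, 4, 7)
            for plant in net.plant_labels:
                row = net.weights[net.plant_index(plant)]
                p = row[row > 0] / row.sum()
                expected = -sum(pi * math.log(pi) for pi in p)
                assert interaction_diversity(net, plant) == pytest.approx(
                    expected, abs=1e-10
                )

    def test_jensen_bound(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            net = random_network(rng, 6, 9)
            for plant in net.plant_labels:
                h = interaction_diversity(net, plant)
                level = linkage_level(net, plant)
                assert h <= math.log(level) + 1e-12

    def test_zero_row(self, caplog):
        net = BipartiteNetwork(["A", "B"], ["x"], [[0.0], [1.0]])
        with caplog.at_level("WARNING"):
            assert linkage_level(net, "A") == 0
        assert "no interactions" in caplog.text
        with pytest.raises(ValueError, match="zero total"):
            interaction_diversity(net, "A")

    def test_unknown_plant(self):
        net = net_from([[1.0]])
        with pytest.raises(KeyError):
            linkage_level(net, "nope")


class TestProjection:
    def test_shared_pollinator_links(self):
        proj = project_unipartite(net_from([[1, 0], [1, 0]]))
        assert proj.adjacency[0, 1]

    def test_disjoint_pollinators_no_link(self):
        proj = project_unipartite(net_from([[1, 0], [0, 1]]))
        assert not proj.adjacency[0, 1]

    def test_path_topology(self):
        # A,B share x; B,C share y -> path A-B-C (set-intersection oracle)
        proj = project_unipartite(net_from([[1, 0], [1, 1], [0, 1]], ["A", "B", "C"]))
        expected = np.array(
            [[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=bool
        )
        np.testing.assert_array_equal(proj.adjacency, expected)


class TestCloseness:
    def test_triangle_is_central(self):
        proj = project_unipartite(net_from([[1], [1], [1]], ["A", "B", "C"]))
        assert closeness_centrality(proj, "A") == pytest.approx(1.0)

    def test_path_endpoint(self):
        proj = project_unipartite(net_from([[1, 0], [1, 1], [0, 1]], ["A", "B", "C"]))
        assert closeness_centrality(proj, "A") == pytest.approx(2 / 3)
        assert closeness_centrality(proj, "B") == pytest.approx(1.0)

    def test_disconnected_graph_convention(self):
        weights = np.zeros((5, 6))
        weights[:4, 0] = 1  # four plants share a pollinator
        weights[4, 5] = 1  # fifth is isolated in the projection
        proj = project_unipartite(net_from(weights))
        # any node with an unreachable peer gets 0 — including the well
        # connected ones, since the isolated plant is unreachable from them
        assert closeness_centrality(proj, "P4") == 0.0
        assert closeness_centrality(proj, "P0") == 0.0

    def test_single_plant_undefined(self):
        proj = project_unipartite(net_from([[1.0]]))
        with pytest.raises(ValueError):
            closeness_centrality(proj, "P0")

    @pytest.mark.parametrize("seed", range(20))
    def test_brute_force_oracle(self, seed):
        """All-pairs Floyd-Warshall oracle on random graphs of <= 12 nodes."""
        rng = np.random.default_rng(seed)
        p = int(rng.integers(2, 13))
        adj = rng.uniform(size=(p, p)) < 0.3
        adj = adj | adj.T
        np.fill_diagonal(adj, False)
        from pollindep.network import UnipartiteProjection

        proj = UnipartiteProjection([f"P{i}" for i in range(p)], adj)
        dist = np.where(adj, 1.0, np.inf)
        np.fill_diagonal(dist, 0.0)
        for k in range(p):
            dist = np.minimum(dist, dist[:, [k]] + dist[[k], :])
        for i in range(p):
            total = dist[i].sum() - dist[i, i]
            expected = 0.0 if np.isinf(total) else (p - 1) / total
            assert closeness_centrality(proj, f"P{i}") == pytest.approx(
                expected, abs=1e-10
            )


def test_specialization_table(small_census):
    net = build_network(small_census)
    table = specialization_table(net)
    assert list(table["plant_id"]) == ["A", "B"]
    assert list(table["L"]) == [2, 2]
    assert (table["CC"] == 1.0).all()  # A and B share pollinator y
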