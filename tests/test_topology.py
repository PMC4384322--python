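"""Network topology: degrees, node classes, power-law fit, hub robustness."""

import math
import random

import networkx as nx
import numpy as np
import pytest

from mossnet.interolog import deduplicate
from mossnet.records import EvidenceRecord, RawPrediction
from mossnet.topology import (
    binned_distribution,
    build_network,
    class_histogram,
    classify_degree,
    classify_nodes,
    degree_table,
    fit_power_law,
    hub_deletion_robustness,
    top_hubs,
)


def interactions(pairs):
    return deduplicate([
        RawPrediction(tuple(sorted(p)), EvidenceRecord("human", "Y2H", f"pm{i}", "DIP", p))
        for i, p in enumerate(pairs)
    ])


class TestBuildNetwork:
    def test_nodes_and_edges(self):
        g = build_network(interactions([("a", "b"), ("b", "c"), ("c", "d")]))
        assert g.number_of_nodes() == 4 and g.number_of_edges() == 3

    def test_empty(self):
        g = build_network([])
        assert g.number_of_nodes() == 0

    def test_node_count_equals_endpoint_set(self):
        rng = random.Random(31)
        pairs = [(f"m{rng.randrange(30)}", f"m{rng.randrange(30)}") for _ in range(80)]
        g = build_network(interactions(pairs))
        assert set(g.nodes()) == {p for pair in pairs for p in pair}


class TestDegrees:
    def test_path_graph(self):
        g = build_network(interactions([("A", "B"), ("B", "C")]))
        assert degree_table(g) == {"A": 1, "B": 2, "C": 1}

    def test_self_loop_counts_one_by_default(self):
        g = build_network(interactions([("A", "A")]))
        assert degree_table(g) == {"A": 1}
        assert degree_table(g, count_self_loops=False) == {"A": 0}

    def test_degrees_match_incidence_count(self):
        g = nx.gnm_random_graph(25, 60, seed=4)
        table = degree_table(g)
        for n in g:
            assert table[n] == sum(1 for e in g.edges() if n in e)

    def test_degree_sum_identity(self, world):
        from mossnet.topology import build_network as bn
        g = bn(world["unique"])
        loops = nx.number_of_selfloops(g)
        assert sum(degree_table(g).values()) == 2 * (g.number_of_edges() - loops) + loops


class TestClasses:
    @pytest.mark.parametrize("degree,cls", [
        (1, "free_end"), (2, "pipe"), (3, "minor_hub"), (5, "minor_hub"),
        (6, "small_hub"), (10, "small_hub"), (11, "medium_hub"), (30, "medium_hub"),
        (50, "medium_hub"), (51, "major_hub"), (75, "major_hub"), (100, "major_hub"),
        (101, "super_hub"),
    ])
    def test_degree_class_boundaries(self, degree, cls):
        assert classify_degree(degree) == cls

    def test_degree_zero_excluded_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            classes = classify_nodes({"a": 0, "b": 3})
        assert classes == {"b": "minor_hub"}
        assert any("degree 0" in r.message for r in caplog.records)

    def test_histogram_sums_to_node_count(self):
        rng = random.Random(41)
        degrees = {f"n{i}": rng.randrange(1, 200) for i in range(300)}
        hist = class_histogram(classify_nodes(degrees))
        assert sum(hist.values()) == 300


class TestBinnedDistribution:
    def test_width_ten(self):
        dist = binned_distribution({"a": 1, "b": 2, "c": 11}, 10)
        assert dist == [(1, 10, 2), (11, 20, 1)]

    def test_width_one_is_raw_histogram(self):
        dist = binned_distribution({"a": 1, "b": 1, "c": 3}, 1)
        assert dist == [(1, 1, 2), (2, 2, 0), (3, 3, 1)]

    def test_counts_conserve_nodes(self):
        rng = random.Random(43)
        degrees = {f"n{i}": rng.randrange(1, 95) for i in range(200)}
        dist = binned_distribution(degrees, 7)
        assert sum(c for _, _, c in dist) == 200


class TestPowerLawFit:
    def test_recovers_planted_exponent_exactly(self):
        # counts constructed as C * mid^-2 at the bin midpoints
        dist = []
        for i in range(8):
            lo, hi = i * 10 + 1, (i + 1) * 10
            mid = (lo + hi) / 2
            dist.append((lo, hi, 1e6 * mid ** -2.0))
        fit = fit_power_law(dist)
        assert math.isclose(fit.slope, -2.0, abs_tol=1e-9)
        assert math.isclose(fit.r_squared, 1.0, abs_tol=1e-12)

    def test_flat_counts_give_slope_zero(self):
        dist = [(i * 10 + 1, (i + 1) * 10, 50) for i in range(5)]
        fit = fit_power_law(dist)
        assert math.isclose(fit.slope, 0.0, abs_tol=1e-12)

    def test_exponential_decay_fits_worse_than_power_law(self):
        bins = [(i * 10 + 1, (i + 1) * 10) for i in range(8)]
        power = [(lo, hi, 1e6 * ((lo + hi) / 2) ** -2.0) for lo, hi in bins]
        expo = [(lo, hi, 1e6 * np.exp(-0.15 * (lo + hi) / 2)) for lo, hi in bins]
        assert fit_power_law(expo).r_squared < fit_power_law(power).r_squared

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError, match="3 nonzero bins"):
            fit_power_law([(1, 10, 5), (11, 20, 2)])

    def test_scale_free_fixture_has_negative_slope(self):
        from mossnet.fixtures import generate_scale_free_graph
        g = generate_scale_free_graph(400, 3, seed=2)
        fit = fit_power_law(binned_distribution(degree_table(g), 5))
        assert fit.slope < -0.5


class TestHubs:
    def test_star_center_is_top_hub(self):
        g = nx.star_graph(5)
        assert top_hubs(g, 1) == [0]

    def test_tie_broken_lexicographically(self):
        g = nx.Graph([("b", "x"), ("b", "y"), ("b", "z"), ("a", "x"), ("a", "y"), ("a", "z")])
        assert top_hubs(g, 2) == ["a", "b"]

    def test_matches_brute_force_sort(self):
        g = nx.gnm_random_graph(40, 120, seed=8)
        g = nx.relabel_nodes(g, {n: f"n{n:02d}" for n in g})
        degrees = degree_table(g)
        expected = sorted(degrees, key=lambda n: (-degrees[n], n))[:5]
        assert top_hubs(g, 5) == expected

    def test_k_beyond_node_count_returns_all(self):
        g = nx.path_graph(3)
        assert len(top_hubs(g, 10)) == 3


class TestRobustness:
    def test_star_shatters(self):
        g = nx.star_graph(6)  # center 0 plus 6 leaves
        rep = hub_deletion_robustness(g, 1)
        assert rep.removed == [0]
        assert rep.n_components_after == 6
        assert rep.largest_component_after == 1

    def test_clique_stays_connected(self):
        g = nx.complete_graph(10)
        rep = hub_deletion_robustness(g, 2)
        assert rep.n_components_after == 1
        assert rep.largest_component_after == 8

    def test_stratus_fixture_retains_giant_component(self):
        # dense overlapping neighborhoods: hub loss must not fragment the core
        from mossnet.fixtures import generate_scale_free_graph
        g = generate_scale_free_graph(300, 4, seed=5)
        rep = hub_deletion_robustness(g, 20)
        remaining = g.number_of_nodes() - 20
        assert rep.largest_component_after > 0.95 * remaining

    def test_largest_component_never_grows(self):
        g = nx.gnm_random_graph(50, 80, seed=12)
        rep = hub_deletion_robustness(g, 5)
        assert rep.largest_component_after <= rep.largest_component_before

    def test_k_must_leave_nodes(self):
        with pytest.raises(ValueError):
            hub_deletion_robustness(nx.path_graph(3), 3)
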