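"""Node labeling, mixed-node statistics and cluster extraction."""
from collections import Counter

import numpy as np
import pytest

from somscreen import (
    MouseClass,
    TrainingParams,
    assign_measurements,
    extract_clusters,
    label_nodes,
    mixed_node_stats,
    render_map,
    render_text,
)
from somscreen.maps import NodeAssignment, between_group_mixed
from somscreen.som import SOMap
from somscreen import hexgrid


def make_assignment(side, node_classes, node_mice=None):
    """Build a NodeAssignment from {coord: {code: count}} dictionaries."""
    n = side * side
    indices = [[] for _ in range(n)]
    class_counts = [Counter() for _ in range(n)]
    mouse_counts = [Counter() for _ in range(n)]
    row = 0
    for coord, counts in node_classes.items():
        node = hexgrid.node_index(coord, side)
        for code, k in counts.items():
            class_counts[node][code] += k
            indices[node].extend(range(row, row + k))
            row += k
    if node_mice:
        for coord, counts in node_mice.items():
            node = hexgrid.node_index(coord, side)
            for mouse, k in counts.items():
                mouse_counts[node][mouse] += k
    return NodeAssignment(side, indices, class_counts, mouse_counts)


def make_som(side, dim=2, seed=0):
    rng = np.random.default_rng(seed)
    return SOMap(side=side, weights=rng.random((side * side, dim)), seed=seed,
                 params=TrainingParams(), trained=True)


class TestAssignment:
    def test_counts_are_conserved(self, small_data, fast_params):
        from somscreen import train
        from somscreen.dataset import normalize_minmax, subset
        ds, _ = small_data
        sub = normalize_minmax(subset(ds))
        som = train(sub.values, 4, params=fast_params, seed=2)
        a = assign_measurements(som, sub.values, sub.class_codes, sub.mouse_ids)
        assert a.n_measurements == sub.n_measurements
        assert sum(sum(c.values()) for c in a.class_counts) == sub.n_measurements
        lmap = label_nodes(a)
        assert int(lmap.total_count.sum()) == sub.n_measurements
        for node in range(16):
            assert sum(a.class_counts[node].values()) == lmap.total_count[node]

    def test_samples_on_node_weights_map_to_their_own_nodes(self):
        som = make_som(2, dim=3)
        a = assign_measurements(som, som.weights, ["c-CS-s"] * 4)
        assert [len(ix) for ix in a.indices] == [1, 1, 1, 1]


class TestLabeling:
    def test_majority_and_mixed_flag(self):
        lmap = label_nodes(make_assignment(2, {(0, 0): {"c-CS-s": 10, "c-SC-s": 5}}))
        node = hexgrid.node_index((0, 0), 2)
        assert lmap.majority_class[node] == "c-CS-s"
        assert lmap.is_mixed[node]
        assert not lmap.ties

    def test_tie_breaks_lexicographically_and_is_recorded(self):
        lmap = label_nodes(make_assignment(2, {(0, 0): {"c-SC-s": 7, "c-CS-s": 7}}))
        node = hexgrid.node_index((0, 0), 2)
        assert lmap.majority_class[node] == "c-CS-s"
        assert lmap.ties == [(node, ("c-CS-s", "c-SC-s"))]

    def test_empty_node_is_unlabeled_and_not_mixed(self):
        lmap = label_nodes(make_assignment(2, {}))
        assert lmap.majority_class == [None] * 4
        assert not lmap.is_mixed.any()


class TestMixedStats:
    def test_no_mixing(self):
        lmap = label_nodes(make_assignment(2, {(0, 0): {"c-CS-s": 9}}))
        assert mixed_node_stats(lmap) == (0, 0)

    def test_single_mixed_node_counts_all_its_measurements(self):
        lmap = label_nodes(make_assignment(2, {(0, 0): {"c-CS-s": 8, "c-CS-m": 7}}))
        assert mixed_node_stats(lmap) == (1, 15)

    def test_within_class_restriction(self):
        lmap = label_nodes(make_assignment(
            2, {(0, 0): {"c-CS-s": 5, "c-SC-s": 5},
                (0, 1): {"c-CS-s": 4, "c-CS-m": 2}}))
        assert mixed_node_stats(lmap) == (2, 16)
        # only CS-s vs CS-m mixing counts here
        assert mixed_node_stats(lmap, within_classes=["c-CS-s", "c-CS-m"]) == (1, 6)

    def test_between_group_mixing(self):
        lmap = label_nodes(make_assignment(
            2, {(0, 0): {"c-CS-s": 5, "c-CS-m": 5},
                (0, 1): {"c-CS-s": 4, "c-SC-m": 2}}))
        n, meas = between_group_mixed(lmap, ["c-CS-s", "c-CS-m"],
                                      ["c-SC-s", "c-SC-m"])
        assert (n, meas) == (1, 6)

    def test_unknown_class_rejected(self):
        lmap = label_nodes(make_assignment(2, {}))
        with pytest.raises(ValueError):
            mixed_node_stats(lmap, within_classes=["nope"])


class TestClusterExtraction:
    def test_two_adjacent_pure_nodes_form_a_cluster(self):
        lmap = label_nodes(make_assignment(
            3, {(0, 0): {"c-CS-s": 10}, (0, 1): {"c-CS-s": 5}}))
        clusters = extract_clusters(lmap)
        assert len(clusters) == 1
        cl = clusters[0]
        assert cl.mouse_class == MouseClass.from_code("c-CS-s")
        assert cl.nodes == {(0, 0), (0, 1)}
        assert cl.n_measurements == 15

    @pytest.mark.parametrize("count,accepted", [(12, True), (11, False)])
    def test_singleton_mouse_dominance_boundary(self, count, accepted):
        lmap = label_nodes(make_assignment(
            3, {(1, 1): {"c-CS-s": count + 2}},
            node_mice={(1, 1): {"m1": count, "m2": 2}}))
        clusters = extract_clusters(lmap, nominal_replicates=15)
        assert bool(clusters) is accepted

    def test_mixed_nodes_never_join_clusters(self):
        lmap = label_nodes(make_assignment(
            3, {(0, 0): {"c-CS-s": 10}, (0, 1): {"c-CS-s": 5, "c-SC-s": 1},
                (1, 0): {"c-CS-s": 9}}))
        clusters = extract_clusters(lmap)
        assert len(clusters) == 1
        assert clusters[0].nodes == {(0, 0), (1, 0)}

    def test_matches_bruteforce_connected_components(self):
        # randomized labeled maps vs an independent BFS oracle built on the
        # unit-distance embedding adjacency
        rng = np.random.default_rng(5)
        codes = ["c-CS-s", "c-SC-s", "t-CS-m"]
        for side in (3, 4):
            pos = hexgrid.embedding(side)
            for _ in range(60):
                node_classes = {}
                for r in range(side):
                    for c in range(side):
                        k = rng.integers(0, 4)
                        if k == 3:
                            continue  # empty node
                        node_classes[(r, c)] = {codes[k]: 15}
                lmap = label_nodes(make_assignment(side, node_classes))
                got = {(cl.mouse_class.code, frozenset(cl.nodes))
                       for cl in extract_clusters(lmap)
                       if len(cl.nodes) >= 2}
                # oracle: exhaustive BFS over same-class nodes
                expected = set()
                seen = set()
                for start, counts in node_classes.items():
                    if start in seen:
                        continue
                    code = next(iter(counts))
                    comp, frontier = {start}, [start]
                    while frontier:
                        cur = frontier.pop()
                        i = hexgrid.node_index(cur, side)
                        for other in node_classes:
                            if other in comp or node_classes[other] != {code: 15}:
                                continue
                            j = hexgrid.node_index(other, side)
                            if abs(np.linalg.norm(pos[i] - pos[j]) - 1) < 1e-9:
                                comp.add(other)
                                frontier.append(other)
                    seen |= comp
                    if len(comp) >= 2:
                        expected.add((code, frozenset(comp)))
                assert got == expected

    def test_cluster_invariants_on_trained_map(self, small_data, fast_params):
        from somscreen import train
        from somscreen.dataset import normalize_minmax, subset
        ds, _ = small_data
        sub = normalize_minmax(subset(ds, classes=["c-CS-s", "t-CS-s"]))
        som = train(sub.values, 3, params=fast_params, seed=0)
        lmap = label_nodes(assign_measurements(som, sub.values, sub.class_codes,
                                               sub.mouse_ids))
        clusters = extract_clusters(lmap, nominal_replicates=6)
        all_nodes = [n for cl in clusters for n in cl.nodes]
        assert len(all_nodes) == len(set(all_nodes))  # pairwise disjoint
        for cl in clusters:
            for coord in cl.nodes:
                node = hexgrid.node_index(coord, 3)
                assert set(lmap.assignment.class_counts[node]) == {cl.mouse_class.code}


class TestRendering:
    def test_empty_map_renders_placeholder_grid(self):
        text = render_text(label_nodes(make_assignment(2, {})))
        assert text.count(".") == 4

    def test_rendering_is_deterministic_and_annotated(self, tmp_path):
        lmap = label_nodes(make_assignment(
            2, {(0, 0): {"c-CS-s": 8, "c-SC-s": 7}, (1, 1): {"t-CS-m": 15}}))
        a = render_map(lmap, [], tmp_path / "map.txt")
        b = render_text(lmap)
        assert a == b
        assert "c-CS-s+c-SC-s:15" in a and "t-CS-m:15" in a
        assert (tmp_path / "map.txt").read_text() == a
        assert (tmp_path / "map.png").exists()
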