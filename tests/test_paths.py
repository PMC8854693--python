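"""Optimal paths, pooling, Jaccard ensemble filter, route classification."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from allosnet.contacts import ContactEdge, ContactGraph
from allosnet.paths import (PathEnsemble, PathRecord, classify_routes,
                            edge_length, ensemble_threshold, filter_paths,
                            jaccard_similarity, optimal_paths,
                            pool_unique_paths, route_class_counts)


def make_graph(n_nodes, r_map):
    """ContactGraph + r_map from an {(i, j): r} dict."""
    edges = {tuple(sorted(e)): ContactEdge(1.0, 4.0) for e in r_map}
    return ContactGraph(window_id=0, nodes=list(range(n_nodes)),
                        edges=edges), \
        {tuple(sorted(e)): r for e, r in r_map.items()}


def record(nodes, windows=(0,)):
    return PathRecord(nodes=tuple(nodes), distance=float(len(nodes) - 1),
                      windows=frozenset(windows), source=nodes[0],
                      target=nodes[-1])


def random_ensemble(rng, n_paths, n_nodes=10):
    paths = []
    seen = set()
    while len(paths) < n_paths:
        length = int(rng.integers(3, 6))
        nodes = tuple(rng.choice(n_nodes, size=length, replace=False))
        if nodes in seen:
            continue
        seen.add(nodes)
        windows = frozenset(rng.choice(5, size=int(rng.integers(1, 3)),
                                       replace=False).tolist())
        paths.append(PathRecord(nodes=nodes, distance=float(length),
                                windows=windows, source=nodes[0],
                                target=nodes[-1]))
    return PathEnsemble(paths=paths)


class TestEdgeLength:
    def test_perfect_correlation_zero_length(self):
        assert edge_length(1.0) == 0.0

    def test_inverse_e(self):
        assert edge_length(math.exp(-1)) == pytest.approx(1.0, abs=1e-12)

    def test_monotone(self):
        assert edge_length(0.9) < edge_length(0.3)

    def test_zero_correlation_rejected(self):
        with pytest.raises(ValueError):
            edge_length(0.0)


class TestOptimalPaths:
    def test_line_graph(self):
        g, rmap = make_graph(3, {(0, 1): math.exp(-1), (1, 2): math.exp(-1)})
        (rec,) = optimal_paths(g, rmap, [0], [2])
        assert rec.nodes == (0, 1, 2)
        assert rec.distance == pytest.approx(2.0)

    def test_disconnected_pair_yields_no_record(self):
        g, rmap = make_graph(4, {(0, 1): 0.5, (2, 3): 0.5})
        assert optimal_paths(g, rmap, [0], [3]) == []

    def test_zero_correlation_edge_is_absent(self):
        g, rmap = make_graph(3, {(0, 1): 0.5, (1, 2): 0.0,
                                 (0, 2): 0.001})
        (rec,) = optimal_paths(g, rmap, [0], [2])
        assert rec.nodes == (0, 2)  # long direct edge beats absent edge

    def test_membership_and_disjointness_checked(self):
        g, rmap = make_graph(3, {(0, 1): 0.5})
        with pytest.raises(KeyError):
            optimal_paths(g, rmap, [0], [99])
        with pytest.raises(ValueError):
            optimal_paths(g, rmap, [0], [0])
        with pytest.raises(ValueError):
            optimal_paths(g, rmap, [], [1])

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_exhaustive_enumeration(self, seed):
        """All ≤7-node random graphs: distance equals the minimum over
        every simple path, and the reported sequence attains it."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 8))
        r_map = {}
        for i, j in itertools.combinations(range(n), 2):
            if rng.random() < 0.45:
                r_map[(i, j)] = float(rng.uniform(0.05, 1.0))
        g, rmap = make_graph(n, r_map)
        source, target = 0, n - 1

        nxg = nx.Graph()
        nxg.add_nodes_from(range(n))
        for (i, j), r in rmap.items():
            nxg.add_edge(i, j, length=edge_length(r))
        best = math.inf
        for path in nx.all_simple_paths(nxg, source, target):
            length = sum(nxg[a][b]["length"]
                         for a, b in zip(path, path[1:]))
            best = min(best, length)

        records = optimal_paths(g, rmap, [source], [target])
        if best is math.inf:
            assert records == []
        else:
            (rec,) = records
            assert rec.distance == pytest.approx(best, abs=1e-9)
            walked = sum(edge_length(rmap[tuple(sorted(e))])
                         for e in zip(rec.nodes, rec.nodes[1:]))
            assert walked == pytest.approx(rec.distance, abs=1e-9)

    def test_lexicographic_tie_break(self):
        # two equal-length routes 0-1-3 and 0-2-3 → pick 0-1-3
        r = math.exp(-1)
        g, rmap = make_graph(4, {(0, 1): r, (1, 3): r,
                                 (0, 2): r, (2, 3): r})
        (rec,) = optimal_paths(g, rmap, [0], [3])
        assert rec.nodes == (0, 1, 3)

    def test_subpath_of_optimal_path_is_optimal(self, rng):
        n = 7
        r_map = {}
        for i, j in itertools.combinations(range(n), 2):
            if rng.random() < 0.5:
                r_map[(i, j)] = float(rng.uniform(0.1, 1.0))
        g, rmap = make_graph(n, r_map)
        recs = optimal_paths(g, rmap, [0], [n - 1])
        if not recs:
            pytest.skip("random instance disconnected")
        nodes = recs[0].nodes
        for a in range(len(nodes) - 1):
            for b in range(a + 1, len(nodes)):
                sub = optimal_paths(g, rmap, [nodes[a]], [nodes[b]])
                assert sub[0].nodes == nodes[a:b + 1]


class TestPooling:
    def test_same_sequence_merges_windows(self):
        recs = [record([0, 1, 2], windows=(0,)),
                record([0, 1, 2], windows=(1,)),
                record([0, 3, 2], windows=(1,))]
        ens = pool_unique_paths(recs)
        assert len(ens) == 2
        merged = {p.nodes: p for p in ens.paths}
        assert merged[(0, 1, 2)].windows == frozenset({0, 1})
        assert merged[(0, 3, 2)].windows == frozenset({1})

    def test_pooled_count_matches_hand_enumeration(self):
        # window 0: paths A, B; window 1: paths B, C → 3 unique
        a, b, c = [0, 1, 4], [0, 2, 4], [0, 3, 4]
        ens = pool_unique_paths([record(a, (0,)), record(b, (0,)),
                                 record(b, (1,)), record(c, (1,))])
        assert len(ens) == 3
        assert sum(len(p.windows) > 1 for p in ens.paths) == 1


class TestJaccard:
    def test_identical_paths(self):
        p = record([0, 1, 2, 3])
        assert jaccard_similarity(p, p) == 1.0

    def test_disjoint_paths(self):
        assert jaccard_similarity(record([0, 1, 2]),
                                  record([3, 4, 5])) == 0.0

    def test_worked_overlap(self):
        # edges {ab, bc, cd} vs {bc, cd, de} → 2/4
        a = record([0, 1, 2, 3])
        b = record([1, 2, 3, 4])
        assert jaccard_similarity(a, b) == 0.5

    def test_symmetric_unit_diagonal_matrix(self, rng):
        ens = random_ensemble(rng, 6)
        m = ens.jaccard_matrix()
        np.testing.assert_array_equal(m, m.T)
        np.testing.assert_array_equal(np.diag(m), 1.0)
        assert np.all((m >= 0) & (m <= 1))


def worked_three_paths():
    """Three paths whose pairwise Jaccard similarities are exactly
    0.8, 0.2, 0.2: p1 and p2 share 8 of 10 union edges; p3 shares 2
    edges with each plus one edge outside their union."""
    p1 = record(list(range(10)))              # edges 01..89 (9 edges)
    p2 = record(list(range(9)) + [10])        # shares 01..78, adds 8-10
    p3 = record([11, 0, 1, 2])                # edges {0-11, 01, 12}
    return p1, p2, p3


def brute_force_threshold(ensemble):
    """Scan all candidate thresholds; t* is the largest for which every
    path keeps a neighbour at similarity ≥ t."""
    m = ensemble.jaccard_matrix()
    np.fill_diagonal(m, -1.0)
    candidates = sorted({0.0} | set(m[m >= 0].ravel().tolist()))
    best = None
    for t in candidates:
        if all(m[i].max() >= t for i in range(len(ensemble))):
            best = t
    return best


class TestEnsembleThreshold:
    def test_worked_three_path_example(self):
        # pairwise sims exactly 0.8 / 0.2 / 0.2 → t* = 0.2
        p1, p2, p3 = worked_three_paths()
        ens = PathEnsemble(paths=[p1, p2, p3])
        assert jaccard_similarity(p1, p2) == pytest.approx(0.8, abs=1e-12)
        assert jaccard_similarity(p1, p3) == pytest.approx(0.2, abs=1e-12)
        assert jaccard_similarity(p2, p3) == pytest.approx(0.2, abs=1e-12)
        t = ensemble_threshold(ens)
        assert t == pytest.approx(0.2, abs=1e-12)
        assert t == pytest.approx(brute_force_threshold(ens))

    def test_identical_paths_threshold_one(self):
        ens = PathEnsemble(paths=[record([0, 1, 2], (0,)),
                                  record([0, 1, 2, 3], (1,)),
                                  record([0, 1, 2, 3, 4], (2,))])
        assert 0 < ensemble_threshold(ens) <= 1.0
        same = PathEnsemble(paths=[record([0, 1, 2], (0,)),
                                   record([2, 1, 0], (1,))])
        assert ensemble_threshold(same) == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        ens = random_ensemble(rng, int(rng.integers(3, 9)))
        assert ensemble_threshold(ens) == pytest.approx(
            brute_force_threshold(ens), abs=1e-12)

    def test_threshold_is_attained(self, rng):
        ens = random_ensemble(rng, 7)
        t = ensemble_threshold(ens)
        m = ens.jaccard_matrix()
        np.fill_diagonal(m, -1.0)
        assert all(m[i].max() >= t - 1e-12 for i in range(len(ens)))
        eps = 1e-9
        assert any(m[i].max() < t + eps for i in range(len(ens)))

    def test_single_path_rejected(self):
        with pytest.raises(ValueError):
            ensemble_threshold(PathEnsemble(paths=[record([0, 1])]))


class TestFilterPaths:
    def test_multiwindow_path_always_kept(self):
        lonely = record([0, 1, 2], windows=(0, 1, 2))
        other = record([5, 6, 7], windows=(3,))
        ens = PathEnsemble(paths=[lonely, other])
        kept = filter_paths(ens, 0.6)
        assert lonely in kept.paths
        assert other not in kept.paths

    def test_similarity_rescues_single_window_path(self):
        a = record([0, 1, 2, 3, 4], windows=(0,))
        b = record([0, 1, 2, 3, 5], windows=(1,))   # jaccard 3/5 = 0.6
        ens = PathEnsemble(paths=[a, b])
        assert jaccard_similarity(a, b) == pytest.approx(0.6)
        kept = filter_paths(ens, 0.6)
        assert set(kept.paths) == {a, b}

    def test_dissimilar_single_window_path_removed(self):
        a = record([0, 1, 2, 3, 4], windows=(0,))
        b = record([0, 9, 8, 7, 4], windows=(1,))
        ens = PathEnsemble(paths=[a, b])
        assert jaccard_similarity(a, b) < 0.6
        kept = filter_paths(ens, 0.6)
        assert kept.paths == []

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_direct_rule_evaluation(self, seed):
        rng = np.random.default_rng(1000 + seed)
        ens = random_ensemble(rng, int(rng.integers(4, 10)))
        t = float(rng.uniform(0.0, 1.0))
        kept = filter_paths(ens, t)
        m = ens.jaccard_matrix()
        np.fill_diagonal(m, -1.0)
        expected = [p for i, p in enumerate(ens.paths)
                    if len(p.windows) > 1 or m[i].max() >= t]
        assert kept.paths == expected

    def test_raising_threshold_never_adds_paths(self, rng):
        ens = random_ensemble(rng, 8)
        kept = [set(filter_paths(ens, t).paths)
                for t in (0.0, 0.25, 0.5, 0.75, 1.0)]
        for a, b in zip(kept, kept[1:]):
            assert b <= a

    def test_filtered_is_subset_of_unique(self, rng):
        ens = random_ensemble(rng, 8)
        kept = filter_paths(ens)   # derived threshold
        assert set(kept.paths) <= set(ens.paths)


class TestClassifyRoutes:
    REGIONS = {0: "receptor_R1", 1: "receptor_R1", 2: "receptor_linker",
               3: "receptor_R2", 4: "receptor_R2", 5: "partner",
               6: "partner", 7: "binder"}

    def test_direct_route(self):
        ens = PathEnsemble(paths=[record([0, 1, 2, 3])])
        df = classify_routes(ens, self.REGIONS)
        assert list(df["route_class"]) == ["direct"]
        assert df["trace"][0] == "receptor_R1→receptor_linker→receptor_R2"

    def test_via_partner_route(self):
        ens = PathEnsemble(paths=[record([0, 5, 6, 3])])
        df = classify_routes(ens, self.REGIONS)
        assert list(df["route_class"]) == ["via-partner"]

    def test_counts_and_fractions(self):
        ens = PathEnsemble(paths=[record([0, 1, 2, 3]),
                                  record([1, 2, 3, 4]),
                                  record([0, 5, 6, 3])])
        counts = route_class_counts(ens, self.REGIONS)
        assert counts == {"direct": 2, "via-partner": 1}
        df = classify_routes(ens, self.REGIONS)
        assert df.loc[df["route_class"] == "via-partner",
                      "class_fraction"].iloc[0] == pytest.approx(1 / 3)

    def test_unmapped_node_rejected(self):
        ens = PathEnsemble(paths=[record([0, 99, 3])])
        with pytest.raises(KeyError, match="99"):
            classify_routes(ens, self.REGIONS)
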