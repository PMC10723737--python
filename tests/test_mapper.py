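import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phytomapper import (
    ConfigurationError,
    build_cover,
    mapper_pipeline,
    nerve,
    node_composition,
    parameter_sweep,
    preimage_clusters,
    simplify_graph,
)
from phytomapper.mapper import MapperGraph, MapperNode

from oracles import brute_mapper


class TestCover:
    def test_single_interval_spans_range(self):
        cover = build_cover(-1.0, 3.0, 1, 0.4)
        assert cover.intervals == ((-1.0, 3.0),)

    def test_uniform_overlap_example(self):
        cover = build_cover(0.0, 10.0, 4, 0.5)
        expected = [(0.0, 4.0), (2.0, 6.0), (4.0, 8.0), (6.0, 10.0)]
        for (lo, hi), (elo, ehi) in zip(cover.intervals, expected):
            assert lo == pytest.approx(elo, abs=1e-12)
            assert hi == pytest.approx(ehi, abs=1e-12)
        # union covers [0, 10]; each adjacent overlap is exactly g*L = 2
        for (lo1, hi1), (lo2, hi2) in itertools.pairwise(cover.intervals):
            assert hi1 - lo2 == pytest.approx(2.0, abs=1e-12)

    @given(
        fmin=st.floats(-100, 100),
        width=st.floats(0.1, 100),
        n=st.integers(1, 12),
        g=st.floats(0.0, 0.95),
    )
    def test_closed_form_everywhere(self, fmin, width, n, g):
        fmax = fmin + width
        cover = build_cover(fmin, fmax, n, g)
        L = width / (n - (n - 1) * g)
        for j, (lo, hi) in enumerate(cover.intervals):
            assert lo == pytest.approx(fmin + j * (1 - g) * L, abs=1e-9)
        assert cover.intervals[0][0] == fmin
        assert cover.intervals[-1][1] == fmax
        # consecutive overlaps equal g*L; with g<0.5 non-adjacent are disjoint
        for (lo1, hi1), (lo2, hi2) in itertools.pairwise(cover.intervals):
            assert hi1 - lo2 == pytest.approx(g * L, rel=1e-9, abs=1e-9)

    @pytest.mark.parametrize("args", [(1.0, 0.0, 4, 0.3), (0.0, 1.0, 0, 0.3), (0.0, 1.0, 4, 1.0)])
    def test_invalid_parameters_rejected(self, args):
        with pytest.raises(ConfigurationError):
            build_cover(*args)


def points_1d(values):
    ids = [f"p{i}" for i in range(len(values))]
    X = pd.DataFrame([values], index=["coord"], columns=ids)
    f = pd.Series(values, index=ids, dtype=float)
    return X, f


class TestPreimageClusters:
    def test_two_density_groups(self):
        X, f = points_1d([0.0, 0.1, 0.2, 5.0, 5.1])
        clusters, noise = preimage_clusters(
            X, f, (-1.0, 6.0), eps=0.5, min_samples=2, metric="euclidean"
        )
        assert sorted(map(sorted, clusters)) == [["p0", "p1", "p2"], ["p3", "p4"]]
        assert noise == []

    def test_isolated_point_is_noise(self):
        X, f = points_1d([0.0, 0.1, 9.0])
        clusters, noise = preimage_clusters(
            X, f, (-1.0, 10.0), eps=0.5, min_samples=2, metric="euclidean"
        )
        assert sorted(map(sorted, clusters)) == [["p0", "p1"]]
        assert noise == ["p2"]

    def test_everything_within_eps_is_one_cluster(self):
        X, f = points_1d([0.0, 0.1, 0.2])
        clusters, noise = preimage_clusters(
            X, f, (-1.0, 1.0), eps=10.0, min_samples=1, metric="euclidean"
        )
        assert len(clusters) == 1 and noise == []

    def test_interval_bounds_are_closed(self):
        X, f = points_1d([0.0, 1.0, 2.0])
        clusters, _ = preimage_clusters(
            X, f, (0.0, 1.0), eps=5.0, min_samples=1, metric="euclidean"
        )
        assert sorted(clusters[0]) == ["p0", "p1"]

    def test_empty_preimage_is_not_an_error(self):
        X, f = points_1d([0.0, 1.0])
        assert preimage_clusters(X, f, (5.0, 6.0), 1.0, 1, "euclidean") == ([], [])

    def test_bad_parameters_rejected(self):
        X, f = points_1d([0.0])
        with pytest.raises(ConfigurationError):
            preimage_clusters(X, f, (0, 1), eps=0.0, min_samples=1)
        with pytest.raises(ConfigurationError):
            preimage_clusters(X, f, (0, 1), eps=1.0, min_samples=0)


class TestNerve:
    def test_disjoint_clusters_give_edgeless_graph(self):
        G = nerve([[["a", "b"]], [["c"]]])
        assert len(G.nodes) == 2 and G.edges == []

    def test_shared_sample_edge_and_weight(self):
        G = nerve([[["s1", "s2"]], [["s2", "s3"]], [["s4"]]])
        assert G.edges == [(0, 1, 1)]

    def test_all_pairs_bruteforce(self):
        rng = np.random.default_rng(8)
        samples = [f"s{i}" for i in range(30)]
        clusters_by_interval = [
            [list(rng.choice(samples, size=rng.integers(1, 8), replace=False)) for _ in range(3)]
            for _ in range(4)
        ]
        G = nerve(clusters_by_interval)
        flat = [set(c) for interval in clusters_by_interval for c in interval]
        expected = {
            (i, j, len(flat[i] & flat[j]))
            for i, j in itertools.combinations(range(len(flat)), 2)
            if flat[i] & flat[j]
        }
        assert set(G.edges) == expected


class TestPipeline:
    def test_single_interval_graph_is_edgeless(self):
        X, f = points_1d([0.0, 0.1, 5.0, 5.1])
        G = mapper_pipeline(X, f, 1, 0.0, eps=0.5, min_samples=1,
                            metric="euclidean", transform="none")
        assert len(G.nodes) == 2 and G.edges == []

    def test_deterministic(self, y_cloud):
        pts, ylens, _ = y_cloud
        a = mapper_pipeline(pts, ylens, 4, 0.3, 0.2, 2, "euclidean", "none")
        b = mapper_pipeline(pts, ylens, 4, 0.3, 0.2, 2, "euclidean", "none")
        assert [n.members for n in a.nodes] == [n.members for n in b.nodes]
        assert a.edges == b.edges

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_composition(self, seed):
        rng = np.random.default_rng(200 + seed)
        n_pts = int(rng.integers(10, 60))
        X = pd.DataFrame(
            rng.normal(size=(3, n_pts)), columns=[f"s{i}" for i in range(n_pts)]
        )
        f = pd.Series(X.iloc[0].to_numpy(), index=X.columns)
        n = int(rng.integers(2, 7))
        g = float(rng.uniform(0.1, 0.6))
        eps = float(rng.uniform(0.5, 2.0))
        ms = int(rng.integers(1, 4))
        G = mapper_pipeline(X, f, n, g, eps, ms, metric="euclidean", transform="none")
        nodes, edges, noise = brute_mapper(
            list(X.columns), X.to_numpy(), f.to_numpy(), n, g, eps, ms
        )
        assert [frozenset(nd.members) for nd in G.nodes] == nodes
        assert set((i, j, w) for i, j, w in G.edges) == edges
        assert set(s for _, s in G.noise) == noise

    def test_overlap_region_samples_sit_in_two_nodes(self):
        X, f = points_1d([0.0, 1.0, 2.0, 3.0, 4.0])
        G = mapper_pipeline(X, f, 2, 0.5, eps=10.0, min_samples=1,
                            metric="euclidean", transform="none")
        counts = {}
        for node in G.nodes:
            for s in node.members:
                counts[s] = counts.get(s, 0) + 1
        # lens 4 intervals: (0, 8/3) and (4/3, 4); p1=1.0 and p2=2.0 overlap
        assert counts["p2"] == 2
        assert set(counts) == set(X.columns)


class TestYShape:
    """Planar Y-shaped cloud: canonical branch-detection example."""

    @pytest.mark.parametrize("g", [0.2, 0.3])
    def test_tree_with_single_branch_node(self, y_cloud, g):
        pts, ylens, _ = y_cloud
        G = mapper_pipeline(pts, ylens, 4, g, 0.2, 2, "euclidean", "none").to_networkx()
        assert nx.is_forest(G)
        assert nx.number_connected_components(G) == 1
        degrees = sorted(d for _, d in G.degree())
        assert degrees.count(3) == 1
        assert max(degrees) == 3

    def test_x_lens_gives_different_graph(self, y_cloud):
        pts, ylens, xlens = y_cloud
        Gy = mapper_pipeline(pts, ylens, 4, 0.3, 0.2, 2, "euclidean", "none")
        Gx = mapper_pipeline(pts, xlens, 4, 0.3, 0.2, 2, "euclidean", "none")
        assert (len(Gy.nodes), len(Gy.edges)) != (len(Gx.nodes), len(Gx.edges))


class TestSweep:
    def test_single_cell_grid(self, y_cloud):
        pts, ylens, _ = y_cloud
        sweep = parameter_sweep(pts, ylens, [4], [0.3], 0.2, 2, "euclidean", "none")
        assert len(sweep) == 1
        assert sweep.loc[0, "n_nodes"] == 6

    def test_duplicate_grid_entries_collapsed(self, y_cloud):
        pts, ylens, _ = y_cloud
        sweep = parameter_sweep(pts, ylens, [4, 4], [0.3, 0.3], 0.2, 2, "euclidean", "none")
        assert len(sweep) == 1

    def test_empty_grid_rejected(self, y_cloud):
        pts, ylens, _ = y_cloud
        with pytest.raises(ConfigurationError):
            parameter_sweep(pts, ylens, [], [0.3], 0.2, 2)

    def test_nodes_nondecreasing_in_intervals_for_trivial_clustering(self):
        """With one cluster per interval preimage, node count equals the
        interval count, hence grows with n."""
        X, f = points_1d(list(np.linspace(0, 10, 40)))
        sweep = parameter_sweep(X, f, [2, 4, 6, 8], [0.3], eps=100.0,
                                min_samples=1, metric="euclidean", transform="none")
        nodes = sweep.sort_values("n_intervals")["n_nodes"].to_list()
        assert nodes == [2, 4, 6, 8]


def graph_from_members(member_sets):
    nodes = [
        MapperNode(id=i, interval=i, members=frozenset(m), mean_lens=float(i))
        for i, m in enumerate(member_sets)
    ]
    edges = [
        (a.id, b.id, len(a.members & b.members))
        for a, b in itertools.combinations(nodes, 2)
        if a.members & b.members
    ]
    return MapperGraph(nodes=nodes, edges=edges)


class TestSimplify:
    def test_noop_when_at_or_below_target(self):
        G = graph_from_members([{"a", "b"}, {"c"}])
        S = simplify_graph(G, 2)
        assert sorted(frozenset(n.members) for n in S.nodes) == sorted(
            frozenset(n.members) for n in G.nodes
        )

    def test_greedy_merges_highest_jaccard_pair(self):
        """Chain A-B-C with J(A,B)=0.5 > J(B,C)=0.2: A and B merge first."""
        A, B, C = {"1", "2"}, {"1", "2", "3", "4"}, {"4", "11"}
        S = simplify_graph(graph_from_members([A, B, C]), 2)
        member_sets = sorted((n.members for n in S.nodes), key=len)
        assert member_sets == [frozenset(C), frozenset(A | B)]
        merged = next(n for n in S.nodes if n.members == A | B)
        assert merged.source_ids == (0, 1)

    def test_sample_union_preserved(self, y_cloud):
        pts, ylens, _ = y_cloud
        G = mapper_pipeline(pts, ylens, 6, 0.4, 0.2, 2, "euclidean", "none")
        S = simplify_graph(G, 3)
        assert S.sample_union() == G.sample_union()

    def test_component_count_never_increases(self, y_cloud):
        pts, ylens, _ = y_cloud
        G = mapper_pipeline(pts, ylens, 6, 0.4, 0.2, 2, "euclidean", "none")
        for target in (5, 3, 1):
            assert simplify_graph(G, target).n_components <= G.n_components

    def test_stops_when_no_edges_remain(self):
        G = graph_from_members([{"a"}, {"b"}, {"c"}])
        S = simplify_graph(G, 1)
        assert len(S.nodes) == 3  # disjoint nodes cannot merge


class TestNodeComposition:
    def test_pure_node(self):
        G = graph_from_members([{"a", "b", "c"}])
        meta = pd.DataFrame({"sample": list("abc"), "tissue": ["leaf"] * 3})
        table = node_composition(G, meta, "tissue")
        assert table.loc[0, "leaf"] == 3

    def test_counts_match_bruteforce_tally_and_cover_property(self):
        rng = np.random.default_rng(9)
        samples = [f"s{i}" for i in range(25)]
        meta = pd.DataFrame(
            {"sample": samples, "tissue": rng.choice(["leaf", "root", "seed"], 25)}
        )
        sets = [set(rng.choice(samples, size=8, replace=False)) for _ in range(4)]
        G = graph_from_members(sets)
        table = node_composition(G, meta, "tissue")
        lookup = dict(zip(meta["sample"], meta["tissue"]))
        for node in G.nodes:
            for level in table.columns:
                expected = sum(lookup[s] == level for s in node.members)
                assert table.loc[node.id].get(level, 0) == expected
        assert (table.sum(axis=1) == [len(s) for s in sets]).all()
        assert table.to_numpy().sum() >= len(set().union(*sets))

    def test_missing_sample_rejected(self):
        G = graph_from_members([{"a", "zz"}])
        meta = pd.DataFrame({"sample": ["a"], "tissue": ["leaf"]})
        with pytest.raises(ConfigurationError):
            node_composition(G, meta, "tissue")
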