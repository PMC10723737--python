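"""Mapper graphs over expression samples.

Given samples with a scalar lens value f, the Mapper graph is the
1-dimensional nerve of a cover of the sample set: the lens range is split
into uniformly long, uniformly overlapping intervals; each interval's
preimage is clustered (DBSCAN); each cluster becomes a node; two nodes are
joined by an edge iff they share samples, weighted by the shared count.
Overlapping intervals make shared samples — and hence edges — possible.

Also provided: a hyperparameter sweep summarising graph shape across
(n_intervals, overlap) grids, greedy Jaccard agglomeration into a small
"simplified" graph for interpretation, and per-node factor composition
tables.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

from .errors import ConfigurationError
from .lens import transform_expression

__all__ = [
    "Cover",
    "MapperNode",
    "MapperGraph",
    "build_cover",
    "preimage_clusters",
    "nerve",
    "mapper_pipeline",
    "parameter_sweep",
    "simplify_graph",
    "node_composition",
]


@dataclasses.dataclass(frozen=True)
class Cover:
    """Uniform-length, uniform-overlap interval cover of a lens range."""

    intervals: tuple[tuple[float, float], ...]
    n_intervals: int
    overlap: float

    def __iter__(self):
        return iter(self.intervals)


def build_cover(fmin: float, fmax: float, n: int, g: float) -> Cover:
    """n intervals of common length L = (fmax-fmin) / (n - (n-1) g), adjacent
    pairs overlapping by exactly g*L; interval j starts at
    fmin + j (1-g) L. The last interval ends at fmax."""
    if fmax < fmin:
        raise ConfigurationError("fmax must be >= fmin")
    if n < 1:
        raise ConfigurationError("need at least one interval")
    if not 0.0 <= g < 1.0:
        raise ConfigurationError("overlap fraction must lie in [0, 1)")
    L = (fmax - fmin) / (n - (n - 1) * g)
    step = (1.0 - g) * L
    intervals = [(fmin + j * step, fmin + j * step + L) for j in range(n)]
    lo_last = intervals[-1][0]
    intervals[-1] = (lo_last, fmax)  # pin the endpoint against fp drift
    return Cover(intervals=tuple(intervals), n_intervals=n, overlap=g)


@dataclasses.dataclass(frozen=True)
class MapperNode:
    """One cluster of samples from one cover interval's preimage."""

    id: int
    interval: int
    members: frozenset[str]
    mean_lens: float
    source_ids: tuple[int, ...] = ()  # original node ids, for simplified graphs

    @property
    def size(self) -> int:
        return len(self.members)


@dataclasses.dataclass
class MapperGraph:
    """Nodes plus shared-sample weighted edges (the 1-d nerve)."""

    nodes: list[MapperNode]
    edges: list[tuple[int, int, int]]
    noise: list[tuple[int, str]] = dataclasses.field(default_factory=list)

    def node_by_id(self, node_id: int) -> MapperNode:
        for node in self.nodes:
            if node.id == node_id:
                return node
        raise KeyError(node_id)

    def sample_union(self) -> set[str]:
        out: set[str] = set()
        for node in self.nodes:
            out.update(node.members)
        return out

    def to_networkx(self) -> nx.Graph:
        G = nx.Graph()
        for node in self.nodes:
            G.add_node(
                node.id,
                interval=node.interval,
                size=node.size,
                mean_lens=float(node.mean_lens),
            )
        for i, j, w in self.edges:
            G.add_edge(i, j, weight=int(w))
        return G

    @property
    def n_components(self) -> int:
        return nx.number_connected_components(self.to_networkx())


def _pairwise_distances(X: np.ndarray, metric: str) -> np.ndarray:
    """Distances between matrix *columns*; correlation = 1 - Pearson r."""
    if metric == "euclidean":
        from scipy.spatial.distance import cdist

        return cdist(X.T, X.T, metric="euclidean")
    if metric == "correlation":
        if X.shape[1] == 1:
            return np.zeros((1, 1))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(X.T)
        D = 1.0 - np.nan_to_num(r, nan=0.0)  # constant columns -> distance 1
        np.fill_diagonal(D, 0.0)
        return np.clip(D, 0.0, None)
    raise ConfigurationError(f"unknown metric: {metric!r}")


def preimage_clusters(
    X: pd.DataFrame,
    f: pd.Series,
    interval: tuple[float, float],
    eps: float,
    min_samples: int,
    metric: str = "correlation",
) -> tuple[list[list[str]], list[str]]:
    """DBSCAN-cluster the samples whose lens value falls in the (closed)
    interval. Returns (clusters, noise) as lists of sample ids; an empty
    preimage gives ([], [])."""
    if eps <= 0:
        raise ConfigurationError("eps must be > 0")
    if min_samples < 1:
        raise ConfigurationError("min_samples must be >= 1")
    lo, hi = interval
    ids = [s for s in X.columns if lo <= f[s] <= hi]
    if not ids:
        return [], []
    D = _pairwise_distances(X[ids].to_numpy(dtype=float), metric)
    labels = DBSCAN(eps=eps, min_samples=min_samples, metric="precomputed").fit_predict(D)
    clusters: dict[int, list[str]] = {}
    noise: list[str] = []
    for sid, lab in zip(ids, labels):
        if lab == -1:
            noise.append(sid)
        else:
            clusters.setdefault(int(lab), []).append(sid)
    ordered = [clusters[k] for k in sorted(clusters)]
    return ordered, noise


def nerve(
    clusters_by_interval: Sequence[Sequence[Iterable[str]]],
    lens_values: Mapping[str, float] | None = None,
) -> MapperGraph:
    """The 1-dimensional nerve: a node per cluster, an edge per pair of
    clusters with non-empty sample intersection (weight = shared count)."""
    nodes: list[MapperNode] = []
    nid = 0
    for j, clusters in enumerate(clusters_by_interval):
        for members in clusters:
            mem = frozenset(members)
            if not mem:
                continue
            if lens_values is not None:
                mean_lens = float(np.mean([lens_values[s] for s in mem]))
            else:
                mean_lens = float("nan")
            nodes.append(MapperNode(id=nid, interval=j, members=mem, mean_lens=mean_lens))
            nid += 1
    edges = []
    for a, b in itertools.combinations(nodes, 2):
        shared = a.members & b.members
        if shared:
            edges.append((a.id, b.id, len(shared)))
    return MapperGraph(nodes=nodes, edges=edges)


def mapper_pipeline(
    X: pd.DataFrame,
    f: pd.Series,
    n_intervals: int,
    overlap: float,
    eps: float,
    min_samples: int,
    metric: str = "correlation",
    transform: str = "log2",
) -> MapperGraph:
    """Cover -> per-interval DBSCAN -> nerve, over the full lens range.

    ``transform`` is applied to the expression matrix once before distance
    computation (use ``"none"`` for pre-transformed data or raw point
    clouds). Deterministic: identical inputs give identical graphs.
    """
    f = f.loc[X.columns]
    T = transform_expression(X, transform)
    cover = build_cover(float(f.min()), float(f.max()), n_intervals, overlap)
    clusters_by_interval: list[list[list[str]]] = []
    noise_report: list[tuple[int, str]] = []
    for j, interval in enumerate(cover):
        clusters, noise = preimage_clusters(T, f, interval, eps, min_samples, metric)
        clusters_by_interval.append(clusters)
        noise_report.extend((j, s) for s in noise)
    graph = nerve(clusters_by_interval, lens_values=f)
    graph.noise = noise_report
    return graph


def parameter_sweep(
    X: pd.DataFrame,
    f: pd.Series,
    n_list: Sequence[int],
    g_list: Sequence[float],
    eps: float,
    min_samples: int,
    metric: str = "correlation",
    transform: str = "log2",
) -> pd.DataFrame:
    """Graph-shape summary over an (n_intervals, overlap) grid.

    One row per distinct (n, g): node/edge/component counts plus the
    fraction of covered samples in the largest connected component.
    Duplicate grid entries are collapsed.
    """
    if not n_list or not g_list:
        raise ConfigurationError("empty sweep grid")
    seen: set[tuple[int, float]] = set()
    rows = []
    for n, g in itertools.product(n_list, g_list):
        if (n, g) in seen:
            continue
        seen.add((n, g))
        graph = mapper_pipeline(X, f, n, g, eps, min_samples, metric, transform)
        G = graph.to_networkx()
        covered = graph.sample_union()
        giant = 0.0
        if covered:
            comps = list(nx.connected_components(G))
            by_id = {node.id: node for node in graph.nodes}
            giant = max(
                len(set().union(*(by_id[i].members for i in comp))) for comp in comps
            ) / len(covered)
        rows.append(
            {
                "n_intervals": n,
                "overlap": g,
                "n_nodes": G.number_of_nodes(),
                "n_edges": G.number_of_edges(),
                "n_components": nx.number_connected_components(G) if len(G) else 0,
                "giant_fraction": giant,
            }
        )
    return pd.DataFrame(rows)


def _jaccard(a: frozenset, b: frozenset) -> float:
    return len(a & b) / len(a | b)


def simplify_graph(G: MapperGraph, target_nodes: int) -> MapperGraph:
    """Greedy agglomeration into at most ``target_nodes`` meta-nodes.

    Repeatedly merges the edge-connected pair of (meta-)nodes whose member
    sets have the highest Jaccard similarity — ties broken by the smaller
    sorted id pair — until the target is reached or no edges remain.
    Meta-node members are unions of merged members; meta-edges are re-derived
    from member intersections, so the covered sample set is unchanged and
    the component count never increases.
    """
    if target_nodes < 1:
        raise ConfigurationError("target_nodes must be >= 1")
    members: dict[int, frozenset[str]] = {n.id: n.members for n in G.nodes}
    intervals: dict[int, int] = {n.id: n.interval for n in G.nodes}
    lens_sums: dict[int, tuple[float, int]] = {
        n.id: (n.mean_lens * n.size, n.size) for n in G.nodes
    }
    sources: dict[int, set[int]] = {n.id: set(n.source_ids) or {n.id} for n in G.nodes}

    def connected_pairs():
        ids = sorted(members)
        for a, b in itertools.combinations(ids, 2):
            if members[a] & members[b]:
                yield a, b

    while len(members) > target_nodes:
        best = None
        best_key = None
        for a, b in connected_pairs():
            key = (-_jaccard(members[a], members[b]), a, b)
            if best_key is None or key < best_key:
                best_key = key
                best = (a, b)
        if best is None:
            break
        a, b = best
        members[a] = members[a] | members[b]
        intervals[a] = min(intervals[a], intervals[b])
        sa, na = lens_sums[a]
        sb, nb = lens_sums[b]
        lens_sums[a] = (sa + sb, na + nb)
        sources[a] |= sources[b]
        for d in (members, intervals, lens_sums, sources):
            del d[b]

    order = sorted(members)
    nodes = []
    for new_id, old_id in enumerate(order):
        s, n = lens_sums[old_id]
        nodes.append(
            MapperNode(
                id=new_id,
                interval=intervals[old_id],
                members=members[old_id],
                mean_lens=s / n if n else float("nan"),
                source_ids=tuple(sorted(sources[old_id])),
            )
        )
    edges = []
    for x, y in itertools.combinations(nodes, 2):
        shared = x.members & y.members
        if shared:
            edges.append((x.id, y.id, len(shared)))
    return MapperGraph(nodes=nodes, edges=edges, noise=list(G.noise))


def node_composition(
    G: MapperGraph, meta: pd.DataFrame, factor: str
) -> pd.DataFrame:
    """Per-node counts of a metadata factor (tissue, stress or family).

    Row sums equal node sizes; samples sitting in several nodes are counted
    in each (cover property)."""
    if factor not in meta.columns:
        raise ConfigurationError(f"metadata lacks a {factor!r} column")
    lookup = meta.set_index("sample")[factor]
    rows = {}
    for node in G.nodes:
        missing = [s for s in node.members if s not in lookup.index]
        if missing:
            raise ConfigurationError(f"samples missing from metadata: {sorted(missing)}")
        rows[node.id] = lookup.loc[sorted(node.members)].value_counts().to_dict()
    table = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    table.index.name = "node"
    return table.sort_index()
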