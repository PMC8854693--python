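"""Optimal-path ensembles over the correlation-weighted contact network.

Allosteric communication between a source residue set (e.g. the receptor
lobe a binder grips) and a target set (e.g. the lower-lobe contact
residues) is modelled as shortest paths through the per-window contact
graph with edge length −ln(r_MI): strongly correlated contacts are short,
weakly correlated ones long, and r_MI = 0 contacts are absent.  All-pairs
distances come from the Floyd–Warshall algorithm; paths are reconstructed
deterministically, taking the lexicographically smallest node sequence
among equal-length optima so results are platform independent.

One optimal path per (source, target) pair per window is pooled into an
ensemble of unique paths (uniqueness judged on node sequences).  Noise is
then removed by the ensemble filter: a path is kept if it recurs in more
than one window, or if its maximum Jaccard similarity (on edge sets) to
another path reaches a threshold — either supplied or derived as the
largest value t such that every path still has a neighbour at similarity
≥ t.  Finally paths are classified by the named regions they traverse,
separating direct routes from those detouring through a partner region.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import floyd_warshall

from .contacts import ContactGraph

_REL_TOL = 1e-9


def edge_length(r_mi: float) -> float:
    """Edge length −ln(r_MI); shorter = more correlated.

    Zero-correlation edges are treated as absent, not infinitely long —
    callers must exclude them before asking for a length.
    """
    if not 0.0 < r_mi <= 1.0:
        raise ValueError(f"r_MI must be in (0, 1] for a length, got {r_mi}")
    return -float(np.log(r_mi))


@dataclass(frozen=True)
class PathRecord:
    """One unique optimal path (node sequence from source to target)."""

    nodes: tuple[int, ...]
    distance: float
    windows: frozenset[int]
    source: int
    target: int

    @property
    def edges(self) -> frozenset[tuple[int, int]]:
        return frozenset((min(a, b), max(a, b))
                         for a, b in zip(self.nodes[:-1], self.nodes[1:]))


@dataclass
class PathEnsemble:
    """Unique optimal paths pooled over windows and source/target pairs."""

    paths: list[PathRecord]
    threshold: float | None = None       # derived t*
    applied_threshold: float | None = None

    def __len__(self) -> int:
        return len(self.paths)

    def jaccard_matrix(self) -> np.ndarray:
        n = len(self.paths)
        m = np.eye(n)
        for a in range(n):
            for b in range(a + 1, n):
                m[a, b] = m[b, a] = jaccard_similarity(self.paths[a],
                                                       self.paths[b])
        return m

    def to_dataframe(self) -> pd.DataFrame:
        rows = [{"source": p.source, "target": p.target,
                 "nodes": "-".join(map(str, p.nodes)),
                 "distance": p.distance,
                 "n_windows": len(p.windows),
                 "windows": ",".join(map(str, sorted(p.windows)))}
                for p in self.paths]
        return pd.DataFrame(rows, columns=["source", "target", "nodes",
                                           "distance", "n_windows",
                                           "windows"])


# ---------------------------------------------------------------------------
# Shortest paths
# ---------------------------------------------------------------------------

def length_matrix(graph: ContactGraph, r_map: dict[tuple[int, int], float]
                  ) -> tuple[np.ndarray, list[int]]:
    """Dense −ln(r) length matrix over the graph's connected nodes.

    Only nodes with at least one positive-correlation edge participate.
    Returns the matrix (inf where no edge) and the node list indexing it.
    """
    active = sorted({n for e, r in r_map.items()
                     if e in graph.edges and r > 0.0 for n in e})
    idx = {n: i for i, n in enumerate(active)}
    w = np.full((len(active), len(active)), np.inf)
    np.fill_diagonal(w, 0.0)
    for (i, j), r in r_map.items():
        if r > 0.0 and (i, j) in graph.edges:
            length = edge_length(min(r, 1.0))
            a, b = idx[i], idx[j]
            w[a, b] = w[b, a] = length
    return w, active


def _reconstruct(w: np.ndarray, dist: np.ndarray, s: int, t: int
                 ) -> list[int] | None:
    """Lexicographically smallest shortest path s→t from the distance matrix.

    Greedy: from u, step to the smallest-index neighbour v with
    w[u, v] + dist[v, t] = dist[u, t] (within tolerance).  Because every
    such v lies on some shortest path, the greedy choice yields the
    lexicographically minimal optimal node sequence.
    """
    if not np.isfinite(dist[s, t]):
        return None
    path = [s]
    u = s
    visited = {s}
    while u != t:
        d_rem = dist[u, t]
        best = None
        for v in np.nonzero(np.isfinite(w[u]))[0]:
            if v == u or v in visited:
                continue
            if abs(w[u, v] + dist[v, t] - d_rem) <= \
                    _REL_TOL * max(1.0, abs(d_rem)):
                best = int(v)
                break  # neighbours scanned in ascending index order
        if best is None:     # numerically stranded; should not happen
            return None
        path.append(best)
        visited.add(best)
        u = best
    return path


def optimal_paths(graph: ContactGraph, r_map: dict[tuple[int, int], float],
                  sources, targets, window_id: int | None = None
                  ) -> list[PathRecord]:
    """One optimal path per (source, target) pair on one window's network.

    Unreachable pairs yield no record.  ``window_id`` defaults to the
    graph's window.
    """
    sources, targets = sorted(set(sources)), sorted(set(targets))
    if not sources or not targets:
        raise ValueError("sources and targets must be non-empty")
    if set(sources) & set(targets):
        raise ValueError("sources and targets must be disjoint")
    node_set = set(graph.nodes)
    for n in list(sources) + list(targets):
        if n not in node_set:
            raise KeyError(f"node {n} not in graph")
    wid = graph.window_id if window_id is None else window_id

    w, active = length_matrix(graph, r_map)
    idx = {n: i for i, n in enumerate(active)}
    if not active:
        return []
    dist = floyd_warshall(w)
    records: list[PathRecord] = []
    for s in sources:
        for t in targets:
            if s not in idx or t not in idx:
                continue
            seq = _reconstruct(w, dist, idx[s], idx[t])
            if seq is None:
                continue
            nodes = tuple(active[i] for i in seq)
            records.append(PathRecord(
                nodes=nodes, distance=float(dist[idx[s], idx[t]]),
                windows=frozenset({wid}), source=s, target=t))
    return records


def pool_unique_paths(records: list[PathRecord]) -> PathEnsemble:
    """Merge records with identical node sequences, accumulating windows."""
    merged: dict[tuple[int, ...], PathRecord] = {}
    for rec in records:
        if rec.nodes in merged:
            prev = merged[rec.nodes]
            merged[rec.nodes] = replace(
                prev, windows=prev.windows | rec.windows,
                distance=min(prev.distance, rec.distance))
        else:
            merged[rec.nodes] = rec
    return PathEnsemble(paths=sorted(merged.values(),
                                     key=lambda p: p.nodes))


# ---------------------------------------------------------------------------
# Jaccard ensemble filter
# ---------------------------------------------------------------------------

def jaccard_similarity(a: PathRecord, b: PathRecord) -> float:
    """Intersection-over-union of the two paths' edge sets."""
    ea, eb = a.edges, b.edges
    if not ea or not eb:
        raise ValueError("paths must have at least one edge")
    return len(ea & eb) / len(ea | eb)


def ensemble_threshold(ensemble: PathEnsemble) -> float:
    """Largest t such that every path has a neighbour at similarity ≥ t.

    Equals min over paths of the maximum Jaccard similarity to any other
    path.  Undefined for ensembles of fewer than two paths.
    """
    if len(ensemble) < 2:
        raise ValueError("threshold needs an ensemble of ≥ 2 paths")
    m = ensemble.jaccard_matrix()
    np.fill_diagonal(m, -1.0)
    return float(m.max(axis=1).min())


def filter_paths(ensemble: PathEnsemble, threshold: float | None = None
                 ) -> PathEnsemble:
    """Apply the ensemble noise filter.

    A path is kept iff it was observed in more than one window, or its
    maximum Jaccard similarity to another path of the *unfiltered*
    ensemble is at least ``threshold``.  When ``threshold`` is omitted it
    is derived with :func:`ensemble_threshold`; single-path ensembles fall
    back to the window-count rule alone.
    """
    t_star = None
    if threshold is None:
        if len(ensemble) >= 2:
            t_star = threshold = ensemble_threshold(ensemble)
        else:
            threshold = float("inf")   # degenerate: window rule only
    if threshold != float("inf") and not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")

    keep: list[PathRecord] = []
    m = ensemble.jaccard_matrix() if len(ensemble) >= 2 else None
    if m is not None:
        np.fill_diagonal(m, -1.0)
    for i, p in enumerate(ensemble.paths):
        if len(p.windows) > 1:
            keep.append(p)
        elif m is not None and m[i].max() >= threshold:
            keep.append(p)
    return PathEnsemble(paths=keep, threshold=t_star,
                        applied_threshold=(None if threshold == float("inf")
                                           else threshold))


# ---------------------------------------------------------------------------
# Route classification
# ---------------------------------------------------------------------------

def classify_routes(ensemble: PathEnsemble, region_of: dict[int, str],
                    via_regions: tuple[str, ...] = ("partner",)
                    ) -> pd.DataFrame:
    """Label each path by the regions it traverses.

    Every node must be mapped to a region.  A path whose interior touches
    any of ``via_regions`` is classed ``"via-partner"``, otherwise
    ``"direct"``.  Returns one row per path with the ordered region trace
    (consecutive duplicates collapsed), the class, and ensemble fractions.
    """
    rows = []
    for p in ensemble.paths:
        missing = [n for n in p.nodes if n not in region_of]
        if missing:
            raise KeyError(f"nodes not mapped to a region: {missing}")
        trace: list[str] = []
        for n in p.nodes:
            r = region_of[n]
            if not trace or trace[-1] != r:
                trace.append(r)
        interior = {region_of[n] for n in p.nodes[1:-1]}
        cls = "via-partner" if interior & set(via_regions) else "direct"
        rows.append({"nodes": "-".join(map(str, p.nodes)),
                     "trace": "→".join(trace), "route_class": cls,
                     "n_windows": len(p.windows)})
    df = pd.DataFrame(rows, columns=["nodes", "trace", "route_class",
                                     "n_windows"])
    if len(df):
        df["class_fraction"] = df.groupby("route_class")[
            "route_class"].transform("size") / len(df)
    else:
        df["class_fraction"] = pd.Series(dtype=float)
    return df


def route_class_counts(ensemble: PathEnsemble, region_of: dict[int, str],
                       via_regions: tuple[str, ...] = ("partner",)
                       ) -> dict[str, int]:
    df = classify_routes(ensemble, region_of, via_regions)
    if not len(df):
        return {}
    return df["route_class"].value_counts().to_dict()
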