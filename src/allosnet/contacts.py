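"""Per-window residue contact networks.

Nodes are residues (one per Cα/bead); an edge joins two residues whose
heavy atoms come within a distance cutoff of each other in at least a
minimum fraction of the window's frames.  The defaults — 6 Å cutoff,
75 % persistence — capture interface interactions that a tighter 4.5 Å
cutoff would miss.  Persistence is evaluated per window, so edge sets may
differ between windows of the same system while the node set stays fixed.

Distances use the minimum over all heavy-atom pairs of the two residues;
a distance exactly at the cutoff counts as a contact (≤).  The spatial
search uses a k-d tree over heavy atoms and is exact — tests hold it
bit-identical to the brute-force all-pairs oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx
from scipy.spatial import cKDTree

from .core import MolecularSystem, StructuralError, TrajectoryWindow


@dataclass(frozen=True)
class ContactEdge:
    frequency: float      # fraction of frames in contact, ∈ [0, 1]
    min_distance: float   # smallest heavy-atom distance observed, Å


@dataclass
class ContactGraph:
    """Undirected residue graph for one trajectory window."""

    window_id: int
    nodes: list[int]                              # global residue indices
    edges: dict[tuple[int, int], ContactEdge]     # keys sorted (i < j)

    def has_edge(self, i: int, j: int) -> bool:
        return (min(i, j), max(i, j)) in self.edges

    def neighbors(self, i: int) -> list[int]:
        out = []
        for (a, b) in self.edges:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return sorted(out)

    def to_dataframe(self, system: MolecularSystem | None = None
                     ) -> pd.DataFrame:
        rows = []
        for (i, j), e in sorted(self.edges.items()):
            row = {"node_i": i, "node_j": j, "frequency": e.frequency,
                   "min_distance": e.min_distance}
            if system is not None:
                row["label_i"] = system.node_label(i)
                row["label_j"] = system.node_label(j)
            rows.append(row)
        return pd.DataFrame(rows, columns=["node_i", "node_j", "frequency",
                                           "min_distance"]
                            + (["label_i", "label_j"] if system else []))

    def to_networkx(self, system: MolecularSystem | None = None) -> nx.Graph:
        g = nx.Graph()
        for n in self.nodes:
            attrs = {"label": system.node_label(n)} if system else {}
            g.add_node(n, **attrs)
        for (i, j), e in self.edges.items():
            g.add_edge(i, j, frequency=e.frequency,
                       min_distance=e.min_distance)
        return g


def residue_min_distance(system: MolecularSystem, frame: np.ndarray,
                         res_a: int, res_b: int) -> float:
    """Minimum heavy-atom distance between two residues in one frame (Å)."""
    if res_a == res_b:
        raise ValueError(f"self-pair: residue {res_a} passed twice")
    ha = system.heavy_atoms(res_a)
    hb = system.heavy_atoms(res_b)
    if not ha or not hb:
        raise StructuralError(
            f"residue {res_a if not ha else res_b} has no heavy atoms")
    d = np.linalg.norm(frame[ha][:, None, :] - frame[hb][None, :, :], axis=2)
    return float(d.min())


def build_contact_graph(system: MolecularSystem, window: TrajectoryWindow,
                        cutoff: float = 6.0, min_freq: float = 0.75,
                        include_adjacent: bool = True) -> ContactGraph:
    """Contact graph of one window.

    An edge (i, j) is kept iff the fraction of frames with
    ``residue_min_distance(i, j) ≤ cutoff`` is at least ``min_freq``.
    Sequence-adjacent residues are retained by default — allosteric paths
    must be able to traverse covalent linkers — but can be excluded with
    ``include_adjacent=False``.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    if not 0.0 < min_freq <= 1.0:
        raise ValueError(f"min_freq must be in (0, 1], got {min_freq}")
    if window.n_frames == 0:
        raise ValueError("window has no frames")

    heavy = np.array([i for i, a in enumerate(system.atoms) if a.is_heavy],
                     dtype=int)
    if heavy.size == 0:
        raise StructuralError("system has no heavy atoms")
    res_of_heavy = np.array([system.atoms[i].residue_index for i in heavy],
                            dtype=int)

    # flat (i * n_res + j) keys, i < j; counts and minimum distances
    n_res = system.n_residues
    counts = np.zeros(n_res * n_res, dtype=np.int64)
    min_dist = np.full(n_res * n_res, np.inf)
    for frame in window.coords:
        pts = frame[heavy]
        tree = cKDTree(pts)
        pairs = tree.query_pairs(cutoff, output_type="ndarray")  # dist ≤ r
        if pairs.size == 0:
            continue
        ri = res_of_heavy[pairs[:, 0]]
        rj = res_of_heavy[pairs[:, 1]]
        mask = ri != rj
        if not np.any(mask):
            continue
        lo = np.minimum(ri[mask], rj[mask])
        hi = np.maximum(ri[mask], rj[mask])
        keys = lo * n_res + hi
        d = np.linalg.norm(pts[pairs[mask, 0]] - pts[pairs[mask, 1]], axis=1)
        np.minimum.at(min_dist, keys, d)
        counts[np.unique(keys)] += 1

    n_frames = window.n_frames
    edges: dict[tuple[int, int], ContactEdge] = {}
    for key in np.nonzero(counts)[0]:
        freq = counts[key] / n_frames
        if freq < min_freq:
            continue
        i, j = int(key) // n_res, int(key) % n_res
        if not include_adjacent and abs(i - j) == 1 and \
                system.residues[i].chain_id == system.residues[j].chain_id:
            continue
        edges[(i, j)] = ContactEdge(frequency=float(freq),
                                    min_distance=float(min_dist[key]))
    return ContactGraph(window_id=window.window_id,
                        nodes=list(range(system.n_residues)), edges=edges)


def interface_edges(graph: ContactGraph, set_a, set_b
                    ) -> dict[tuple[int, int], ContactEdge]:
    """Edges with one endpoint in ``set_a`` and the other in ``set_b``."""
    sa, sb = set(set_a), set(set_b)
    if sa & sb:
        raise ValueError(f"sets overlap: {sorted(sa & sb)}")
    return {(i, j): e for (i, j), e in graph.edges.items()
            if (i in sa and j in sb) or (i in sb and j in sa)}


def write_edge_tsv(graph: ContactGraph, path,
                   system: MolecularSystem | None = None) -> None:
    graph.to_dataframe(system).to_csv(path, sep="\t", index=False)


def write_graphml(graph: ContactGraph, path,
                  system: MolecularSystem | None = None) -> None:
    nx.write_graphml(graph.to_networkx(system), path)
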