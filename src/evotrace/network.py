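"""Probabilistic sub-network inference over a typed gene-interaction graph.

A directed interaction network (metabolic, protein-protein, protein-DNA
edges; protein-protein stored as two arcs) is converted to a probabilistic
network in which an edge's probability falls with the out-degree of its
terminal node, so paths through hubs are penalized. Mutated genes are then
connected through k-best loop-free bounded-length paths, and a parsimonious
sub-network is grown greedily from the most probable paths under a per-edge
cost.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "read_sif", "write_sif", "probabilize", "k_best_paths",
    "select_subnetwork", "annotate_overlap", "SubNetwork",
]

EDGE_TYPES = {"metabolic", "protein-protein", "protein-DNA"}
UNDIRECTED_TYPES = {"protein-protein"}


def read_sif(path: str) -> nx.DiGraph:
    """Read a three-column edge list (source, type, target — SIF — or
    source, target, type); protein-protein edges become two arcs."""
    df = pd.read_csv(path, sep=r"\s+", header=None,
                     names=["a", "b", "c"], dtype=str)
    g = nx.DiGraph()
    for _, row in df.iterrows():
        if row["b"] in EDGE_TYPES:          # SIF order: source type target
            src, etype, dst = row["a"], row["b"], row["c"]
        else:                               # edge-list order: source target type
            src, dst, etype = row["a"], row["b"], row["c"]
        if src == dst:
            continue
        g.add_edge(src, dst, type=etype)
        if etype in UNDIRECTED_TYPES:
            g.add_edge(dst, src, type=etype)
    return g


def write_sif(g: nx.DiGraph, path: str) -> None:
    seen = set()
    with open(path, "w") as fh:
        for u, v, d in g.edges(data=True):
            etype = d.get("type", "protein-protein")
            key = (frozenset((u, v)), etype) if etype in UNDIRECTED_TYPES else (u, v, etype)
            if key in seen:
                continue
            seen.add(key)
            fh.write(f"{u}\t{etype}\t{v}\n")


def probabilize(g: nx.DiGraph, p_min: float = 0.1,
                p_max: float = 0.9) -> nx.DiGraph:
    """Attach edge probabilities from the out-degree distribution of edge
    terminal nodes: p(u->v) = p_min + (p_max - p_min) * (1 - percentile-rank
    of out-degree(v) among all edges' terminal nodes), average ranks for
    ties. Topology is unchanged."""
    if g.number_of_edges() == 0:
        raise ValueError("empty network")
    edges = list(g.edges())
    deg = np.array([g.out_degree(v) for _, v in edges], dtype=float)
    m = len(edges)
    if m == 1:
        pct = np.array([0.0])
    else:
        pct = (rankdata(deg, method="average") - 1) / (m - 1)
    probs = p_min + (p_max - p_min) * (1.0 - pct)
    pg = g.copy()
    for (u, v), p in zip(edges, probs):
        pg.edges[u, v]["probability"] = float(p)
    return pg


def k_best_paths(pg: nx.DiGraph, source: str, target: str, k: int = 100,
                 max_len: int = 4, cutoff: float = 0.01
                 ) -> list[tuple[tuple[str, ...], float]]:
    """Up to ``k`` most probable loop-free paths of at most ``max_len`` edges.

    Path probability is the product of edge probabilities; partial paths
    falling below ``cutoff`` are pruned; ties in probability are broken by
    lexicographic node sequence. Best-first search guarantees the returned
    list is sorted by non-increasing probability.
    """
    if source == target:
        raise ValueError("source and target must differ")
    if source not in pg or target not in pg:
        missing = [n for n in (source, target) if n not in pg]
        raise KeyError(f"node(s) not in network: {missing}")
    results: list[tuple[tuple[str, ...], float]] = []
    # heap entries: (-probability, path); tuple comparison breaks ties
    heap: list[tuple[float, tuple[str, ...]]] = [(-1.0, (source,))]
    while heap and len(results) < k:
        neg_p, path = heapq.heappop(heap)
        prob = -neg_p
        node = path[-1]
        if node == target:
            results.append((path, prob))
            continue
        if len(path) - 1 >= max_len:
            continue
        for _, nxt, data in pg.out_edges(node, data=True):
            if nxt in path:
                continue
            p2 = prob * data["probability"]
            if p2 < cutoff:
                continue
            heapq.heappush(heap, (-p2, path + (nxt,)))
    return results


@dataclass
class SubNetwork:
    """Selected sub-graph connecting mutated genes."""
    graph: nx.DiGraph
    mutated: list[str]
    intermediaries: list[str] = field(default_factory=list)
    paths: list[tuple[tuple[str, ...], float]] = field(default_factory=list)
    unconnected: list[str] = field(default_factory=list)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)


def select_subnetwork(pg: nx.DiGraph, mutated_genes: list[str],
                      cost: float = 0.25, k: int = 100, max_len: int = 4,
                      cutoff: float = 0.01) -> SubNetwork:
    """Grow a parsimonious sub-network from k-best paths between mutated
    genes.

    Candidate paths (k best per ordered mutated-gene pair) are visited in
    decreasing probability; a path is accepted when its probability exceeds
    ``cost`` times the number of edges it would newly introduce. Selection
    stops when no remaining candidate qualifies. Larger costs therefore give
    smaller sub-networks.
    """
    present = [m for m in mutated_genes if m in pg]
    missing = [m for m in mutated_genes if m not in pg]
    if not present:
        raise ValueError(f"no mutated gene present in network; missing: {missing}")
    candidates: list[tuple[tuple[str, ...], float]] = []
    for a in present:
        for b in present:
            if a == b:
                continue
            candidates.extend(k_best_paths(pg, a, b, k=k, max_len=max_len,
                                           cutoff=cutoff))
    candidates.sort(key=lambda x: (-x[1], x[0]))
    selected = nx.DiGraph()
    accepted: list[tuple[tuple[str, ...], float]] = []
    remaining = candidates
    changed = True
    while changed:  # edges added by earlier paths make later paths cheaper
        changed = False
        deferred = []
        for path, prob in remaining:
            edges = list(zip(path[:-1], path[1:]))
            new = [e for e in edges if not selected.has_edge(*e)]
            if not new or prob - cost * len(new) > 0:
                for u, v in edges:
                    selected.add_edge(u, v, **pg.edges[u, v])
                accepted.append((path, prob))
                changed = True
            else:
                deferred.append((path, prob))
        remaining = deferred
    connected = {n for path, _ in accepted for n in path}
    unconnected = sorted(set(present) - connected)
    intermediaries = sorted(n for n in selected.nodes if n not in set(present))
    for n in selected.nodes:
        selected.nodes[n]["mutated"] = n in set(present)
    return SubNetwork(graph=selected, mutated=sorted(present),
                      intermediaries=intermediaries, paths=accepted,
                      unconnected=unconnected + sorted(missing))


def annotate_overlap(sub: SubNetwork, full: nx.DiGraph,
                     reference: set[str]) -> dict[str, float]:
    """Fraction of sub-network genes found in a reference gene set, and the
    same fraction for genes of the full network outside the sub-network."""
    if not reference:
        raise ValueError("reference set is empty")
    inside = set(sub.graph.nodes)
    outside = set(full.nodes) - inside
    return {
        "inside_fraction": (len(inside & reference) / len(inside)) if inside else 0.0,
        "outside_fraction": (len(outside & reference) / len(outside)) if outside else 0.0,
        "n_inside": len(inside), "n_outside": len(outside),
    }
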