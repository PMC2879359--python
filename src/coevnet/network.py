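"""Residue graphs: node filtering, pruning, consensus networks, edge-set comparison.

A score matrix over alignment columns becomes a dense weighted undirected
graph whose nodes are canonical residue positions. Three node filters are
applied first:

* columns more than 10% gapped in the MSA,
* columns whose entropy is not above a floor (default: the entropy of a
  two-symbol column at 95%/5%, ~0.2864 bits — "at least 5% of the residues
  are changing"),
* columns where the canonical sequence is gapped (they carry no residue
  number).

The dense graph is then pruned to its maximal spanning tree (MST), its top
N-1 edges (TNm1) or its bottom N-1 edges (BNm1). Pruned graphs from many
resampled sub-alignments are combined into a consensus network whose edge
weights are occurrence frequencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .msa import Alignment, entropy_bits, N_AA
from .scoring import ScoreMatrix

#: entropy of a binary column with frequencies 95% / 5%, in bits
DEFAULT_ENTROPY_FLOOR_BITS = -(0.95 * math.log2(0.95) + 0.05 * math.log2(0.05))


class DegenerateGraphError(ValueError):
    """Raised when filtering leaves fewer than two usable nodes."""


def eligible_columns(
    aln: Alignment,
    gap_cutoff: float = 0.10,
    entropy_floor_bits: float = DEFAULT_ENTROPY_FLOOR_BITS,
) -> np.ndarray:
    """Boolean mask of columns passing all three node filters."""
    m = aln.to_matrix()
    valid = m >= 0
    gap_fraction = 1.0 - valid.mean(axis=0)
    ent = np.empty(aln.length)
    for i in range(aln.length):
        counts = np.bincount(m[valid[:, i], i], minlength=N_AA)
        ent[i] = entropy_bits(counts)
    canonical_ungapped = aln.canonical_residue_numbers() > 0
    return (gap_fraction <= gap_cutoff) & (ent > entropy_floor_bits) & canonical_ungapped


def build_graph(
    sm: ScoreMatrix,
    aln: Alignment,
    gap_cutoff: float = 0.10,
    entropy_floor_bits: float = DEFAULT_ENTROPY_FLOOR_BITS,
) -> nx.Graph:
    """Dense weighted graph over canonical residue numbers.

    Nodes are columns passing the three node filters intersected with the
    score matrix's own eligibility mask; node labels are 1-based canonical
    residue numbers. Edge weights are the pair scores.
    """
    if sm.L != aln.length:
        raise ValueError("score matrix and alignment have different lengths")
    mask = eligible_columns(aln, gap_cutoff, entropy_floor_bits) & sm.eligible
    idx = np.flatnonzero(mask)
    if len(idx) < 2:
        raise DegenerateGraphError(f"only {len(idx)} columns survive the node filters")
    numbers = aln.canonical_residue_numbers()
    g = nx.Graph()
    g.add_nodes_from(int(numbers[i]) for i in idx)
    for a in range(len(idx)):
        i = idx[a]
        for b in range(a + 1, len(idx)):
            j = idx[b]
            w = sm.scores[i, j]
            if not np.isnan(w):
                g.add_edge(int(numbers[i]), int(numbers[j]), weight=float(w))
    return g


# ---------------------------------------------------------------------------
# Pruning
# ---------------------------------------------------------------------------

def _sorted_edges(g: nx.Graph, descending: bool) -> list[tuple[int, int, float]]:
    """Edges as (u, v, w) with u < v, ordered by weight then (u, v).

    Descending order sorts by (-w, u, v); ascending by (w, u, v). The node
    tie-break makes every pruner deterministic.
    """
    edges = [(min(u, v), max(u, v), d["weight"]) for u, v, d in g.edges(data=True)]
    if descending:
        edges.sort(key=lambda e: (-e[2], e[0], e[1]))
    else:
        edges.sort(key=lambda e: (e[2], e[0], e[1]))
    return edges


def prune_mst(g: nx.Graph) -> nx.Graph:
    """Maximal spanning tree via Kruskal with deterministic tie-breaking.

    Exactly N-1 edges over the N nodes; raises on disconnected input (dense
    score graphs are always connected).
    """
    parent = {n: n for n in g.nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    tree = nx.Graph()
    tree.add_nodes_from(g.nodes)
    for u, v, w in _sorted_edges(g, descending=True):
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
            tree.add_edge(u, v, weight=w)
            if tree.number_of_edges() == g.number_of_nodes() - 1:
                break
    if tree.number_of_edges() != g.number_of_nodes() - 1:
        raise DegenerateGraphError("graph is disconnected: no spanning tree exists")
    return tree


def prune_topk(g: nx.Graph, k: int | None = None, direction: str = "top") -> nx.Graph:
    """Keep the k largest ("top", TNm1) or smallest ("bottom", BNm1) edges.

    ``k`` defaults to N-1. If the graph has fewer than k edges, all are kept.
    Boundary ties resolve by (weight, then lower (u, v)) ordering.
    """
    if direction not in ("top", "bottom"):
        raise ValueError("direction must be 'top' or 'bottom'")
    if k is None:
        k = g.number_of_nodes() - 1
    if k < 1:
        raise ValueError("k must be >= 1")
    edges = _sorted_edges(g, descending=(direction == "top"))[:k]
    out = nx.Graph()
    out.add_nodes_from(g.nodes)
    out.add_weighted_edges_from(edges)
    return out


PRUNERS = {
    "mst": prune_mst,
    "tnm1": lambda g: prune_topk(g, direction="top"),
    "bnm1": lambda g: prune_topk(g, direction="bottom"),
}


# ---------------------------------------------------------------------------
# Consensus networks
# ---------------------------------------------------------------------------

def _edge_key(u, v) -> tuple:
    return (u, v) if u <= v else (v, u)


@dataclass
class ConsensusNetwork:
    """Edge occurrence frequencies across an ensemble of pruned graphs.

    ``frequencies`` maps unordered node pairs to occurrence/total_graphs in
    (0, 1]; only edges seen at least once are stored.
    """

    frequencies: dict
    total_graphs: int

    def cut(self, cutoff: float) -> nx.Graph:
        return cut_consensus(self, cutoff)

    def edge_set(self, cutoff: float = 0.0) -> set:
        return {e for e, f in self.frequencies.items() if f >= cutoff}


def consensus(graphs) -> ConsensusNetwork:
    """Per-edge presence frequency over a collection of pruned graphs."""
    graphs = list(graphs)
    if not graphs:
        raise ValueError("consensus of an empty graph collection")
    counts: dict = {}
    for g in graphs:
        for u, v in g.edges:
            key = _edge_key(u, v)
            counts[key] = counts.get(key, 0) + 1
    total = len(graphs)
    return ConsensusNetwork({e: c / total for e, c in counts.items()}, total)


def cut_consensus(cn: ConsensusNetwork, cutoff: float) -> nx.Graph:
    """Graph of consensus edges with frequency >= cutoff (weights = frequencies)."""
    if not (0.0 <= cutoff <= 1.0):
        raise ValueError("cutoff must lie in [0, 1]")
    g = nx.Graph()
    for (u, v), f in cn.frequencies.items():
        if f >= cutoff:
            g.add_edge(u, v, weight=f)
    return g


def largest_component(g: nx.Graph) -> int:
    """Node count of the largest connected component (0 for an empty graph)."""
    if g.number_of_nodes() == 0:
        return 0
    return max(len(c) for c in nx.connected_components(g))


def jaccard_edges(a, b) -> float:
    """Jaccard index of two edge sets: |A & B| / |A | B|.

    Accepts graphs or iterables of (u, v) pairs; edge identity is the
    unordered node pair, weights ignored. Two empty sets have index 1.
    """
    def as_set(x) -> set:
        edges = x.edges if isinstance(x, nx.Graph) else x
        return {_edge_key(u, v) for u, v in edges}

    sa, sb = as_set(a), as_set(b)
    if not sa and not sb:
        return 1.0
    return len(sa & sb) / len(sa | sb)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def write_edgelist_tsv(g: nx.Graph, path) -> None:
    """Write edges as TSV (u, v, weight), u < v, sorted."""
    rows = sorted((min(u, v), max(u, v), d.get("weight", 1.0)) for u, v, d in g.edges(data=True))
    with open(path, "w") as fh:
        fh.write("u\tv\tweight\n")
        for u, v, w in rows:
            fh.write(f"{u}\t{v}\t{w:.10g}\n")


def write_graphml(g: nx.Graph, path) -> None:
    nx.write_graphml(g, str(path))
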