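"""Structural mapping and the accuracy / reproducibility metrics.

Predicted couplings are judged against the canonical sequence's 3D structure
through C-beta distances (C-alpha for glycine, the standard contact proxy).
Distances are rescaled by the minimum and mean over all mappable residue
pairs,

    s(u, v) = (d(u, v) - d_min) / (d_avg - d_min),

so that the accuracy of a pruned graph,

    accuracy = 1 - sum_e w_e s_e / sum_e w_e,

is 1 when every predicted pair sits at the minimal attainable distance and 0
in expectation for uniformly random pair choices. Reproducibility of a split
is the Pearson correlation of edge weights between the two halves' pruned
graphs over the union of their edges, absent edges weighted zero; disjoint
predictions therefore score negative, identical ones score 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np

from .msa import Alignment
from .network import ConsensusNetwork, _edge_key


class DegenerateMetricError(ValueError):
    """Raised when a metric is undefined (zero variance, no edges, ...)."""


class MappingError(ValueError):
    """Raised when the structure cannot be reconciled with the canonical sequence."""


@dataclass
class StructureMap:
    """Residue number -> 3D coordinate (Angstrom) of the contact atom.

    One coordinate per residue: the C-beta atom, or C-alpha for glycine and
    for residues whose C-beta is missing.
    """

    coordinates: dict
    chain_id: str = "A"
    source_id: str = ""

    def __contains__(self, residue_number: int) -> bool:
        return residue_number in self.coordinates

    def __getitem__(self, residue_number: int) -> np.ndarray:
        return self.coordinates[residue_number]

    def __len__(self) -> int:
        return len(self.coordinates)


def read_structure(path, chain: str = "A") -> StructureMap:
    """Parse ATOM records of a PDB file into a :class:`StructureMap`.

    Uses the first model; residue numbers are the PDB residue sequence
    numbers of the chosen chain. Residues with neither C-beta nor C-alpha
    are dropped with a warning.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.Polypeptide import is_aa

    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure("s", str(path))
    except Exception as exc:  # pragma: no cover - biopython error paths
        raise MappingError(f"cannot parse PDB file {path}: {exc}") from exc
    model = next(iter(structure))
    if chain not in [c.id for c in model]:
        raise MappingError(f"chain {chain!r} not found in {path}")
    coords: dict = {}
    for residue in model[chain]:
        if not is_aa(residue, standard=False):
            continue
        atom = None
        if "CB" in residue:
            atom = residue["CB"]
        elif "CA" in residue:
            atom = residue["CA"]
        if atom is None:
            warnings.warn(
                f"residue {residue.id[1]} has neither CB nor CA; dropped", stacklevel=2
            )
            continue
        coords[int(residue.id[1])] = np.asarray(atom.coord, dtype=float)
    if not coords:
        raise MappingError(f"chain {chain!r} contains no usable residues")
    return StructureMap(coords, chain_id=chain, source_id=str(path))


@dataclass
class DistanceContext:
    """Pairwise distances over mappable canonical positions.

    ``d_min`` and ``d_avg`` are the minimum and mean distance over *all*
    unordered mappable pairs — the rescaling anchors of the accuracy metric.
    """

    positions: np.ndarray
    _dist: dict = field(repr=False, default_factory=dict)
    d_min: float = 0.0
    d_avg: float = 0.0

    def distance(self, u: int, v: int) -> float:
        return self._dist[_edge_key(u, v)]

    def __contains__(self, position: int) -> bool:
        return position in set(self.positions.tolist())


def map_columns(aln: Alignment, smap: StructureMap) -> DistanceContext:
    """Build the distance context linking canonical positions to the structure.

    Positions mapped are those canonical (1-based, ungapped) positions that
    carry a structure coordinate. Structure residues numbered beyond the
    canonical length indicate a numbering mismatch and raise
    :class:`MappingError`.
    """
    n_can = aln.canonical.ungapped_length
    beyond = [p for p in smap.coordinates if p < 1 or p > n_can]
    if beyond:
        raise MappingError(
            f"{len(beyond)} structure residues outside canonical range 1..{n_can} "
            f"(e.g. {sorted(beyond)[:5]}); renumber the structure to canonical positions"
        )
    positions = np.array(sorted(smap.coordinates), dtype=int)
    if len(positions) < 2:
        raise MappingError("need at least 2 mappable positions")
    dist: dict = {}
    for u, v in combinations(positions.tolist(), 2):
        dist[(u, v)] = float(np.linalg.norm(smap[u] - smap[v]))
    values = np.array(list(dist.values()))
    return DistanceContext(positions, dist, float(values.min()), float(values.mean()))


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def accuracy(g: nx.Graph, ctx: DistanceContext) -> float:
    """Weight-averaged structural proximity of a pruned graph's edges.

    1 when all edges sit at ``d_min``; 0 in expectation for random pairs; can
    be negative for predictions worse than random. Edge weights must be
    usable as averaging weights: if any retained weight is <= 0 (z-scored
    metrics), all weights are shifted by ``-min + 1e-6`` first, which leaves
    the metric invariant under uniform weight rescaling but not shifting.
    """
    edges = [(u, v, d.get("weight", 1.0)) for u, v, d in g.edges(data=True)]
    if not edges:
        raise DegenerateMetricError("accuracy of an edgeless graph is undefined")
    if ctx.d_avg == ctx.d_min:
        raise DegenerateMetricError("degenerate geometry: d_avg == d_min")
    w = np.array([e[2] for e in edges])
    if w.min() <= 0:
        w = w - w.min() + 1e-6
    s = np.array(
        [(ctx.distance(u, v) - ctx.d_min) / (ctx.d_avg - ctx.d_min) for u, v, _ in edges]
    )
    return float(1.0 - (w * s).sum() / w.sum())


def reproducibility(a: nx.Graph, b: nx.Graph) -> float:
    """Pearson correlation of edge weights over the union of two edge sets.

    An edge present in one graph only contributes its weight there and zero
    in the other. Raises :class:`DegenerateMetricError` when either weight
    vector has zero variance (e.g. fewer than two edges in the union).
    """
    wa = {_edge_key(u, v): d.get("weight", 1.0) for u, v, d in a.edges(data=True)}
    wb = {_edge_key(u, v): d.get("weight", 1.0) for u, v, d in b.edges(data=True)}
    union = sorted(set(wa) | set(wb))
    if len(union) < 2:
        raise DegenerateMetricError("reproducibility needs >= 2 edges in the union")
    x = np.array([wa.get(e, 0.0) for e in union])
    y = np.array([wb.get(e, 0.0) for e in union])
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise DegenerateMetricError("reproducibility undefined: constant weight vector")
    return float(np.corrcoef(x, y)[0, 1])


def mean_linear_separation(g: nx.Graph) -> float:
    """Mean |u - v| over edges, in canonical residue numbering (unweighted)."""
    if g.number_of_edges() == 0:
        raise DegenerateMetricError("mean linear separation of an edgeless graph")
    return float(np.mean([abs(u - v) for u, v in g.edges]))


def mean_contact_distance(cn: ConsensusNetwork, cutoff: float, ctx: DistanceContext) -> float:
    """Unweighted mean structural distance of consensus edges above a cutoff."""
    edges = [e for e, f in cn.frequencies.items() if f >= cutoff]
    if not edges:
        raise DegenerateMetricError(f"no consensus edges at cutoff {cutoff}")
    return float(np.mean([ctx.distance(u, v) for u, v in edges]))


# ---------------------------------------------------------------------------
# Toy-structure writer (used for synthetic fixtures)
# ---------------------------------------------------------------------------

def write_pdb(smap: StructureMap, path) -> None:
    """Write a StructureMap as a minimal single-chain PDB of CB pseudo-atoms."""
    with open(path, "w") as fh:
        serial = 1
        for resnum in sorted(smap.coordinates):
            x, y, z = smap[resnum]
            fh.write(
                f"ATOM  {serial:5d}  CB  ALA {smap.chain_id}{resnum:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
            )
            serial += 1
        fh.write("END\n")
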