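"""Split-half resampling of an alignment and the ensemble pipeline driver.

The pipeline-sensitivity framework partitions the alignment many times into
two disjoint equal halves (the canonical sequence is added to both, for
numbering), runs each half independently through node filtering, scoring and
pruning, and compares the two pruned graphs of every split:

* **reproducibility** — Pearson correlation of edge weights over the union
  of the two halves' edges (absent edges weighted zero);
* **accuracy** — weight-averaged rescaled structural distance of each half's
  edges (when a structure is supplied);

and aggregates all pruned graphs into a consensus network whose edge
weights are occurrence frequencies.

The entry point is :class:`CoevolutionModel` (data + configuration) whose
:meth:`~CoevolutionModel.fit` returns an :class:`EnsembleResults` carrying
the per-split metrics table, the consensus network and a ``summary()``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .msa import Alignment
from .network import (
    DEFAULT_ENTROPY_FLOOR_BITS,
    ConsensusNetwork,
    DegenerateGraphError,
    PRUNERS,
    build_graph,
    consensus,
    cut_consensus,
    largest_component,
)
from .scoring import SCORERS, DegenerateScoreError, compute_scores
from .structure import (
    DegenerateMetricError,
    DistanceContext,
    accuracy,
    mean_contact_distance,
    mean_linear_separation,
    reproducibility,
)
from . import network

logger = logging.getLogger(__name__)


@dataclass
class SplitPair:
    """One disjoint 2-split: two equal half-alignments sharing the canonical."""

    half_a: Alignment
    half_b: Alignment
    split_index: int
    seed: int

    def __post_init__(self) -> None:
        can = self.half_a.canonical_id
        a = {r.identifier for r in self.half_a.records} - {can}
        b = {r.identifier for r in self.half_b.records} - {can}
        if a & b:
            raise ValueError("split halves share non-canonical sequences")
        if len(self.half_a) != len(self.half_b):
            raise ValueError("split halves differ in size")


def make_splits(aln: Alignment, n_splits: int = 150, seed: int = 0) -> list[SplitPair]:
    """Generate ``n_splits`` independent disjoint 2-splits.

    Each split draws its own RNG seeded ``seed + split_index``, shuffles the
    non-canonical records and deals them alternately into the two halves;
    for an odd count one (uniformly random) record sits out so the halves
    stay equal. The canonical record joins both halves. Fully reproducible
    from the master seed.
    """
    canonical = aln.canonical
    others = [k for k, r in enumerate(aln.records) if r is not canonical]
    if len(others) < 3:
        raise ValueError("need at least 3 non-canonical sequences to split")
    can_idx = aln.records.index(canonical)
    splits = []
    for s in range(n_splits):
        split_seed = seed + s
        rng = np.random.default_rng(split_seed)
        perm = rng.permutation(len(others))
        if len(perm) % 2:
            perm = perm[:-1]  # the dropped index is uniform under the shuffle
        ia = [others[p] for p in perm[0::2]]
        ib = [others[p] for p in perm[1::2]]
        half_a = aln.subset(sorted(ia + [can_idx]))
        half_b = aln.subset(sorted(ib + [can_idx]))
        splits.append(SplitPair(half_a, half_b, s, split_seed))
    return splits


# ---------------------------------------------------------------------------
# Ensemble driver
# ---------------------------------------------------------------------------

def _process_half(
    half: Alignment,
    scorer: str,
    pruner: str,
    gap_cutoff: float,
    entropy_floor_bits: float,
    seed: int,
):
    """Node filters -> score matrix -> dense graph -> pruned graph for one half."""
    mask = network.eligible_columns(half, gap_cutoff, entropy_floor_bits)
    if mask.sum() < 2:
        raise DegenerateScoreError("fewer than 2 eligible columns in this half")
    sm = compute_scores(half, scorer, mask, seed=seed)
    dense = build_graph(sm, half, gap_cutoff, entropy_floor_bits)
    return PRUNERS[pruner](dense)


def run_ensemble(
    aln: Alignment,
    scorer: str = "znmi",
    pruner: str = "mst",
    n_splits: int = 150,
    seed: int = 0,
    gap_cutoff: float = 0.10,
    entropy_floor_bits: float = DEFAULT_ENTROPY_FLOOR_BITS,
    distance_context: DistanceContext | None = None,
) -> "EnsembleResults":
    """Run the full split-half pipeline; functional form of ``CoevolutionModel.fit``."""
    model = CoevolutionModel(
        aln,
        scorer=scorer,
        pruner=pruner,
        gap_cutoff=gap_cutoff,
        entropy_floor_bits=entropy_floor_bits,
        distance_context=distance_context,
    )
    return model.fit(n_splits=n_splits, seed=seed)


@dataclass
class CoevolutionModel:
    """Split-half pipeline-sensitivity analysis of one alignment.

    Parameters
    ----------
    alignment
        The preprocessed MSA (similarity/length filtering is up to the
        caller; see :func:`coevnet.msa.filter_by_similarity`).
    scorer, pruner
        Registered names: scorers ``mi, nmi, znmi, mip, zres, omes, rand``;
        pruners ``mst, tnm1, bnm1``.
    gap_cutoff, entropy_floor_bits
        Node filters, recomputed on every half-alignment.
    distance_context
        Optional structural distances for accuracy; reproducibility is
        computed regardless.
    """

    alignment: Alignment
    scorer: str = "znmi"
    pruner: str = "mst"
    gap_cutoff: float = 0.10
    entropy_floor_bits: float = DEFAULT_ENTROPY_FLOOR_BITS
    distance_context: DistanceContext | None = None

    def __post_init__(self) -> None:
        if self.scorer not in SCORERS:
            raise KeyError(f"unknown scorer {self.scorer!r}; registered: {sorted(SCORERS)}")
        if self.pruner not in PRUNERS:
            raise KeyError(f"unknown pruner {self.pruner!r}; registered: {sorted(PRUNERS)}")

    def fit(self, n_splits: int = 150, seed: int = 0) -> "EnsembleResults":
        """Score and prune every half of ``n_splits`` 2-splits.

        Splits in which either half retains fewer than two eligible columns
        are skipped with a warning and the consensus denominator adjusted.
        """
        splits = make_splits(self.alignment, n_splits=n_splits, seed=seed)
        graphs = []
        rows = []
        with_structure = self.distance_context is not None
        for sp in splits:
            try:
                ga = _process_half(
                    sp.half_a, self.scorer, self.pruner, self.gap_cutoff,
                    self.entropy_floor_bits, seed=2 * sp.seed,
                )
                gb = _process_half(
                    sp.half_b, self.scorer, self.pruner, self.gap_cutoff,
                    self.entropy_floor_bits, seed=2 * sp.seed + 1,
                )
            except (DegenerateScoreError, DegenerateGraphError) as exc:
                logger.warning("split %d skipped: %s", sp.split_index, exc)
                continue
            graphs.extend([ga, gb])
            row = {"split_index": sp.split_index}
            try:
                row["reproducibility"] = reproducibility(ga, gb)
            except DegenerateMetricError as exc:
                logger.warning("split %d reproducibility undefined: %s", sp.split_index, exc)
                row["reproducibility"] = np.nan
            row["mean_separation_a"] = mean_linear_separation(ga)
            row["mean_separation_b"] = mean_linear_separation(gb)
            if with_structure:
                row["accuracy_a"] = accuracy(ga, self.distance_context)
                row["accuracy_b"] = accuracy(gb, self.distance_context)
            rows.append(row)
        if not graphs:
            raise DegenerateGraphError("every split was degenerate; nothing to aggregate")
        metrics = pd.DataFrame(rows).set_index("split_index")
        return EnsembleResults(
            model=self, consensus_network=consensus(graphs), metrics=metrics,
            n_splits_requested=n_splits, seed=seed,
        )


@dataclass
class EnsembleResults:
    """Results of a fitted split-half ensemble.

    Attributes
    ----------
    metrics
        Per-split table: reproducibility, mean linear separations and (when
        a structure was supplied) the two halves' accuracies.
    consensus_network
        Edge occurrence frequencies over all 2 x n_splits pruned graphs.
    """

    model: CoevolutionModel
    consensus_network: ConsensusNetwork
    metrics: pd.DataFrame
    n_splits_requested: int
    seed: int
    _cache: dict = field(default_factory=dict, repr=False)

    # -- aggregates --------------------------------------------------------
    @property
    def mean_reproducibility(self) -> float:
        return float(self.metrics["reproducibility"].mean())

    @property
    def mean_accuracy(self) -> float:
        if "accuracy_a" not in self.metrics:
            raise DegenerateMetricError("no structure was supplied: accuracy unavailable")
        both = pd.concat([self.metrics["accuracy_a"], self.metrics["accuracy_b"]])
        return float(both.mean())

    def consensus_at(self, cutoff: float):
        """Consensus graph cut at an edge-frequency cutoff."""
        return cut_consensus(self.consensus_network, cutoff)

    def largest_component_curve(self, cutoffs) -> pd.Series:
        """Largest-component size as a function of frequency cutoff."""
        return pd.Series(
            {c: largest_component(self.consensus_at(c)) for c in cutoffs},
            name="largest_component",
        )

    def contact_distance_curve(self, cutoffs) -> pd.Series:
        """Mean structural distance of surviving consensus edges per cutoff."""
        ctx = self.model.distance_context
        if ctx is None:
            raise DegenerateMetricError("no structure was supplied")
        out = {}
        for c in cutoffs:
            try:
                out[c] = mean_contact_distance(self.consensus_network, c, ctx)
            except DegenerateMetricError:
                out[c] = np.nan
        return pd.Series(out, name="mean_contact_distance")

    def summary(self) -> str:
        """Human-readable summary table of the ensemble."""
        m = self.model
        lines = [
            "Split-half coevolution ensemble",
            "=" * 47,
            f"{'scorer':<28}{m.scorer:>19}",
            f"{'pruner':<28}{m.pruner:>19}",
            f"{'splits (used/requested)':<28}"
            f"{f'{len(self.metrics)}/{self.n_splits_requested}':>19}",
            f"{'graphs in consensus':<28}{self.consensus_network.total_graphs:>19}",
            f"{'consensus edges':<28}{len(self.consensus_network.frequencies):>19}",
            f"{'master seed':<28}{self.seed:>19}",
            "-" * 47,
        ]

        def stat(name, series):
            lines.append(
                f"{name:<28}{series.mean():>9.4f} +/- {series.std(ddof=0):<7.4f}"
            )

        stat("reproducibility", self.metrics["reproducibility"])
        if "accuracy_a" in self.metrics:
            both = pd.concat([self.metrics["accuracy_a"], self.metrics["accuracy_b"]])
            stat("accuracy", both)
        sep = pd.concat(
            [self.metrics["mean_separation_a"], self.metrics["mean_separation_b"]]
        )
        stat("mean linear separation", sep)
        lines.append("=" * 47)
        return "\n".join(lines)
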