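"""Synthetic alignment families with planted covarying column pairs.

The generator emulates the signal/noise structure of a real protein family
at the level the pipeline sees it: independent background columns of varying
alphabet size (hence varying entropy — the source of the column bias that
motivates NMI/ZNMI), a set of *planted* covarying column pairs in which the
second column copies a bijective image of the first with probability c (the
coupling strength), optional near-duplicate redundant sequences mimicking
phylogenetic oversampling, per-column gapping, and a toy 3D structure in
which planted pairs are spatially close (< 6 Angstrom) while all other
residues lie on an extended 3.8 Angstrom-per-residue chain.

It does not emulate a phylogeny (sequences are exchangeable) or a Potts-like
global coupling model; recovered-signal results on these fixtures exercise
the pipeline's statistics, not alignment quality on real families.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .msa import AMINO_ACIDS, Alignment, SequenceRecord, write_alignment
from .structure import StructureMap, write_pdb

#: planted pairs are placed within this distance in the toy structure
CONTACT_THRESHOLD = 6.0

_DEFAULT_PAIRS = [(5, 20, 0.8), (10, 35, 0.8), (15, 44, 0.8), (25, 50, 0.8), (30, 55, 0.8)]


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic family.

    Defaults describe the standard study condition used throughout the test
    suite: 60 columns, 400 sequences, five planted pairs at coupling 0.8.
    ``planted_pairs`` entries are (column_i, column_j, coupling) with 0-based
    disjoint columns and coupling in [0, 1].
    """

    L: int = 60
    n_seqs: int = 400
    planted_pairs: list = field(default_factory=lambda: [tuple(p) for p in _DEFAULT_PAIRS])
    background_alphabet_size: int = 6
    gap_rate: float = 0.02
    redundancy_rate: float = 0.0
    mutation_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.L < 4:
            raise ValueError("L must be >= 4")
        if self.n_seqs < 10:
            raise ValueError("n_seqs must be >= 10")
        if not (2 <= self.background_alphabet_size <= len(AMINO_ACIDS)):
            raise ValueError("background_alphabet_size must be in [2, 20]")
        for r in (self.gap_rate, self.redundancy_rate, self.mutation_rate):
            if not (0.0 <= r <= 1.0):
                raise ValueError("rates must lie in [0, 1]")
        cols: list[int] = []
        for i, j, c in self.planted_pairs:
            if not (0 <= i < self.L and 0 <= j < self.L and i != j):
                raise ValueError(f"planted pair ({i}, {j}) out of range for L={self.L}")
            if not (0.0 <= c <= 1.0):
                raise ValueError("coupling must lie in [0, 1]")
            cols.extend((i, j))
        if len(cols) != len(set(cols)):
            raise ValueError("planted pairs must occupy disjoint columns")


@dataclass
class SyntheticTruth:
    """A generated family plus its ground truth."""

    alignment: Alignment
    planted_pairs: list
    structure: StructureMap
    spec: SyntheticSpec

    def planted_column_pairs(self) -> set:
        return {(min(i, j), max(i, j)) for i, j, _ in self.planted_pairs}

    def planted_residue_pairs(self) -> set:
        """Planted pairs in 1-based canonical residue numbering.

        The canonical sequence is generated ungapped, so residue number is
        column index + 1.
        """
        return {(i + 1, j + 1) for i, j in self.planted_column_pairs()}


def _column_distribution(rng, size: int, concentration: float) -> tuple[np.ndarray, np.ndarray]:
    """A random alphabet (residue codes) and symbol frequencies for one column."""
    alphabet = rng.choice(len(AMINO_ACIDS), size=size, replace=False)
    probs = rng.dirichlet(np.full(size, concentration))
    return alphabet, probs


def generate(spec: SyntheticSpec) -> SyntheticTruth:
    """Generate the alignment and toy structure described by ``spec``.

    Background columns draw i.i.d. from a column-specific multinomial whose
    alphabet size varies between 2 and ``background_alphabet_size`` (flat
    Dirichlet frequencies), giving realistic entropy heterogeneity across
    columns. Planted base columns use at least 3 symbols with near-uniform
    frequencies so they comfortably pass the downstream entropy filter; the
    partner column copies a bijective image of the base symbol with
    probability c, else draws from its own background. The first sequence is
    the canonical: generated from the same distributions but never gapped or
    mutated.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    L, n = spec.L, spec.n_seqs
    planted_i = {i: (j, c) for i, j, c in spec.planted_pairs}
    planted_j = {j for _, j, _ in spec.planted_pairs}

    codes = np.empty((n, L), dtype=np.int16)
    col_alphabet: dict[int, np.ndarray] = {}
    col_probs: dict[int, np.ndarray] = {}
    for col in range(L):
        planted = col in planted_i or col in planted_j
        size = (
            max(3, min(4, spec.background_alphabet_size))
            if planted
            else int(rng.integers(2, spec.background_alphabet_size + 1))
        )
        concentration = 5.0 if planted else 1.0
        col_alphabet[col], col_probs[col] = _column_distribution(rng, size, concentration)

    # background draw for every column
    for col in range(L):
        draws = rng.choice(col_alphabet[col], size=n, p=col_probs[col])
        codes[:, col] = draws

    # planted coupling: column j copies a bijective image of column i
    for i, (j, c) in planted_i.items():
        src = col_alphabet[i]
        image = col_alphabet[j]
        mapping = dict(zip(src.tolist(), rng.permutation(image).tolist()))
        copy_mask = rng.random(n) < c
        mapped = np.array([mapping[s] for s in codes[:, i]])
        codes[copy_mask, j] = mapped[copy_mask]

    # redundant near-duplicates of earlier rows (phylogenetic oversampling)
    n_red = int(round(spec.redundancy_rate * n))
    if n_red:
        for row in range(max(2, n - n_red), n):
            src = int(rng.integers(1, row))  # never duplicate the canonical
            codes[row] = codes[src]
            mut = rng.random(L) < spec.mutation_rate
            for col in np.flatnonzero(mut):
                codes[row, col] = rng.choice(col_alphabet[col])

    # gaps per column; canonical (row 0) stays ungapped
    gapped = rng.random((n, L)) < spec.gap_rate
    gapped[0, :] = False

    records = []
    for row in range(n):
        chars = [
            "-" if gapped[row, col] else AMINO_ACIDS[codes[row, col]] for col in range(L)
        ]
        ident = "CANONICAL" if row == 0 else f"seq{row:04d}"
        records.append(SequenceRecord(ident, "".join(chars)))
    aln = Alignment(records, "CANONICAL")

    # toy structure: extended chain, planted partners pulled into contact
    coords = {p + 1: np.array([3.8 * p, 0.0, 0.0]) for p in range(L)}
    for i, (j, _) in planted_i.items():
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        radius = rng.uniform(3.5, CONTACT_THRESHOLD - 0.5)
        coords[j + 1] = coords[i + 1] + radius * direction
    structure = StructureMap(coords, chain_id="A", source_id="synthetic")

    return SyntheticTruth(aln, [tuple(p) for p in spec.planted_pairs], structure, spec)


def truth_recovery_report(truth: SyntheticTruth, sm, k: int) -> float:
    """Fraction of planted pairs among the top-k scoring eligible pairs."""
    planted = truth.planted_column_pairs()
    if k < len(planted):
        raise ValueError("k must be at least the number of planted pairs")
    top = set(sm.top_pairs(k))
    return len(planted & top) / len(planted)


def write_fixture(truth: SyntheticTruth, directory) -> dict:
    """Write FASTA + toy PDB + JSON truth manifest; returns the paths."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    fasta = directory / "synthetic.fasta"
    pdb = directory / "synthetic.pdb"
    manifest = directory / "truth.json"
    write_alignment(truth.alignment, fasta)
    write_pdb(truth.structure, pdb)
    with open(manifest, "w") as fh:
        json.dump(
            {
                "spec": asdict(truth.spec),
                "planted_pairs": [list(p) for p in truth.planted_pairs],
                "canonical_id": truth.alignment.canonical_id,
                "contact_threshold": CONTACT_THRESHOLD,
            },
            fh,
            indent=2,
        )
    return {"fasta": fasta, "pdb": pdb, "manifest": manifest}
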