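"""Alignment data model, I/O and sequence-level preprocessing.

A protein multiple sequence alignment (MSA) is held as an ordered list of
equal-length gapped sequences with one *canonical* record: the family member
with a known 3D structure, used for residue numbering and structural mapping.
Column statistics here (residue counts, gap fraction, entropy, pairwise joint
counts) are the raw material for every coupling scorer in
:mod:`coevnet.scoring`.

Conventions
-----------
* Gap character is ``'-'``; ``'.'`` is accepted on read and normalised.
* Ambiguous residues (``X``, ``B``, ``Z``, ``J``, ``O``, ``U``, ``*``) are
  treated as gaps for all counting purposes, so the counting alphabet is the
  twenty standard amino acids.
* Gapped rows are excluded pairwise: a row contributes to the joint counts of
  columns (i, j) only if it is ungapped at *both* columns.
* Entropies are in bits (log base 2). The base cancels in normalised mutual
  information and in z-scores, so this is a reporting choice only.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
#: residues mapped to integer codes 0..19; everything else counts as a gap
AA_TO_CODE = {aa: k for k, aa in enumerate(AMINO_ACIDS)}
N_AA = len(AMINO_ACIDS)


class AlignmentFormatError(ValueError):
    """Raised for ragged or otherwise malformed alignment input."""


class CanonicalIdError(ValueError):
    """Raised when the canonical identifier is missing or duplicated."""


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned sequence: an identifier and its gapped residue string."""

    identifier: str
    residues: str

    def __post_init__(self) -> None:
        if not self.identifier:
            raise ValueError("empty sequence identifier")
        if not self.residues:
            raise ValueError(f"empty residues for {self.identifier!r}")

    @property
    def ungapped_length(self) -> int:
        return len(self.residues) - self.residues.count(GAP)


def _normalise(seq: str) -> str:
    return seq.upper().replace(".", GAP)


class Alignment:
    """An MSA with a designated canonical record.

    Parameters
    ----------
    records
        Ordered sequence records, all of the same length.
    canonical_id
        Identifier of the canonical (structure-bearing) record; must occur
        exactly once among ``records``.
    """

    def __init__(self, records: Sequence[SequenceRecord], canonical_id: str):
        records = list(records)
        if len(records) < 2:
            raise AlignmentFormatError("an alignment needs at least 2 records")
        lengths = {len(r.residues) for r in records}
        if len(lengths) != 1:
            raise AlignmentFormatError(f"ragged alignment: lengths {sorted(lengths)}")
        (length,) = lengths
        if length < 2:
            raise AlignmentFormatError("alignment must have at least 2 columns")
        hits = [r for r in records if r.identifier == canonical_id]
        if len(hits) != 1:
            raise CanonicalIdError(
                f"canonical id {canonical_id!r} occurs {len(hits)} times (need exactly 1)"
            )
        self.records = records
        self.canonical_id = canonical_id
        self._matrix: np.ndarray | None = None

    # -- basic geometry ----------------------------------------------------
    @property
    def length(self) -> int:
        """Number of columns L."""
        return len(self.records[0].residues)

    @property
    def n_sequences(self) -> int:
        return len(self.records)

    @property
    def canonical(self) -> SequenceRecord:
        return next(r for r in self.records if r.identifier == self.canonical_id)

    def __len__(self) -> int:
        return self.n_sequences

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"<Alignment {self.n_sequences} seqs x {self.length} cols, "
            f"canonical={self.canonical_id!r}>"
        )

    # -- encodings ---------------------------------------------------------
    def to_matrix(self) -> np.ndarray:
        """Integer encoding, shape (n_sequences, L): 0..19 residues, -1 gap.

        Ambiguous residues encode as -1 (gap) so that all counting is over
        the twenty standard amino acids.
        """
        if self._matrix is None:
            lut = np.full(128, -1, dtype=np.int16)
            for aa, code in AA_TO_CODE.items():
                lut[ord(aa)] = code
            rows = [
                lut[np.frombuffer(r.residues.encode("ascii"), dtype=np.uint8)]
                for r in self.records
            ]
            self._matrix = np.vstack(rows)
            self._matrix.setflags(write=False)
        return self._matrix

    def canonical_residue_numbers(self) -> np.ndarray:
        """Per column: 1-based residue number in the ungapped canonical, or 0.

        Columns where the canonical sequence is gapped get 0 (they carry no
        residue number and are removed by the node filters downstream).
        """
        out = np.zeros(self.length, dtype=int)
        n = 0
        for i, ch in enumerate(self.canonical.residues):
            if ch != GAP:
                n += 1
                out[i] = n
        return out

    def subset(self, indices: Iterable[int]) -> "Alignment":
        """New alignment from record indices (canonical must be included)."""
        recs = [self.records[i] for i in indices]
        return Alignment(recs, self.canonical_id)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_alignment(path, fmt: str = "fasta", canonical_id: str | None = None) -> Alignment:
    """Read a FASTA or Stockholm alignment and designate the canonical record.

    Residues are upper-cased and ``'.'`` gaps normalised to ``'-'``.
    Ragged input raises :class:`AlignmentFormatError`; a missing or
    duplicated ``canonical_id`` raises :class:`CanonicalIdError`.
    """
    if fmt not in ("fasta", "stockholm"):
        raise ValueError(f"unsupported alignment format {fmt!r}")
    records = [
        SequenceRecord(rec.id, _normalise(str(rec.seq)))
        for rec in SeqIO.parse(str(path), fmt)
    ]
    if not records:
        raise AlignmentFormatError(f"no sequences parsed from {path}")
    if canonical_id is None:
        canonical_id = records[0].identifier
    return Alignment(records, canonical_id)


def write_alignment(aln: Alignment, path) -> None:
    """Write the alignment as FASTA."""
    seqs = [SeqRecord(Seq(r.residues), id=r.identifier, description="") for r in aln.records]
    SeqIO.write(seqs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Sequence-level preprocessing
# ---------------------------------------------------------------------------

def pairwise_identity(a: str, b: str) -> float:
    """Fractional identity over positions where both sequences are ungapped.

    Returns 0.0 when the two sequences share no ungapped positions.
    """
    matches = 0
    shared = 0
    for x, y in zip(a, b):
        if x != GAP and y != GAP:
            shared += 1
            if x == y:
                matches += 1
    return matches / shared if shared else 0.0


def filter_by_similarity(aln: Alignment, max_identity: float = 0.95) -> Alignment:
    """Remove redundant sequences sharing more than ``max_identity`` identity.

    Greedy deduplication: the canonical record is seeded first, then the
    remaining records are scanned in input order; a record is discarded if its
    fractional identity to any already-retained record exceeds the threshold.
    The output preserves the input record order and always keeps the
    canonical. Idempotent by construction.
    """
    if not (0.0 < max_identity <= 1.0):
        raise ValueError("max_identity must be in (0, 1]")
    canonical = aln.canonical
    kept: list[SequenceRecord] = [canonical]
    for rec in aln.records:
        if rec is canonical:
            continue
        if all(pairwise_identity(rec.residues, k.residues) <= max_identity for k in kept):
            kept.append(rec)
    keep_ids = {id(r) for r in kept}
    ordered = [r for r in aln.records if id(r) in keep_ids]
    return Alignment(ordered, aln.canonical_id)


def filter_by_length(
    records: Iterable[SequenceRecord],
    min_len: int = 0,
    max_len: int | None = None,
    canonical_id: str | None = None,
) -> list[SequenceRecord]:
    """Keep records whose *ungapped* length lies in [min_len, max_len].

    Bounds are inclusive; a record matching ``canonical_id`` is always kept.
    """
    if max_len is not None and min_len > max_len:
        raise ValueError("min_len must not exceed max_len")
    out = []
    for rec in records:
        if rec.identifier == canonical_id:
            out.append(rec)
            continue
        n = rec.ungapped_length
        if n >= min_len and (max_len is None or n <= max_len):
            out.append(rec)
    return out


# ---------------------------------------------------------------------------
# Column statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ColumnProfile:
    """Residue counts, gap fraction and entropy (bits) for one column."""

    column_index: int
    symbol_counts: dict = field(default_factory=dict)
    gap_fraction: float = 0.0
    entropy_bits: float = 0.0


def entropy_bits(counts: np.ndarray) -> float:
    """Shannon entropy in bits of a count vector (zeros ignored)."""
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def column_profile(aln: Alignment, i: int) -> ColumnProfile:
    """Profile column ``i``: counts over non-gap rows, gap fraction, entropy."""
    if not (0 <= i < aln.length):
        raise IndexError(f"column {i} out of range for L={aln.length}")
    col = aln.to_matrix()[:, i]
    valid = col >= 0
    counts = np.bincount(col[valid], minlength=N_AA)
    symbol_counts = {AMINO_ACIDS[k]: int(c) for k, c in enumerate(counts) if c > 0}
    gap_fraction = 1.0 - valid.sum() / len(col)
    return ColumnProfile(i, symbol_counts, float(gap_fraction), entropy_bits(counts))


def pair_counts(aln: Alignment, i: int, j: int) -> tuple[np.ndarray, int]:
    """Joint residue counts for columns (i, j) over pairwise-ungapped rows.

    Returns a 20x20 count table (rows indexed by column ``i``'s residue) and
    ``n_valid``, the number of rows ungapped at both columns. ``n_valid`` may
    be 0 (degenerate table: callers must handle).
    """
    if i == j:
        raise ValueError("pair_counts requires two distinct columns")
    m = aln.to_matrix()
    a, b = m[:, i], m[:, j]
    valid = (a >= 0) & (b >= 0)
    a, b = a[valid], b[valid]
    table = np.bincount(a * N_AA + b, minlength=N_AA * N_AA).reshape(N_AA, N_AA)
    return table, int(valid.sum())
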