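"""Shared fixtures: tiny hand-built alignments and the standard synthetic family."""

import numpy as np
import pytest

from coevnet import Alignment, SequenceRecord
from coevnet.synthetic import SyntheticSpec, generate


def aln_from_columns(columns, canonical_id="c0"):
    """Build an alignment from a list of column strings (rows read down)."""
    n = len(columns[0])
    rows = ["".join(col[r] for col in columns) for r in range(n)]
    records = [SequenceRecord(f"c{r}", rows[r]) for r in range(n)]
    return Alignment(records, canonical_id)


@pytest.fixture
def correlated_pair_aln():
    """Columns (A,A,R,R) / (L,L,K,K): perfectly correlated balanced binaries."""
    return aln_from_columns(["AARR", "LLKK"])


@pytest.fixture
def independent_pair_aln():
    """Columns (A,A,R,R) / (L,K,L,K): independent balanced binaries."""
    return aln_from_columns(["AARR", "LKLK"])


@pytest.fixture(scope="session")
def default_truth():
    """The standard study condition: L=60, n=400, five planted pairs at c=0.8."""
    return generate(SyntheticSpec())


@pytest.fixture(scope="session")
def strong_truth():
    """Deterministic planted pairs (c=1) at n=500 for exact-recovery checks."""
    spec = SyntheticSpec(n_seqs=500, planted_pairs=[(5, 20, 1.0), (10, 35, 1.0)], seed=11)
    return generate(spec)


def random_alignment(rng, n=12, L=8, gap_rate=0.1):
    """A small random gapped alignment with an ungapped canonical first row."""
    from coevnet.msa import AMINO_ACIDS

    rows = []
    for r in range(n):
        chars = []
        for _ in range(L):
            if r > 0 and rng.random() < gap_rate:
                chars.append("-")
            else:
                chars.append(AMINO_ACIDS[rng.integers(0, 20)])
        rows.append("".join(chars))
    records = [SequenceRecord(f"s{r}", rows[r]) for r in range(n)]
    return Alignment(records, "s0")
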