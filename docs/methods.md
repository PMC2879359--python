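# Methods

This note records the model, the defaults, the numerical conventions and the
deliberately open design choices behind `coevnet`.

## Counting conventions

All column statistics are computed over the twenty standard amino acids.
Gaps (`-`, with `.` normalised on read) and ambiguity codes (`X`, `B`, `Z`,
`J`, `O`, `U`) are excluded from counts rather than treated as a 21st
symbol; for a column *pair*, rows gapped at either column are excluded from
that pair's joint counts (pairwise deletion). Frequencies are raw maximum-
likelihood estimates — no pseudocounts. Entropies and MI are reported in
bits; the base cancels in NMI (a ratio) and in every z-scored quantity, so
this is a presentation choice with no effect on rankings.

## ZNMI

The background distribution of column *i* is the set {NMI(i,k) : k ≠ i over
eligible columns}, summarised by its mean μ_i and *population* (1/n)
standard deviation σ_i; population normalisation is used for every column
statistic because the z-scoring population is the complete set of pairs, not
a sample from a larger one. The pair (i,j) is z-scored against the Gaussian
*density product* N(μ_i, σ_i²)·N(μ_j, σ_j²) ∝ N(μ_ij, σ_ij²) with the
precision-weighted mean and harmonic variance given in the README. The
density product (rather than the moment-matched distribution of a product
of two random variables) is the form under which "closed under products"
holds exactly and under which a pair is significant precisely when it lies
far to the right of *both* column distributions; the alternative reading is
noted as rejected. Degenerate columns with σ = 0 are floored at σ = 1e−12
before any division.

MIp uses row means of MI and the grand mean over eligible unordered pairs;
an all-zero MI matrix yields MIp ≡ 0 by convention. Zres regresses MI on the
product of row means (ordinary least squares over eligible pairs), z-scores
the residual within each of the pair's two rows — the pair itself included
in its row population, which is not specified in the literature and is a
recorded choice — and multiplies the two z-scores, flipping the sign to
negative when both z-scores are negative so that "both below background"
never masquerades as a strong positive coupling. Rows with zero residual
variance score 0.

## Node filters

Three filters define graph eligibility, recomputed independently on every
half-alignment (each half has its own gap and entropy profile):

| filter | default | rationale |
|---|---|---|
| gap fraction | exclude > 0.10 | heavily gapped columns have unstable pair counts |
| entropy floor | exclude ≤ 0.2864 bits | entropy of a 95%/5% two-symbol column: at least ~5% of residues must vary for a co-fluctuation to be measurable; exposed as a knob because the appropriate floor depends on the log base and alphabet convention |
| canonical gap | exclude | such columns carry no residue number and cannot be mapped to structure |

## Pruning and consensus

MST uses Kruskal's algorithm on edges sorted by (−weight, u, v), so equal
weights resolve toward the lexicographically smaller node pair —
deterministic and order-stable, which matters because the resampling
framework compares edge sets across runs. TNm1/BNm1 use the same ordering.
Consensus edge identity is the unordered node pair; weights are ignored for
membership. The Jaccard index of two empty edge sets is defined as 1
(identity of emptiness).

## Reproducibility and accuracy

Reproducibility is Pearson correlation over the *union* of the two halves'
edges with absent edges weighted zero. The union definition keeps the
comparison on a fixed scale across splits and algorithms, at a price worth
stating plainly: pruned graphs retain only top-band weights, so two graphs
with nearly disjoint edge sets produce a correlation close to −1, and a
pure-noise scorer is therefore *strongly negative*, not zero (its edge sets
are almost disjoint and its retained weights nearly constant). Only
increases in reproducibility are meaningful; the magnitude of a negative
value is not. Splits whose weight vectors are constant (no variance) are
logged and recorded as missing.

Accuracy rescales each edge's Cβ distance by d_min and d_avg computed over
*all* mappable residue pairs — no sequence-separation exclusion — because
the zero point of the metric is defined by blind uniform pair-picking over
that same universe. Edge weights act as averaging weights; scorers that
produce negative weights (ZNMI, Zres, MIp) have their retained weights
shifted by −min + 1e−6 first, preserving invariance under uniform weight
*rescaling*. Glycines and residues missing a Cβ fall back to Cα. The first
PDB model is used.

## Split construction

Non-canonical sequences are shuffled with a per-split RNG seeded
master_seed + split_index and dealt alternately into two halves; with an odd
count, one sequence (uniform under the shuffle) sits out of that split. The
canonical sequence joins both halves and is counted in the amino-acid
frequencies of each half — it is a genuine member of each sub-alignment by
construction; whether the original framework counted it or used it for
numbering only is unknowable from the text, and the effect vanishes as
1/n_half. Scorer-level randomness (Rand) receives 2·split_seed and
2·split_seed + 1 for the two halves.

## Synthetic generator

The generator emulates exactly the features the pipeline is sensitive to:

- **entropy heterogeneity** — each background column draws its alphabet size
  uniformly from {2, …, background_alphabet_size (default 6)} and its symbol
  frequencies from a flat Dirichlet; this variation is what produces the
  column-moment bias of raw MI that ZNMI is designed to remove;
- **planted couplings** — for a pair (i, j, c), column j copies a *bijective
  image* of column i's symbol with probability c (covariation without
  identity, so conservation cannot mimic the signal); planted columns use
  3–4 symbols with concentrated Dirichlet frequencies so they sit safely
  above the entropy floor;
- **redundancy** — an optional fraction of rows are near-copies of earlier
  rows (point mutations at mutation_rate), mimicking phylogenetic
  oversampling; deduplication at 95% identity removes them;
- **gaps** — per-column i.i.d. gapping (default 2%); the canonical first row
  is never gapped or mutated, so planted columns are never lost to the
  canonical-gap filter;
- **toy structure** — residues on an extended 3.8 Å/residue chain, with each
  planted pair's second residue relocated within 6 Å of the first.

The default condition (L = 60, n = 400, five pairs at c = 0.8) is the
standard study condition used by the test suite and the acceptance script;
the deterministic-recovery checks use c = 1 at n = 500. What the generator
does **not** emulate: a real phylogeny (rows are exchangeable), alignment
error, Potts-style higher-order couplings, and realistic contact geometry.
Passing tests on these fixtures validate the pipeline's statistics — they do
not certify performance on real families, where phylogenetic structure is
the dominant confounder.

## Problem sizes

The ensemble runs used by the tests and the acceptance script are 50–150
splits of the 400-sequence synthetic family; scoring one half (200
sequences, 60 columns, 1770 pairs) takes ~50 ms, a 150-split ZNMI ensemble
~20 s on one core. Published-scale alignments (765–2476 sequences, hundreds
of columns) run through the identical code path; only the inputs grow.

## Known limitations

- ELSC, oSCA, nSCA and McBASC scorers are out of scope (their definitions
  live in primary literature not reimplemented here); the scorer registry
  accepts additions.
- Community detection on the consensus network is deliberately absent;
  modularity maximisation is known to be unproductive on these dense,
  low-dynamic-range graphs.
- Structure mapping assumes PDB residue numbers equal canonical ungapped
  positions (true of the generated fixtures; real structures may need
  renumbering upstream).
- mmCIF input and multi-chain/assembly distance analysis are not supported.
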