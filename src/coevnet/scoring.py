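"""Column-pair coupling scorers for multiple sequence alignments.

Implements the information-theoretic family of coevolution scores:

``mi``
    Mutual information between the residue distributions of two columns,
    MI(i,j) = sum p(x,y) log2 [p(x,y) / (p(x) p(y))], estimated from the rows
    ungapped at both columns.
``nmi``
    MI normalised by the joint entropy H(i,j) of the same rows; lies in
    [0, 1] and corrects for column alphabet size.
``znmi``
    Z-scored-product NMI. Each column's background NMI distribution
    {NMI(i,k), k != i} is approximated as a Gaussian N(mu_i, sigma_i^2). The
    product of the two column densities is again Gaussian with

        mu_ij    = (mu_i sigma_j^2 + mu_j sigma_i^2) / (sigma_i^2 + sigma_j^2)
        sigma_ij = sigma_i sigma_j / sqrt(sigma_i^2 + sigma_j^2)

    and ZNMI(i,j) = (NMI(i,j) - mu_ij) / sigma_ij: how far a pair sits in the
    tails of *both* of its columns' background distributions.
``mip``
    Average-product correction: MI(i,j) - mu_i mu_j / <MI> with mu the row
    means of MI and <MI> the grand mean over eligible pairs.
``zres``
    Residuals of the regression of MI(i,j) on mu_i mu_j, z-scored within each
    of the two rows; the score is the product of the two z-scores, forced
    negative when both z-scores are negative.
``omes``
    Observed-minus-expected-squared chi-square-style statistic,
    sum (N_obs - N_exp)^2 / n_valid.
``rand``
    I.i.d. Uniform[0, 1) scores: the null baseline.

All scorers return a symmetric :class:`ScoreMatrix` over the eligible
columns; entries touching ineligible columns (and the diagonal) are NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .msa import N_AA, Alignment

#: floor applied to column standard deviations before any division
SIGMA_FLOOR = 1e-12


class DegenerateScoreError(ValueError):
    """Raised when too few eligible columns exist for a scorer."""


@dataclass
class ScoreMatrix:
    """Symmetric L x L column-pair scores with an eligibility mask.

    ``scores[i, j]`` is NaN on the diagonal and wherever either column is
    ineligible. ``method`` names the scorer; ``meta`` records seeds etc.
    """

    method: str
    scores: np.ndarray
    eligible: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.eligible = np.asarray(self.eligible, dtype=bool)
        if self.scores.shape != (self.L, self.L):
            raise ValueError("scores must be square and match the mask length")

    @property
    def L(self) -> int:
        return len(self.eligible)

    def pair_index(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (ii, jj) of eligible unordered pairs, i < j."""
        idx = np.flatnonzero(self.eligible)
        ii, jj = np.meshgrid(idx, idx, indexing="ij")
        keep = ii < jj
        return ii[keep], jj[keep]

    def pair_values(self) -> np.ndarray:
        ii, jj = self.pair_index()
        return self.scores[ii, jj]

    def top_pairs(self, k: int) -> list[tuple[int, int]]:
        """The k highest-scoring eligible pairs, ties broken by (i, j)."""
        ii, jj = self.pair_index()
        vals = self.scores[ii, jj]
        order = np.lexsort((jj, ii, -vals))
        return [(int(ii[o]), int(jj[o])) for o in order[:k]]


def _check_mask(aln: Alignment, mask: np.ndarray | None, minimum: int = 2) -> np.ndarray:
    if mask is None:
        mask = np.ones(aln.length, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (aln.length,):
        raise ValueError("eligibility mask length must equal alignment length")
    if mask.sum() < minimum:
        raise DegenerateScoreError(f"need >= {minimum} eligible columns, have {mask.sum()}")
    return mask


def _mi_joint_entropy(aln: Alignment, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """MI and joint entropy (bits) for every eligible pair; NaN elsewhere.

    Works on the integer-encoded alignment; rows gapped (or ambiguous) at
    either column are excluded from that pair's counts. Pairs with no valid
    rows score MI = 0 with joint entropy 0.
    """
    m = aln.to_matrix()
    L = aln.length
    mi = np.full((L, L), np.nan)
    hj = np.full((L, L), np.nan)
    idx = np.flatnonzero(mask)
    cols = [m[:, i] for i in idx]
    valids = [c >= 0 for c in cols]
    for a_pos, i in enumerate(idx):
        ai, vi = cols[a_pos], valids[a_pos]
        for b_pos in range(a_pos + 1, len(idx)):
            j = idx[b_pos]
            bj, vj = cols[b_pos], valids[b_pos]
            v = vi & vj
            n = int(v.sum())
            if n == 0:
                mi[i, j] = mi[j, i] = 0.0
                hj[i, j] = hj[j, i] = 0.0
                continue
            joint = np.bincount(ai[v] * N_AA + bj[v], minlength=N_AA * N_AA)
            pj = joint[joint > 0] / n
            h_joint = float(-(pj * np.log2(pj)).sum())
            px = np.bincount(ai[v], minlength=N_AA) / n
            py = np.bincount(bj[v], minlength=N_AA) / n
            hx = float(-(px[px > 0] * np.log2(px[px > 0])).sum())
            hy = float(-(py[py > 0] * np.log2(py[py > 0])).sum())
            val = max(hx + hy - h_joint, 0.0)
            mi[i, j] = mi[j, i] = val
            hj[i, j] = hj[j, i] = h_joint
    return mi, hj


# ---------------------------------------------------------------------------
# Scorers
# ---------------------------------------------------------------------------

def score_mi(aln: Alignment, mask: np.ndarray | None = None) -> ScoreMatrix:
    """Mutual information (bits) for every eligible column pair."""
    mask = _check_mask(aln, mask)
    mi, _ = _mi_joint_entropy(aln, mask)
    return ScoreMatrix("mi", mi, mask)


def score_nmi(aln: Alignment, mask: np.ndarray | None = None) -> ScoreMatrix:
    """MI normalised by joint entropy; 0 where the joint entropy vanishes."""
    mask = _check_mask(aln, mask)
    mi, hj = _mi_joint_entropy(aln, mask)
    with np.errstate(invalid="ignore", divide="ignore"):
        nmi = np.where(hj > 0, mi / np.where(hj > 0, hj, 1.0), 0.0)
    nmi[np.isnan(mi)] = np.nan
    return ScoreMatrix("nmi", nmi, mask)


def column_score_stats(sm: ScoreMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-column mean and population std of the off-diagonal eligible scores.

    Row i's background distribution is {score(i, k) : k != i, k eligible}.
    NaN for ineligible columns. Requires at least 3 eligible columns so each
    distribution has at least two points.
    """
    if sm.eligible.sum() < 3:
        raise DegenerateScoreError("column score statistics need >= 3 eligible columns")
    idx = np.flatnonzero(sm.eligible)
    sub = sm.scores[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub, np.nan)
    mu = np.full(sm.L, np.nan)
    sigma = np.full(sm.L, np.nan)
    mu[idx] = np.nanmean(sub, axis=1)
    sigma[idx] = np.nanstd(sub, axis=1)  # population (1/n) normalisation
    return mu, sigma


# Backwards-friendly alias used when the input is an NMI matrix.
column_nmi_stats = column_score_stats


def znmi_product_gaussian(
    mu_i: float, sigma_i: float, mu_j: float, sigma_j: float
) -> tuple[float, float]:
    """Parameters of the product of two Gaussian densities.

    The product density N(mu_i, sigma_i^2) * N(mu_j, sigma_j^2) is (up to
    normalisation) Gaussian with precision-weighted mean and harmonic
    variance; sigma_ij <= min(sigma_i, sigma_j) and mu_ij lies between the
    two means. Zero sigmas are floored at :data:`SIGMA_FLOOR`.
    """
    si = max(float(sigma_i), SIGMA_FLOOR)
    sj = max(float(sigma_j), SIGMA_FLOOR)
    vi, vj = si * si, sj * sj
    mu = (mu_i * vj + mu_j * vi) / (vi + vj)
    sigma = math.sqrt(vi * vj / (vi + vj))
    return mu, sigma


def score_znmi(aln: Alignment, mask: np.ndarray | None = None) -> ScoreMatrix:
    """Z-scored-product normalised mutual information.

    For each eligible pair (i, j): approximate both columns' background NMI
    distributions as Gaussians, form the product Gaussian, and z-score
    NMI(i, j) against it. Scores may be negative.
    """
    mask = _check_mask(aln, mask, minimum=3)
    nmi = score_nmi(aln, mask)
    mu, sigma = column_score_stats(nmi)
    sigma = np.maximum(sigma, SIGMA_FLOOR)
    var = sigma * sigma
    idx = np.flatnonzero(mask)
    out = np.full_like(nmi.scores, np.nan)
    vi = var[idx][:, None]
    vj = var[idx][None, :]
    mu_i = mu[idx][:, None]
    mu_j = mu[idx][None, :]
    mu_prod = (mu_i * vj + mu_j * vi) / (vi + vj)
    sigma_prod = np.sqrt(vi * vj / (vi + vj))
    z = (nmi.scores[np.ix_(idx, idx)] - mu_prod) / sigma_prod
    out[np.ix_(idx, idx)] = z
    np.fill_diagonal(out, np.nan)
    return ScoreMatrix("znmi", out, mask)


def score_mip(aln: Alignment, mask: np.ndarray | None = None) -> ScoreMatrix:
    """MI with the average-product correction subtracted.

    MIp(i,j) = MI(i,j) - mu_i mu_j / <MI>, with mu_i the mean MI of column i
    against all other eligible columns and <MI> the mean over all eligible
    unordered pairs. Identically 0 when <MI> = 0.
    """
    mask = _check_mask(aln, mask, minimum=3)
    mi = score_mi(aln, mask)
    mu, _ = column_score_stats(mi)
    mean_mi = float(np.mean(mi.pair_values()))
    idx = np.flatnonzero(mask)
    out = np.full_like(mi.scores, np.nan)
    if mean_mi == 0.0:
        out[np.ix_(idx, idx)] = 0.0
    else:
        apc = mu[idx][:, None] * mu[idx][None, :] / mean_mi
        out[np.ix_(idx, idx)] = mi.scores[np.ix_(idx, idx)] - apc
    np.fill_diagonal(out, np.nan)
    return ScoreMatrix("mip", out, mask)


def score_zres(aln: Alignment, mask: np.ndarray | None = None) -> ScoreMatrix:
    """Z-scored residual mutual information.

    Fits MI(i,j) ~ a + b * (mu_i mu_j) by least squares over all eligible
    pairs, z-scores the residual r_ij within row i and within row j
    (population sigma, the pair itself included), and returns the product of
    the two z-scores with the both-negative case forced negative.
    """
    mask = _check_mask(aln, mask, minimum=3)
    mi = score_mi(aln, mask)
    mu, _ = column_score_stats(mi)
    ii, jj = mi.pair_index()
    x = mu[ii] * mu[jj]
    y = mi.scores[ii, jj]
    if np.ptp(x) == 0.0:
        b, a = 0.0, float(np.mean(y))
    else:
        b, a = np.polyfit(x, y, 1)
    idx = np.flatnonzero(mask)
    resid = np.full_like(mi.scores, np.nan)
    sub_mu = mu[idx][:, None] * mu[idx][None, :]
    resid[np.ix_(idx, idx)] = mi.scores[np.ix_(idx, idx)] - (a + b * sub_mu)
    np.fill_diagonal(resid, np.nan)

    sub = resid[np.ix_(idx, idx)]
    row_mu = np.nanmean(sub, axis=1)
    row_sd = np.nanstd(sub, axis=1)
    z = np.full_like(sub, np.nan)
    ok = row_sd > 0
    z[ok, :] = (sub[ok, :] - row_mu[ok, None]) / row_sd[ok, None]
    z[~ok, :] = 0.0  # zero residual variance in a row -> its pairs score 0

    prod = z * z.T
    both_neg = (z < 0) & (z.T < 0)
    prod = np.where(both_neg, -prod, prod)
    out = np.full_like(mi.scores, np.nan)
    out[np.ix_(idx, idx)] = prod
    np.fill_diagonal(out, np.nan)
    return ScoreMatrix("zres", out, mask)


def score_omes(aln: Alignment, mask: np.ndarray | None = None) -> ScoreMatrix:
    """Observed-minus-expected-squared covariation score.

    OMES(i,j) = sum_xy (N_obs(x,y) - N_exp(x,y))^2 / n_valid with
    N_exp(x,y) = count_x count_y / n_valid, all over the pairwise-ungapped
    rows. Pairs with no valid rows score 0.
    """
    mask = _check_mask(aln, mask)
    m = aln.to_matrix()
    L = aln.length
    out = np.full((L, L), np.nan)
    idx = np.flatnonzero(mask)
    for a_pos, i in enumerate(idx):
        ai = m[:, i]
        vi = ai >= 0
        for b_pos in range(a_pos + 1, len(idx)):
            j = idx[b_pos]
            bj = m[:, j]
            v = vi & (bj >= 0)
            n = int(v.sum())
            if n == 0:
                out[i, j] = out[j, i] = 0.0
                continue
            obs = np.bincount(ai[v] * N_AA + bj[v], minlength=N_AA * N_AA).reshape(
                N_AA, N_AA
            )
            cx = obs.sum(axis=1)
            cy = obs.sum(axis=0)
            exp = np.outer(cx, cy) / n
            out[i, j] = out[j, i] = float(((obs - exp) ** 2).sum() / n)
    return ScoreMatrix("omes", out, mask)


def score_rand(
    aln: Alignment, mask: np.ndarray | None = None, seed: int = 0
) -> ScoreMatrix:
    """Null scorer: i.i.d. Uniform[0, 1) pair scores, reproducible from seed."""
    mask = _check_mask(aln, mask)
    rng = np.random.default_rng(seed)
    L = aln.length
    upper = rng.random((L, L))
    out = np.full((L, L), np.nan)
    iu, ju = np.triu_indices(L, k=1)
    out[iu, ju] = upper[iu, ju]
    out[ju, iu] = upper[iu, ju]
    ineligible = ~mask
    out[ineligible, :] = np.nan
    out[:, ineligible] = np.nan
    return ScoreMatrix("rand", out, mask, meta={"seed": seed})


#: scorer registry used by the resampling driver and the CLI.
SCORERS: dict[str, Callable[..., ScoreMatrix]] = {
    "mi": score_mi,
    "nmi": score_nmi,
    "znmi": score_znmi,
    "mip": score_mip,
    "zres": score_zres,
    "omes": score_omes,
    "rand": score_rand,
}


def compute_scores(
    aln: Alignment, method: str, mask: np.ndarray | None = None, seed: int | None = None
) -> ScoreMatrix:
    """Dispatch to a registered scorer by name."""
    try:
        fn = SCORERS[method]
    except KeyError:
        raise KeyError(
            f"unknown scorer {method!r}; registered: {sorted(SCORERS)}"
        ) from None
    if method == "rand":
        return fn(aln, mask, seed=0 if seed is None else seed)
    return fn(aln, mask)


# ---------------------------------------------------------------------------
# Column-moment diagnostics
# ---------------------------------------------------------------------------

def moment_correlation(sm: ScoreMatrix, moment: str = "mean") -> float:
    """Pearson correlation of pair scores with a column-moment product.

    For each eligible column i, compute m_i = mean (or population std) of
    {score(i,k)}; the diagnostic is the correlation between score(i,j) and
    m_i * m_j over all eligible pairs. Large values indicate the column bias
    that NMI/ZNMI are designed to remove.
    """
    if moment not in ("mean", "std"):
        raise ValueError("moment must be 'mean' or 'std'")
    mu, sigma = column_score_stats(sm)
    m = mu if moment == "mean" else sigma
    ii, jj = sm.pair_index()
    x = sm.scores[ii, jj]
    y = m[ii] * m[jj]
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise DegenerateScoreError("moment correlation undefined: zero variance")
    return float(np.corrcoef(x, y)[0, 1])


# ---------------------------------------------------------------------------
# Score matrix I/O (TSV with a commented metadata header)
# ---------------------------------------------------------------------------

def write_scores_tsv(sm: ScoreMatrix, path, residue_numbers: np.ndarray | None = None) -> None:
    """Write eligible pair scores as TSV (col_i, col_j, score).

    ``residue_numbers`` (per-column canonical numbering) relabels columns if
    given; a commented header records the method and any metadata.
    """
    ii, jj = sm.pair_index()
    vals = sm.scores[ii, jj]
    with open(path, "w") as fh:
        fh.write(f"# method={sm.method}\n")
        for k, v in sorted(sm.meta.items()):
            fh.write(f"# {k}={v}\n")
        fh.write("col_i\tcol_j\tscore\n")
        for i, j, v in zip(ii, jj, vals):
            a = int(residue_numbers[i]) if residue_numbers is not None else int(i)
            b = int(residue_numbers[j]) if residue_numbers is not None else int(j)
            fh.write(f"{a}\t{b}\t{v:.10g}\n")
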