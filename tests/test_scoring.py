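"""Coupling scorers: analytic cases, brute-force oracles, invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coevnet import (
    moment_correlation,
    pair_counts,
    score_mi,
    score_mip,
    score_nmi,
    score_omes,
    score_rand,
    score_znmi,
    score_zres,
    znmi_product_gaussian,
)
from coevnet.scoring import DegenerateScoreError, ScoreMatrix, column_score_stats
from coevnet.synthetic import SyntheticSpec, generate

from conftest import aln_from_columns, random_alignment


def direct_mi_bits(table, n):
    """Independent oracle: direct summation of p log2 p/(pq) over the table."""
    total = 0.0
    px = table.sum(axis=1) / n
    py = table.sum(axis=0) / n
    for x in range(table.shape[0]):
        for y in range(table.shape[1]):
            if table[x, y]:
                p = table[x, y] / n
                total += p * math.log2(p / (px[x] * py[y]))
    return total


# ---------------------------------------------------------------------------
# MI / NMI
# ---------------------------------------------------------------------------

class TestMI:
    def test_perfectly_correlated_binary_columns(self, correlated_pair_aln):
        sm = score_mi(correlated_pair_aln)
        assert sm.scores[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_independent_balanced_columns(self, independent_pair_aln):
        sm = score_mi(independent_pair_aln)
        assert sm.scores[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_six_row_toy_against_direct_summation(self):
        # joint counts {AL:3, AK:1, RL:1, RK:1}
        aln = aln_from_columns(["AAAARR", "LLLKLK"])
        table, n = pair_counts(aln, 0, 1)
        assert n == 6
        expected = direct_mi_bits(table, n)
        assert score_mi(aln).scores[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_symmetric_and_nonnegative(self):
        aln = random_alignment(np.random.default_rng(7), n=20, L=6, gap_rate=0.1)
        s = score_mi(aln).scores
        valid = ~np.isnan(s)
        assert np.allclose(s[valid], s.T[valid])
        assert (s[valid] >= 0).all()


class TestNMI:
    def test_perfect_correlation_gives_one(self, correlated_pair_aln):
        assert score_nmi(correlated_pair_aln).scores[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_independence_gives_zero(self, independent_pair_aln):
        assert score_nmi(independent_pair_aln).scores[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_constant_columns_zero_by_convention(self):
        aln = aln_from_columns(["AAAA", "LLLL"])
        assert score_nmi(aln).scores[0, 1] == 0.0

    def test_bounded_by_unit_interval(self):
        aln = random_alignment(np.random.default_rng(3), n=25, L=7, gap_rate=0.1)
        vals = score_nmi(aln).pair_values()
        assert ((vals >= -1e-12) & (vals <= 1 + 1e-12)).all()


# ---------------------------------------------------------------------------
# Column statistics and the product Gaussian
# ---------------------------------------------------------------------------

class TestColumnStats:
    def test_two_point_population_stats(self):
        scores = np.full((3, 3), np.nan)
        scores[0, 1] = scores[1, 0] = 0.2
        scores[0, 2] = scores[2, 0] = 0.4
        scores[1, 2] = scores[2, 1] = 0.9
        sm = ScoreMatrix("nmi", scores, np.ones(3, bool))
        mu, sigma = column_score_stats(sm)
        assert mu[0] == pytest.approx(0.3, abs=1e-12)
        assert sigma[0] == pytest.approx(0.1, abs=1e-12)

    def test_constant_row_zero_sigma(self):
        scores = np.full((3, 3), 0.5)
        np.fill_diagonal(scores, np.nan)
        sm = ScoreMatrix("nmi", scores, np.ones(3, bool))
        mu, sigma = column_score_stats(sm)
        assert np.allclose(mu[np.isfinite(mu)], 0.5) and np.allclose(sigma, 0.0)

    def test_agrees_with_brute_force_per_row(self):
        rng = np.random.default_rng(0)
        raw = rng.random((6, 6))
        scores = (raw + raw.T) / 2
        np.fill_diagonal(scores, np.nan)
        sm = ScoreMatrix("x", scores, np.ones(6, bool))
        mu, sigma = column_score_stats(sm)
        for i in range(6):
            row = [scores[i, k] for k in range(6) if k != i]
            assert mu[i] == pytest.approx(np.mean(row), abs=1e-12)
            assert sigma[i] == pytest.approx(np.std(row), abs=1e-12)

    def test_too_few_columns_is_degenerate(self):
        sm = ScoreMatrix("x", np.full((3, 3), np.nan), np.array([True, True, False]))
        with pytest.raises(DegenerateScoreError):
            column_score_stats(sm)


class TestProductGaussian:
    def test_symmetric_inputs(self):
        mu, sigma = znmi_product_gaussian(0.3, 0.2, 0.3, 0.2)
        assert mu == pytest.approx(0.3, abs=1e-15)
        assert sigma == pytest.approx(0.2 / math.sqrt(2), abs=1e-15)

    def test_closed_form_worked_case(self):
        mu, sigma = znmi_product_gaussian(0.2, 0.1, 0.4, 0.1)
        assert mu == pytest.approx(0.3, abs=1e-12)
        assert sigma == pytest.approx(0.1 / math.sqrt(2), abs=1e-12)

    def test_flat_factor_limit(self):
        mu, sigma = znmi_product_gaussian(0.2, 0.1, 0.9, 1e6)
        assert mu == pytest.approx(0.2, abs=1e-9)
        assert sigma == pytest.approx(0.1, abs=1e-9)

    @settings(max_examples=50, deadline=None)
    @given(
        st.floats(0, 1), st.floats(1e-6, 1), st.floats(0, 1), st.floats(1e-6, 1)
    )
    def test_contraction_properties(self, mi, si, mj, sj):
        mu, sigma = znmi_product_gaussian(mi, si, mj, sj)
        assert sigma <= min(si, sj) + 1e-12
        assert min(mi, mj) - 1e-12 <= mu <= max(mi, mj) + 1e-12


class TestZNMI:
    def test_zero_at_the_product_mean(self):
        mu, sigma = znmi_product_gaussian(0.2, 0.1, 0.4, 0.1)
        assert (mu - mu) / sigma == 0.0  # NMI exactly at mu_ij

    def test_worked_z_score(self):
        mu, sigma = znmi_product_gaussian(0.2, 0.1, 0.4, 0.1)
        z = (0.44 - mu) / sigma
        assert z == pytest.approx(1.4 * math.sqrt(2), abs=1e-9)

    def test_matrix_matches_per_pair_closed_form(self):
        aln = random_alignment(np.random.default_rng(5), n=30, L=6, gap_rate=0.05)
        nmi = score_nmi(aln)
        mu, sigma = column_score_stats(nmi)
        z = score_znmi(aln)
        for i in range(6):
            for j in range(i + 1, 6):
                m, s = znmi_product_gaussian(mu[i], sigma[i], mu[j], sigma[j])
                assert z.scores[i, j] == pytest.approx(
                    (nmi.scores[i, j] - m) / s, rel=1e-9
                )

    def test_planted_deterministic_pair_ranks_first(self):
        spec = SyntheticSpec(n_seqs=500, planted_pairs=[(7, 40, 1.0)], seed=4)
        truth = generate(spec)
        sm = score_znmi(truth.alignment)
        assert sm.top_pairs(1) == [(7, 40)]


# ---------------------------------------------------------------------------
# MIp
# ---------------------------------------------------------------------------

class TestMIp:
    def test_constant_mi_matrix_gives_zero(self):
        # four mutually perfectly-correlated balanced binary columns:
        # every pair has MI = 1 bit, so MIp = 1 - 1*1/1 = 0 everywhere
        aln = aln_from_columns(["AARR", "LLKK", "FFYY", "DDEE"])
        vals = score_mip(aln).pair_values()
        assert np.allclose(vals, 0.0, atol=1e-12)

    def test_all_constant_columns_convention(self):
        aln = aln_from_columns(["AAAA", "LLLL", "KKKK"])
        assert np.allclose(score_mip(aln).pair_values(), 0.0)

    def test_matches_direct_formula_on_random_alignment(self):
        aln = random_alignment(np.random.default_rng(9), n=25, L=5, gap_rate=0.0)
        mi = score_mi(aln).scores
        mip = score_mip(aln).scores
        mean_mi = np.nanmean(mi[np.triu_indices(5, 1)])
        for i in range(5):
            for j in range(i + 1, 5):
                mu_i = np.nanmean([mi[i, k] for k in range(5) if k != i])
                mu_j = np.nanmean([mi[j, k] for k in range(5) if k != j])
                assert mip[i, j] == pytest.approx(
                    mi[i, j] - mu_i * mu_j / mean_mi, abs=1e-12
                )


# ---------------------------------------------------------------------------
# Zres
# ---------------------------------------------------------------------------

class TestZres:
    def test_sign_rules(self):
        # both-negative pairs flip to negative; both-positive stay positive
        z_i, z_j = -2.0, -1.5
        prod = z_i * z_j
        assert (-prod if (z_i < 0 and z_j < 0) else prod) == -3.0
        z_i, z_j = 2.0, 1.5
        assert (-prod if (z_i < 0 and z_j < 0) else prod) == 3.0

    def test_matches_independent_least_squares_recomputation(self):
        aln = random_alignment(np.random.default_rng(21), n=30, L=5, gap_rate=0.0)
        mi = score_mi(aln).scores
        zres = score_zres(aln).scores

        # oracle: explicit regression + two-sided z-scoring
        mu = np.array([np.nanmean([mi[i, k] for k in range(5) if k != i]) for i in range(5)])
        xs, ys = [], []
        for i in range(5):
            for j in range(i + 1, 5):
                xs.append(mu[i] * mu[j])
                ys.append(mi[i, j])
        b, a = np.polyfit(xs, ys, 1)
        resid = np.full((5, 5), np.nan)
        for i in range(5):
            for j in range(5):
                if i != j:
                    resid[i, j] = mi[i, j] - (a + b * mu[i] * mu[j])
        for i in range(5):
            for j in range(i + 1, 5):
                row_i = [resid[i, k] for k in range(5) if k != i]
                row_j = [resid[j, k] for k in range(5) if k != j]
                zi = (resid[i, j] - np.mean(row_i)) / np.std(row_i)
                zj = (resid[i, j] - np.mean(row_j)) / np.std(row_j)
                expect = -abs(zi * zj) if (zi < 0 and zj < 0) else zi * zj
                assert zres[i, j] == pytest.approx(expect, rel=1e-9, abs=1e-12)

    def test_symmetric(self):
        aln = random_alignment(np.random.default_rng(2), n=25, L=6, gap_rate=0.05)
        s = score_zres(aln).scores
        valid = ~np.isnan(s)
        assert np.allclose(s[valid], s.T[valid])


# ---------------------------------------------------------------------------
# OMES / Rand
# ---------------------------------------------------------------------------

class TestOMES:
    def test_independent_balanced_columns_zero(self, independent_pair_aln):
        assert score_omes(independent_pair_aln).scores[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_worked_four_sequence_case(self, correlated_pair_aln):
        # four cells with (obs-exp)^2 = 1 each, n_valid = 4 -> OMES = 1.0
        assert score_omes(correlated_pair_aln).scores[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_gapped_row_excluded_from_observed_and_expected(self):
        aln = aln_from_columns(["AARR", "LLK-"])
        table, n = pair_counts(aln, 0, 1)
        assert n == 3
        obs = table
        cx, cy = obs.sum(axis=1), obs.sum(axis=0)
        exp = np.outer(cx, cy) / n
        expected = ((obs - exp) ** 2).sum() / n
        assert score_omes(aln).scores[0, 1] == pytest.approx(expected, abs=1e-12)


class TestRand:
    def test_seed_reproducibility_and_range(self):
        aln = aln_from_columns(["AARR", "LLKK", "FFYY"])
        a = score_rand(aln, seed=42).scores
        b = score_rand(aln, seed=42).scores
        c = score_rand(aln, seed=43).scores
        va = a[np.triu_indices(3, 1)]
        assert np.array_equal(a[~np.isnan(a)], b[~np.isnan(b)])
        assert ((va >= 0) & (va < 1)).all()
        assert not np.array_equal(va, c[np.triu_indices(3, 1)])


# ---------------------------------------------------------------------------
# Column-moment diagnostics
# ---------------------------------------------------------------------------

class TestMomentCorrelation:
    def test_exact_product_structure_gives_unit_correlation(self):
        # score(i,j) = m_i * m_j by construction -> correlation 1
        m = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        scores = np.outer(m, m).astype(float)
        np.fill_diagonal(scores, np.nan)
        sm = ScoreMatrix("x", scores, np.ones(5, bool))
        # row moments of a rank-one product matrix track the generating
        # vector only approximately (each row mean excludes its own entry),
        # so the correlation is near, not exactly, 1
        assert moment_correlation(sm, "mean") > 0.99

    def test_matches_direct_recomputation(self):
        rng = np.random.default_rng(17)
        raw = rng.random((7, 7))
        scores = (raw + raw.T) / 2
        np.fill_diagonal(scores, np.nan)
        sm = ScoreMatrix("x", scores, np.ones(7, bool))
        for moment, fn in (("mean", np.mean), ("std", np.std)):
            m = np.array(
                [fn([scores[i, k] for k in range(7) if k != i]) for i in range(7)]
            )
            xs, ys = [], []
            for i in range(7):
                for j in range(i + 1, 7):
                    xs.append(scores[i, j])
                    ys.append(m[i] * m[j])
            expect = np.corrcoef(xs, ys)[0, 1]
            assert moment_correlation(sm, moment) == pytest.approx(expect, abs=1e-12)

    def test_znmi_reduces_column_bias_relative_to_mi(self, default_truth):
        aln = default_truth.alignment
        mi = score_mi(aln)
        znmi = score_znmi(aln)
        for moment in ("mean", "std"):
            assert abs(moment_correlation(znmi, moment)) < abs(
                moment_correlation(mi, moment)
            )
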