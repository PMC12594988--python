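import numpy as np
import pytest

from conftest import random_dna
from oracles import enumerate_score_pmf
from motifbench.background import (
    BackgroundModel,
    UNIFORM_BACKGROUND,
    best_hit_pvalue,
    discretize_cells,
    fit_background,
    pseudo_auroc,
    pvalue_of_score,
    quantize_weights,
    score_distribution,
    score_of_pvalue,
)
from motifbench.motifs import FrequencyMatrix, WeightMatrix, pfm_to_pwm
from motifbench.scanning import best_hit


def random_background(rng, order):
    if order == 0:
        return BackgroundModel(0, rng.dirichlet(np.ones(4)))
    return BackgroundModel(
        1, rng.dirichlet(np.ones(4)), rng.dirichlet(np.ones(4), size=4)
    )


class TestFitBackground:
    def test_single_acgt_is_uniform(self):
        bg = fit_background(["ACGT"], order=0)
        np.testing.assert_allclose(bg.base_freqs, 0.25)

    def test_homopolymer_transition_near_one(self):
        bg = fit_background(["A" * 200], order=1)
        assert bg.transitions[0, 0] > 0.95  # add-one smoothing keeps it < 1
        assert bg.transitions[0, 0] < 1.0

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            fit_background([], order=0)

    def test_simulation_round_trip(self, rng):
        # dinucleotide frequencies of a sequence generated from the fitted
        # model match the model within 3 standard errors
        bg = fit_background([random_dna(rng, 500) + "AAAATTTTGGGG" * 30], order=1)
        n = 200_000
        seq = np.empty(n, dtype=int)
        seq[0] = rng.choice(4, p=bg.base_freqs)
        for i in range(1, n):
            seq[i] = rng.choice(4, p=bg.transitions[seq[i - 1]])
        counts = np.zeros((4, 4))
        np.add.at(counts, (seq[:-1], seq[1:]), 1)
        est = counts / counts.sum(axis=1, keepdims=True)
        row_n = counts.sum(axis=1, keepdims=True)
        se = np.sqrt(bg.transitions * (1 - bg.transitions) / row_n)
        assert np.all(np.abs(est - bg.transitions) < 3 * se + 1e-9)


class TestScoreDistribution:
    @pytest.mark.parametrize("order", [0, 1])
    @pytest.mark.parametrize("d", [1, 10, 100])
    def test_dp_equals_enumeration(self, rng, order, d):
        for _ in range(8):
            w = int(rng.integers(1, 7))
            weights = pfm_to_pwm(
                FrequencyMatrix(rng.dirichlet(np.ones(4), size=w)), 100
            )
            bg = random_background(rng, order)
            dist = score_distribution(weights, bg, d)
            expected = enumerate_score_pmf(discretize_cells(weights, d), bg)
            for s, p in expected.items():
                assert dist.pmf[s - dist.min_bin] == pytest.approx(p, abs=1e-12)
            assert dist.pmf.sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_matrix_point_mass(self):
        dist = score_distribution(WeightMatrix(np.zeros((4, 4))), UNIFORM_BACKGROUND)
        assert dist.pmf.size == 1
        assert pvalue_of_score(dist, 0.0) == 1.0

    def test_dinucleotide_with_identical_rows_reduces_to_iid(self, rng, random_weights):
        w = random_weights(4)
        base = rng.dirichlet(np.ones(4))
        bg0 = BackgroundModel(0, base)
        bg1 = BackgroundModel(1, base, np.tile(base, (4, 1)))
        d0 = score_distribution(w, bg0, 10)
        d1 = score_distribution(w, bg1, 10)
        assert d0.min_bin == d1.min_bin
        np.testing.assert_allclose(d0.pmf, d1.pmf, atol=1e-12)

    def test_length2_uniform_pvalues_are_word_fractions(self, rng, random_weights):
        w = random_weights(2)
        dist = score_distribution(w, UNIFORM_BACKGROUND, 10)
        cells = discretize_cells(w, 10)
        word_scores = [cells[0, a] + cells[1, b] for a in range(4) for b in range(4)]
        for t in sorted(set(word_scores)):
            expected = sum(s >= t for s in word_scores) / 16
            assert pvalue_of_score(dist, t / 10) == pytest.approx(expected, abs=1e-12)

    def test_refinement_toward_exact_pvalue(self, rng):
        # the discretized P-value approaches the exact word-level value as
        # d grows
        weights = pfm_to_pwm(
            FrequencyMatrix(np.random.default_rng(11).dirichlet(np.ones(4), size=4)),
            100,
        )
        mat = weights.matrix
        words = [(a, b, c, e) for a in range(4) for b in range(4)
                 for c in range(4) for e in range(4)]
        exact_scores = np.array(
            [mat[0, a] + mat[1, b] + mat[2, c] + mat[3, e] for a, b, c, e in words]
        )
        s = np.median(exact_scores)
        exact_p = (exact_scores >= s - 1e-12).mean()
        errors = []
        for d in (1, 10, 100, 1000):
            dist = score_distribution(weights, UNIFORM_BACKGROUND, d)
            errors.append(abs(pvalue_of_score(dist, s) - exact_p))
        assert errors[-1] <= errors[0]
        assert errors[-1] < 0.05


class TestPvalueConversions:
    def test_below_support_is_one(self, random_weights):
        w = random_weights(3)
        dist = score_distribution(w, UNIFORM_BACKGROUND, 10)
        assert pvalue_of_score(dist, dist.min_bin / 10 - 5) == 1.0

    def test_galois_connection(self, rng, random_weights):
        w = random_weights(5)
        dist = score_distribution(w, UNIFORM_BACKGROUND, 10)
        for p in rng.random(50):
            if p == 0:
                continue
            s = score_of_pvalue(dist, p)
            assert pvalue_of_score(dist, s) <= p + 1e-12

    def test_one_hot_max_score_pvalue(self):
        w = pfm_to_pwm(FrequencyMatrix([[1, 0, 0, 0]] * 3), 100)
        dist = score_distribution(w, UNIFORM_BACKGROUND, 10)
        assert pvalue_of_score(dist, dist.max_bin / 10) == pytest.approx(1 / 64)

    def test_invalid_pvalue_rejected(self, random_weights):
        dist = score_distribution(random_weights(3), UNIFORM_BACKGROUND, 10)
        for p in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                score_of_pvalue(dist, p)


class TestBestHitPvalue:
    def test_zero_window_pvalue_gives_zero(self, random_weights):
        w = random_weights(4)
        dist = score_distribution(w, UNIFORM_BACKGROUND, 100)
        huge = dist.max_bin / 100 + 1
        assert best_hit_pvalue(w, UNIFORM_BACKGROUND, 50, huge) == 0.0

    def test_length_equal_width_two_windows(self, random_weights):
        w = random_weights(4)
        dist = score_distribution(w, UNIFORM_BACKGROUND, 100)
        s = score_of_pvalue(dist, 0.3)
        p_win = pvalue_of_score(dist, s)
        expected = 1 - (1 - p_win) ** 2
        assert best_hit_pvalue(w, UNIFORM_BACKGROUND, 4, s) == pytest.approx(expected)

    def test_too_short_sequence_raises(self, random_weights):
        with pytest.raises(ValueError):
            best_hit_pvalue(random_weights(5), UNIFORM_BACKGROUND, 4, 0.0)

    def test_monte_carlo_agreement(self, rng):
        # independence approximation vs simulation in the moderate tail
        weights = pfm_to_pwm(
            FrequencyMatrix(rng.dirichlet(np.ones(4) * 2, size=6)), 100
        )
        dist = score_distribution(weights, UNIFORM_BACKGROUND, 100)
        s = score_of_pvalue(dist, 1e-3)
        analytic = best_hit_pvalue(weights, UNIFORM_BACKGROUND, 50, s, d=100)
        qw = quantize_weights(weights, 100)
        n = 10_000
        hits = sum(
            best_hit(qw, random_dna(rng, 50)).score >= s - 1e-12 for _ in range(n)
        )
        mc = hits / n
        se = np.sqrt(max(mc * (1 - mc), 1e-9) / n)
        assert abs(analytic - mc) < 3 * se + 1e-3


class TestPseudoAuroc:
    def test_null_calibration(self, rng):
        weights = pfm_to_pwm(
            FrequencyMatrix(rng.dirichlet(np.ones(4) * 2, size=8)), 100
        )
        positives = [random_dna(rng, 301) for _ in range(500)]
        value = pseudo_auroc(weights, positives, d=100)
        assert abs(value - 0.5) < 3 * (12 * 500) ** -0.5

    def test_planted_sites_near_one(self, rng):
        mat = np.full((10, 4), 0.1 / 3)
        cons = rng.integers(0, 4, 10)
        for j, b in enumerate(cons):
            mat[j, b] = 0.9
        weights = pfm_to_pwm(FrequencyMatrix(mat), 100)
        word = "".join("ACGT"[b] for b in cons)
        positives = [
            random_dna(rng, 150) + word + random_dna(rng, 141) for _ in range(300)
        ]
        assert pseudo_auroc(weights, positives, d=100) > 0.99

    def test_duplication_invariance(self, rng, random_weights):
        # with a fixed background, duplicating the positive set leaves the
        # statistic unchanged (mean of u over a duplicated multiset)
        w = random_weights(5)
        positives = [random_dna(rng, 100) for _ in range(30)]
        a = pseudo_auroc(w, positives, bg_source="fixed", bg=UNIFORM_BACKGROUND)
        b = pseudo_auroc(w, positives * 2, bg_source="fixed", bg=UNIFORM_BACKGROUND)
        assert a == pytest.approx(b, abs=1e-12)

    def test_equals_threshold_sweep_roc(self, rng, random_weights):
        # 1 - mean(u) equals numerically integrating the ROC whose FPR at
        # P-value threshold alpha is alpha
        from motifbench.background import fit_background, score_distribution
        from motifbench.scanning import best_hit

        w = random_weights(5)
        positives = [random_dna(rng, 120) for _ in range(80)]
        value = pseudo_auroc(w, positives, d=50)
        bg = fit_background(positives, order=1)
        dist = score_distribution(w, bg, 50)
        qw = quantize_weights(w, 50)
        us = np.array(
            [
                best_hit_pvalue(w, bg, len(s), best_hit(qw, s).score, d=50, dist=dist)
                for s in positives
            ]
        )
        grid = np.linspace(0, 1, 20001)
        tpr = [(us <= a).mean() for a in grid]
        integral = np.trapezoid(tpr, grid)
        assert value == pytest.approx(integral, abs=2e-3)
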