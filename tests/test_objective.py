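"""Closed forms, gradients and schedules of the training objective."""

import numpy as np
import pytest

from lemmap import objective as obj
from lemmap.extremum import detect_extrema
from lemmap.scoremap import sigmoid


def fd_grad(f, S, i, j, eps=1e-6):
    Sp, Sm = S.copy(), S.copy()
    Sp[i, j] += eps
    Sm[i, j] -= eps
    return (f(Sp) - f(Sm)) / (2 * eps)


class TestEliminationLoss:
    def test_zero_map_closed_form(self):
        S = np.zeros((4, 5))
        # every cell both max and min, each contributing sigmoid(0) twice
        assert obj.elimination_loss(S, detect_extrema(S)) == pytest.approx(4 * 5)

    def test_correctly_signed_extrema_contribute_half_each(self):
        S = np.array([[0.0, 0.0, 0.0, 0.0],
                      [0.0, 2.0, 0.0, -3.0],
                      [0.0, 0.0, 0.0, 0.0]])
        E = detect_extrema(S)
        # isolate the two genuine extrema: one positive max, one negative min
        E.smax &= S > 0
        E.smin &= S < 0
        assert obj.elimination_loss(S, E) == pytest.approx(0.5 * 2)

    def test_wrong_maximum_value_and_gradient_sign(self):
        S = np.full((3, 3), -2.0)
        S[1, 1] = -1.0  # a single negative (wrongly signed) local maximum
        E = detect_extrema(S)
        E.smin[...] = False
        assert obj.elimination_loss(S, E) == pytest.approx(float(sigmoid(-1.0)))
        g = obj.elimination_grad(S, E)
        num = fd_grad(lambda s: obj.elimination_loss(s, E), S, 1, 1)
        assert g[1, 1] == pytest.approx(num, rel=1e-5)
        assert g[1, 1] > 0  # descent pushes the wrong maximum further down


class TestPenaltyLoss:
    def test_zero_map_closed_form(self):
        S = np.zeros((4, 5))
        per_cell = 2 * float(sigmoid(3.0))
        assert per_cell == pytest.approx(1.90515, abs=1e-5)
        assert obj.penalty_loss(S, 3.0) == pytest.approx(4 * 5 * per_cell)

    def test_single_out_of_band_cell(self):
        S = np.zeros((4, 4))
        S[2, 2] = 5.0
        expected = (16 - 1) * 2 * sigmoid(3.0) + sigmoid(5.0) + sigmoid(3.0)
        assert obj.penalty_loss(S, 3.0) == pytest.approx(float(expected))

    def test_gradient_zero_inside_band_positive_outside(self):
        S = np.zeros((3, 3))
        S[0, 0] = 2.0   # inside |S| <= tau
        S[1, 1] = 5.0   # above tau
        S[2, 2] = -4.0  # below -tau
        g = obj.penalty_grad(S, 3.0)
        for (i, j) in [(0, 0), (1, 1), (2, 2), (0, 1)]:
            num = fd_grad(lambda s: obj.penalty_loss(s, 3.0), S, i, j)
            assert g[i, j] == pytest.approx(num, abs=1e-6)
        assert g[0, 0] == 0.0 and g[0, 1] == 0.0
        assert g[1, 1] > 0 and g[2, 2] < 0


class TestSparseLoss:
    def test_gamma_zero_reduces_to_elimination(self, rng):
        S = rng.normal(size=(5, 5))
        E = detect_extrema(S)
        assert obj.sparse_loss(S, E, 0.0, 3.0) == obj.elimination_loss(S, E)

    def test_zero_map_sum_of_closed_forms(self):
        S = np.zeros((4, 5))
        E = detect_extrema(S)
        assert obj.sparse_loss(S, E, 1.0, 3.0) == pytest.approx(
            4 * 5 * (1.0 + 2 * float(sigmoid(3.0))))

    def test_term_by_term_oracle(self, rng):
        """Re-evaluate the published formulas cell by cell with plain loops."""
        S = rng.normal(size=(6, 6)) * 3
        E = detect_extrema(S)
        gamma, tau = 0.37, 2.0
        total = 0.0
        for i in range(6):
            for j in range(6):
                s = S[i, j]
                if E.smax[i, j]:
                    total += float(sigmoid(min(s, 0.0)))
                if E.smin[i, j]:
                    total += float(sigmoid(-max(s, 0.0)))
                total += gamma * float(sigmoid(max(s, tau)) + sigmoid(-min(s, -tau)))
        assert obj.sparse_loss(S, E, gamma, tau) == pytest.approx(total, rel=1e-12)

    def test_all_terms_nonnegative(self, rng):
        for _ in range(50):
            S = rng.normal(size=(4, 4)) * 5
            E = detect_extrema(S)
            assert obj.elimination_loss(S, E) >= 0
            assert obj.penalty_loss(S, 2.5) >= 0
            assert obj.sparse_loss(S, E, 0.3, 2.5) >= 0


class TestClassificationLoss:
    def test_half_probability_gives_log_two(self):
        assert obj.classification_loss(0.5, 0) == pytest.approx(np.log(2))
        assert obj.classification_loss(0.5, 1) == pytest.approx(np.log(2))

    def test_perfect_prediction_limit(self):
        assert obj.classification_loss(1.0 - 1e-9, 1) < 1e-6
        assert obj.classification_loss(1e-9, 0) < 1e-6

    def test_direct_analytic_value(self):
        assert obj.classification_loss(0.9, 1) == pytest.approx(-np.log(0.9))

    def test_degenerate_probabilities_clipped_not_infinite(self):
        assert np.isfinite(obj.classification_loss(0.0, 1))
        assert np.isfinite(obj.classification_loss(1.0, 0))


class TestTotalObjective:
    def test_alpha_zero_is_pure_gap_regime(self):
        assert obj.total_objective(5.0, 7.0, 1.25, 4.0, alpha=0.0, mu=1.0,
                                   lam=0.1) == pytest.approx(1.25 + 0.05 * 4.0)

    def test_alpha_one_mu_zero_lam_zero_is_lem_alone(self):
        assert obj.total_objective(5.0, 7.0, 1.25, 4.0, alpha=1.0, mu=0.0,
                                   lam=0.0) == pytest.approx(7.0)

    def test_matches_hand_coded_affine_combination(self, rng):
        for _ in range(20):
            spa, lem, gap, th = rng.uniform(0, 5, 4)
            a, m, l = rng.uniform(0, 1), rng.uniform(0, 2), rng.uniform(0, 0.1)
            expected = a * (m * spa + lem) + (1 - a) * gap + l / 2 * th
            assert obj.total_objective(spa, lem, gap, th, a, m, l) == pytest.approx(expected)


class TestSchedules:
    def test_alpha_endpoints_and_monotonicity(self):
        vals = [obj.alpha_schedule(e, 30) for e in range(30)]
        assert vals[0] == pytest.approx(0.1)
        assert vals[15] == pytest.approx(1.0) and vals[29] == pytest.approx(1.0)
        assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))

    def test_lr_schedule_exact_over_400_epochs(self):
        for e in range(400):
            assert obj.lr_schedule(e) == pytest.approx(1e-4 * 0.98 ** (e // 8),
                                                       rel=1e-12)
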