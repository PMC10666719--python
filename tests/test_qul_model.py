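"""QUL preference model: probabilities, optima, fitting, and curves.

The grid-search maximiser in this file is the independent oracle for the
gradient-based fit: it evaluates the same Bernoulli likelihood on a dense
(a, b) lattice and never touches the optimizer under test.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

from prefnr import qul_model as qm
from prefnr import synthetic_cohort as sc
from prefnr import trial_design as td


class TestProbability:
    def test_identical_stimuli_are_a_coin_flip(self):
        assert qm.qul_probability(1.3, -0.7, 9, 9) == 0.5

    def test_flat_utility_is_a_coin_flip(self):
        assert qm.qul_probability(0.0, 0.0, 3, 17) == 0.5

    def test_hand_evaluated_logistic(self):
        # u(10) = 4 - 2 = 2, u(0) = 0 -> logistic(2)
        p = qm.qul_probability(0.4, -0.02, 10, 0)
        assert p == pytest.approx(float(expit(2.0)), abs=1e-12)
        assert p == pytest.approx(0.8808, abs=1e-4)

    def test_complementarity(self):
        p12 = qm.qul_probability(0.5, -0.03, 7, 12)
        p21 = qm.qul_probability(0.5, -0.03, 12, 7)
        assert p12 + p21 == pytest.approx(1.0)

    def test_non_finite_inputs_rejected(self):
        with pytest.raises(ValueError):
            qm.qul_probability(float("nan"), 0.0, 0, 9)


class TestGOpt:
    @pytest.mark.parametrize(
        "a, b, expected_g, expected_boundary",
        [
            (0.4, -0.02, 10.0, False),  # interior vertex -a/(2b)
            (0.88, -0.02, 18.0, True),  # unconstrained vertex 22, clamped
            (0.0, -0.05, 0.0, True),  # vertex at zero
            (-0.2, -0.01, 0.0, True),  # negative vertex, clamped to 0
            (1.0, 0.0, 18.0, True),  # linear increasing utility
            (-1.0, 0.0, 0.0, True),  # linear decreasing utility
        ],
    )
    def test_known_optima(self, a, b, expected_g, expected_boundary):
        g, boundary = qm.g_opt_from_coefficients(a, b)
        assert g == pytest.approx(expected_g)
        assert boundary is expected_boundary

    def test_convex_tie_returns_midpoint(self):
        # b > 0 with the vertex at the interval centre: equal endpoint utility
        g, boundary = qm.g_opt_from_coefficients(-18.0, 1.0, (0.0, 18.0))
        assert g == 9.0 and boundary is False

    @given(
        st.floats(-1e6, 1e6, allow_nan=False),
        st.floats(-1e6, 1e6, allow_nan=False),
    )
    @settings(max_examples=300, deadline=None)
    def test_clamp_totality(self, a, b):
        g, _ = qm.g_opt_from_coefficients(a, b, (0.0, 18.0))
        assert 0.0 <= g <= 18.0


def _grid_search_mle(trials, a_grid, b_grid):
    """Brute-force likelihood maximiser over an (a, b) lattice (oracle)."""
    g1 = np.array([t.first for t in trials])
    g2 = np.array([t.second for t in trials])
    y = np.array([1.0 if t.choice == "first" else -1.0 for t in trials])
    dg = g1 - g2
    dg2 = g1 * g1 - g2 * g2
    best = (-np.inf, None, None)
    for a in a_grid:
        eta = y * (a * dg + b_grid[:, None] * dg2)  # (len(b), n)
        ll = -np.logaddexp(0.0, -eta).sum(axis=1)
        j = int(np.argmax(ll))
        if ll[j] > best[0]:
            best = (float(ll[j]), float(a), float(b_grid[j]))
    return best


class TestFit:
    def test_coin_flip_data_yield_flat_preference(self, rng):
        """With purely random choices the fitted curve is flat within 2 SE."""
        templates = td.enumerate_design(td.STUDY_LEVELS, 2)
        trials = [
            td.Trial("p", a, b, repetition=r,
                     choice="first" if rng.random() < 0.5 else "second")
            for a, b, r in templates
        ]
        fit = qm.fit_qul(trials)
        assert fit.converged and not fit.separated
        assert abs(fit.a) < 2 * fit.se_a + 1e-9
        assert abs(fit.b) < 2 * fit.se_b + 1e-9

    def test_recovery_and_grid_oracle_agreement(self):
        """MLE recovers the generating optimum and matches the grid oracle."""
        a_true, b_true = 0.48, -0.03  # true vertex at 8 dB
        rng = np.random.default_rng(42)
        trials = sc.simulate_trials("p", a_true, b_true, td.STUDY_DESIGN, rng)
        fit = qm.fit_qul(trials)
        assert abs(fit.g_opt - 8.0) <= 1.5

        step = 0.005
        a_grid = np.arange(fit.a - 0.15, fit.a + 0.15, step)
        b_grid = np.arange(fit.b - 0.02, fit.b + 0.02, step / 10)
        _, a_star, b_star = _grid_search_mle(trials, a_grid, b_grid)
        assert abs(fit.a - a_star) <= step
        assert abs(fit.b - b_star) <= step / 10

    def test_perfect_high_preference_is_separated(self):
        """A deterministic stronger-is-better responder has no finite MLE."""
        templates = td.enumerate_design(td.STUDY_LEVELS, 2)
        trials = [
            td.Trial("p", a, b, repetition=r,
                     choice="first" if a > b else "second")
            for a, b, r in templates
        ]
        fit = qm.fit_qul(trials)
        assert fit.separated
        assert fit.g_opt == 18.0
        assert fit.at_boundary
        assert np.all(np.isnan(fit.covariance))

    def test_order_effect_term_recovers_presentation_bias(self):
        """With the optional order term, a first-presentation bias is picked
        up as a positive delta while the balanced default stays near zero."""
        rng = np.random.default_rng(6)
        a, b = 0.48, -0.03
        templates = td.enumerate_design(td.STUDY_LEVELS, 2)
        delta_true = 0.8
        trials = []
        for g1, g2, r in templates:
            eta = delta_true + (a * g1 + b * g1 * g1) - (a * g2 + b * g2 * g2)
            choice = "first" if rng.random() < expit(eta) else "second"
            trials.append(td.Trial("p", g1, g2, repetition=r, choice=choice))
        fit = qm.fit_qul(trials, order_effect=True)
        se_delta = np.sqrt(fit.covariance[2, 2])
        assert abs(fit.order_bias - delta_true) <= 3 * se_delta
        assert fit.order_bias > 0

        balanced = sc.simulate_trials("p", a, b, td.STUDY_DESIGN,
                                      np.random.default_rng(7))
        fit0 = qm.fit_qul(balanced, order_effect=True)
        assert abs(fit0.order_bias) <= 3 * np.sqrt(fit0.covariance[2, 2])

    def test_single_pair_is_insufficient(self):
        trials = [td.Trial("p", 0, 9, choice="first")] * 6
        with pytest.raises(qm.InsufficientDesignError):
            qm.fit_qul(trials)

    def test_off_range_levels_rejected(self):
        trials = [td.Trial("p", 0, 25), td.Trial("p", 25, 9)]
        with pytest.raises(ValueError, match="clamp"):
            qm.fit_qul(trials)


class TestPreferenceCurve:
    def _fit(self, a, b, n=180):
        cov = np.eye(2) * 1e-4
        return qm.QULFit(a=a, b=b, covariance=cov, g_opt=9.0, at_boundary=False,
                         converged=True, separated=False, log_likelihood=0.0,
                         g_lo=0.0, g_hi=18.0, n_trials=n)

    def test_flat_model_gives_half_everywhere(self, study_design):
        curve = qm.preference_curve(self._fit(0.0, 0.0), study_design)
        assert np.allclose(curve["fraction"], 0.5)
        assert np.all(curve["se"] >= 0)

    def test_flat_model_ses_mirror_on_a_symmetric_grid(self):
        """Flat utility on a mirror-symmetric grid: SEs pair up by symmetry
        (they are not identical across levels on an asymmetric grid)."""
        design = td.Design((1, 4, 9, 14, 17), 2)
        templates = td.enumerate_design(design.levels, 2)
        trials = [td.Trial("p", a, b, repetition=r, choice="first")
                  for a, b, r in templates]
        X, _ = qm._design_matrix(trials)
        cov = np.linalg.inv(qm._hessian(np.zeros(2), X))
        fit = qm.QULFit(0.0, 0.0, cov, 9.0, False, True, False, 0.0, 0.0, 18.0, len(trials))
        se = qm.preference_curve(fit, design)["se"]
        assert se[0] == pytest.approx(se[4])
        assert se[1] == pytest.approx(se[3])

    def test_utility_symmetric_levels_have_equal_fractions(self):
        """Vertex at 9 dB: levels equidistant from it share a win fraction."""
        design = td.Design((5, 7, 9, 11, 13), 1)
        b = -0.05
        a = -2 * b * 9.0
        curve = qm.preference_curve(self._fit(a, b), design)
        frac = dict(zip(design.levels, curve["fraction"]))
        assert frac[7] == pytest.approx(frac[11])
        assert frac[5] == pytest.approx(frac[13])
        assert frac[9] == max(frac.values())

    def test_curve_matches_monte_carlo_win_fractions(self):
        """Model curve agrees with brute simulation of the same responder."""
        a, b = 0.48, -0.03
        design = td.STUDY_DESIGN
        rng = np.random.default_rng(11)
        n_per_pair = 10_000
        levels = np.array(design.levels, dtype=float)
        u = a * levels + b * levels**2
        wins = np.zeros(len(levels))
        npair = len(levels) - 1
        for i in range(len(levels)):
            for j in range(len(levels)):
                if i == j:
                    continue
                p = float(expit(u[i] - u[j]))
                wins[i] += rng.binomial(n_per_pair, p) / n_per_pair
        mc_frac = wins / npair
        mc_se = math.sqrt(0.25 / (n_per_pair * npair))
        curve = qm.preference_curve(self._fit(a, b), design)
        assert np.all(np.abs(curve["fraction"] - mc_frac) < 3 * mc_se + 3e-3)

    def test_separated_fit_flags_unreliable_ses(self, study_design):
        fit = self._fit(5.0, -1e-4)
        fit.separated = True
        fit.covariance = np.full((2, 2), np.nan)
        curve = qm.preference_curve(fit, study_design)
        assert not curve["se_reliable"]
        assert np.all(np.isnan(curve["se"]))
        assert np.all(np.isfinite(curve["fraction"]))
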