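"""Unit tests for the decision signals, first-passage densities and the
race-mixture likelihood."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import integrate, stats

from gazerace import likelihood as lk


def hand_trial(values, gazes, choice, rt):
    row = {f"item_value_{i}": v for i, v in enumerate(values)}
    row.update({f"gaze_{i}": g for i, g in enumerate(gazes)})
    row.update({"choice": choice, "rt": rt, "subject": 0, "trial": 0})
    return row


class TestDecisionSignals:
    def test_gamma_zero_hand_values(self):
        # r=(5,1,3), g=(0.16,0.62,0.22): A_i = g_i * r_i when gamma = 0
        a = lk.gaze_weighted_signal([5, 1, 3], [0.16, 0.62, 0.22], 0.0)
        np.testing.assert_allclose(a, [0.8, 0.62, 0.66], atol=1e-12)

    def test_gamma_one_is_exactly_the_values(self):
        rng = np.random.default_rng(0)
        r = rng.uniform(1, 10, 5)
        g = rng.dirichlet(np.ones(5))
        assert np.array_equal(lk.gaze_weighted_signal(r, g, 1.0), r)

    def test_full_gaze_ignores_gamma(self):
        a = lk.gaze_weighted_signal([4.0, 2.0], [1.0, 0.0], -1.5)
        assert a[0] == 4.0

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="shape"):
            lk.gaze_weighted_signal([1, 2, 3], [0.5, 0.5], 0.3)

    def test_relative_signals_hand_values(self):
        # R* = (0.14, -0.18, -0.14); logistic at tau=1
        r = lk.relative_signals([0.8, 0.62, 0.66], 1.0)
        np.testing.assert_allclose(np.round(r, 4), [0.5349, 0.4551, 0.4651])

    def test_tau_zero_gives_half(self):
        r = lk.relative_signals([3.0, 1.0, 2.0], 0.0)
        np.testing.assert_array_equal(r, 0.5)

    def test_exact_top_tie_gives_half(self):
        r = lk.relative_signals([2.0, 2.0, 1.0], 3.7)
        assert r[0] == 0.5 and r[1] == 0.5 and r[2] < 0.5

    @given(st.lists(st.floats(0.1, 10), min_size=2, max_size=5),
           st.floats(0, 10))
    def test_signals_bounded_and_max_item_dominates(self, values, tau):
        values = np.array(values)
        r = lk.relative_signals(values, tau)
        assert np.all((r > 0) & (r < 1))
        # the maximal item is the only one that can exceed 0.5
        top = values.max()
        assert np.all(r[values == top] >= 0.5)
        assert np.all(r[values < top] <= 0.5)

    def test_parameter_set_validation(self):
        with pytest.raises(ValueError):
            lk.ParameterSet(v=-1, gamma=0.3, sigma=0.2, tau=1)
        with pytest.raises(ValueError):
            lk.ParameterSet(v=1, gamma=1.2, sigma=0.2, tau=1)
        with pytest.raises(ValueError):
            lk.ParameterSet(v=1, gamma=0.3, sigma=0.2, tau=1, b=2.0)


class TestFirstPassage:
    def test_pdf_normalizes(self):
        total, _ = integrate.quad(lambda t: float(lk.ig_fpt_pdf(t, 0.5, 0.3)),
                                  0, np.inf, limit=200)
        assert abs(total - 1.0) < 1e-6

    def test_mode_matches_closed_form(self):
        drift, sigma = 0.5, 0.3
        mu, lam = 1 / drift, 1 / sigma**2
        mode = mu * (np.sqrt(1 + 9 * mu**2 / (4 * lam**2)) - 3 * mu / (2 * lam))
        grid = np.linspace(mode - 0.2, mode + 0.2, 20001)
        dens = lk.ig_fpt_pdf(grid, drift, sigma)
        assert abs(grid[np.argmax(dens)] - mode) < 1e-3

    def test_mean_is_boundary_over_drift(self):
        drift, sigma = 0.7, 0.25
        mean, _ = integrate.quad(
            lambda t: t * float(lk.ig_fpt_pdf(t, drift, sigma)), 0, np.inf,
            limit=200)
        assert abs(mean - 1 / drift) < 1e-6

    @pytest.mark.parametrize("drift,sigma", [(0.7, 0.25), (0.2, 0.5), (2.0, 1.5)])
    def test_matches_scipy_invgauss(self, drift, sigma):
        mu, lam = 1 / drift, 1 / sigma**2
        ref = stats.invgauss(mu / lam, scale=lam)
        t = np.geomspace(0.05, 50, 40)
        np.testing.assert_allclose(lk.ig_fpt_logpdf(t, drift, sigma),
                                   ref.logpdf(t), rtol=1e-10)
        np.testing.assert_allclose(lk.ig_fpt_cdf(t, drift, sigma),
                                   ref.cdf(t), atol=1e-12)
        np.testing.assert_allclose(lk.ig_fpt_logsf(t, drift, sigma),
                                   ref.logsf(t), rtol=1e-9)

    @pytest.mark.parametrize("t", [0.5, 1.0, 3.0])
    def test_cdf_equals_pdf_quadrature(self, t):
        val, _ = integrate.quad(lambda s: float(lk.ig_fpt_pdf(s, 0.7, 0.25)),
                                0, t, limit=200)
        assert abs(float(lk.ig_fpt_cdf(t, 0.7, 0.25)) - val) < 1e-6

    def test_cdf_monotone_and_limits(self):
        t = np.linspace(1e-3, 60, 1000)
        f = lk.ig_fpt_cdf(t, 0.6, 0.4)
        assert np.all(np.diff(f) >= -1e-12)  # flat plateau at 1 up to rounding
        assert float(lk.ig_fpt_cdf(1e4, 0.6, 0.4)) > 1 - 1e-12
        assert float(lk.ig_fpt_cdf(-1.0, 0.6, 0.4)) == 0.0
        assert float(lk.ig_fpt_pdf(-1.0, 0.6, 0.4)) == 0.0

    def test_logsf_floor_in_far_tail(self):
        assert float(lk.ig_fpt_logsf(1e9, 2.0, 0.1)) >= np.log(1e-300)


class TestRace:
    def test_some_accumulator_wins_with_probability_one(self):
        drifts = np.full(3, 0.5)
        total = sum(
            integrate.quad(lambda t, i=i: float(lk.race_density(t, i, drifts, 0.3)),
                           0, np.inf, limit=200)[0]
            for i in range(3))
        assert abs(total - 1.0) < 1e-4

    def test_symmetric_drifts_share_wins_equally(self):
        drifts = np.full(3, 0.5)
        p0, _ = integrate.quad(lambda t: float(lk.race_density(t, 0, drifts, 0.3)),
                               0, np.inf, limit=200)
        assert abs(p0 - 1 / 3) < 1e-4

    def test_win_probability_matches_monte_carlo(self):
        drifts = np.array([0.6, 0.3, 0.3])
        p0, _ = integrate.quad(lambda t: float(lk.race_density(t, 0, drifts, 0.3)),
                               0, np.inf, limit=200)
        rng = np.random.default_rng(5)
        n = 30000
        fpt = rng.wald(1 / drifts, 1 / 0.09, (n, 3))
        freq = float((fpt.argmin(axis=1) == 0).mean())
        se = np.sqrt(p0 * (1 - p0) / n)
        assert abs(freq - p0) < 3 * se

    def test_non_finite_drifts_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            lk.race_log_density(1.0, 0, np.array([0.5, np.inf]), 0.3)


class TestTrialLikelihood:
    cont = lk.ContaminantModel(n_items=3, rt_min=0.4, rt_max=3.2, epsilon=0.05)
    params = lk.ParameterSet(v=0.7, gamma=0.3, sigma=0.25, tau=1.0)

    def test_pure_contaminant_is_uniform(self):
        cont = lk.ContaminantModel(3, 0.4, 3.2, epsilon=1.0)
        lik = lk.trial_likelihood(hand_trial([5, 1, 3], [0.2, 0.5, 0.3], 0, 1.5),
                                  self.params, cont)
        assert lik.likelihood == pytest.approx(1 / (3 * (3.2 - 0.4)), rel=1e-12)

    def test_vanishing_race_leaves_contaminant_floor(self):
        # far in the tail the race density underflows to zero
        cont = lk.ContaminantModel(3, 0.1, 1000.0, epsilon=0.05)
        lik = lk.trial_likelihood(hand_trial([5, 1, 3], [0.2, 0.5, 0.3], 0, 900.0),
                                  self.params, cont)
        assert lik.likelihood == pytest.approx(0.05 / (3 * 999.9), rel=1e-9)

    def test_gamma_one_gaze_permutation_invariance_is_exact(self):
        params = lk.ParameterSet(v=0.7, gamma=1.0, sigma=0.25, tau=1.0)
        gazes = [0.16, 0.62, 0.22]
        base = lk.trial_likelihood(hand_trial([5, 1, 3], gazes, 0, 2.056),
                                   params, self.cont)
        for perm in ([0.62, 0.22, 0.16], [0.22, 0.16, 0.62]):
            other = lk.trial_likelihood(hand_trial([5, 1, 3], perm, 0, 2.056),
                                        params, self.cont)
            assert other.log_likelihood == base.log_likelihood

    def test_log_matches_linear(self):
        lik = lk.trial_likelihood(hand_trial([5, 1, 3], [0.2, 0.5, 0.3], 2, 1.1),
                                  self.params, self.cont)
        assert abs(np.log(lik.likelihood) - lik.log_likelihood) < 1e-10

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_mixture_is_a_proper_density(self, seed):
        # sum over items of the integrated mixture likelihood equals 1
        rng = np.random.default_rng(seed)
        params = lk.ParameterSet(v=rng.uniform(0.3, 1.5),
                                 gamma=rng.uniform(-1, 1),
                                 sigma=rng.uniform(0.15, 0.6),
                                 tau=rng.uniform(0.2, 3))
        values = rng.integers(1, 11, 3).astype(float)
        gazes = rng.dirichlet(np.ones(3))
        cont = lk.ContaminantModel(3, 0.2, 8.0, epsilon=0.05)
        total = 0.0
        for i in range(3):
            def integrand(t, i=i):
                return lk.trial_likelihood(
                    hand_trial(values, gazes, i, t), params, cont).likelihood
            part, _ = integrate.quad(integrand, 1e-6, 200.0, limit=400,
                                     points=[0.2, 1.0, 8.0])
            total += part
        assert abs(total - 1.0) < 1e-3

    def test_table_log_likelihood_matches_trial_likelihood(self):
        rng = np.random.default_rng(3)
        n = 40
        values = rng.integers(1, 11, (n, 3)).astype(float)
        gazes = rng.dirichlet(np.ones(3), n)
        choice = rng.integers(0, 3, n)
        rt = rng.uniform(0.5, 3, n)
        vec = lk.table_log_likelihood(
            values, gazes, choice, rt,
            np.full(n, self.params.v), np.full(n, self.params.gamma),
            np.full(n, self.params.sigma), np.full(n, self.params.tau),
            self.cont.epsilon, np.full(n, self.cont.log_u))
        ref = [lk.trial_likelihood(hand_trial(values[k], gazes[k], choice[k],
                                              rt[k]), self.params, self.cont
                                   ).log_likelihood for k in range(n)]
        np.testing.assert_allclose(vec, ref, atol=1e-12)
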