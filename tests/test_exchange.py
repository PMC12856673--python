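"""Closed-form exchange-coupled relaxation vs independent oracles."""

import numpy as np
import pytest

from protonex import (
    ExchangePair,
    fast_exchange_approx,
    longitudinal_eigenrates,
    longitudinal_signal,
    longitudinal_solution,
    observed_signal,
    ode_reference,
    predicted_coefficients,
    transverse_signal,
    transverse_solution,
)
from protonex.fitting import DecayCurve, FitConfig, fit_recovery

TIMES = np.geomspace(1e-3, 20.0, 40)


class TestEigenrates:
    def test_decoupled_pools_reduce_to_pool_rates(self):
        pair = ExchangePair(R1_A=2.0, R1_B=0.5, k_ex=0.0, A_tot=1e4, B_tot=1e3)
        assert longitudinal_eigenrates(pair) == pytest.approx((0.5, 2.0))

    def test_symmetric_pools(self):
        # equal rates and equal pools: lambda = (R, R + 2k)
        pair = ExchangePair(R1_A=1.0, R1_B=1.0, k_ex=1e-3, A_tot=5e3, B_tot=5e3)
        k = 1e-3 * 5e3
        l1, l2 = longitudinal_eigenrates(pair)
        assert l1 == pytest.approx(1.0, rel=1e-12)
        assert l2 == pytest.approx(1.0 + 2 * k, rel=1e-12)

    def test_matches_matrix_eigenvalues(self, pair_ensemble):
        for pair in pair_ensemble:
            K = np.array([[pair.r_A, -pair.k_B], [-pair.k_A, pair.r_B]])
            expected = np.sort(np.linalg.eigvals(K).real)
            assert longitudinal_eigenrates(pair) == pytest.approx(tuple(expected), rel=1e-10)

    def test_label_swap_symmetry(self, pair_ensemble):
        for pair in pair_ensemble:
            assert longitudinal_eigenrates(pair) == pytest.approx(
                longitudinal_eigenrates(pair.swapped()), rel=1e-12)


class TestLongitudinalSolution:
    def test_amplitude_identity(self, pair_ensemble):
        for pair in pair_ensemble:
            sol = longitudinal_solution(pair)
            assert sol.Lambda1 + sol.Lambda2 == pytest.approx(
                pair.Mz_inf_A, rel=1e-12)

    def test_saturation_boundary_values(self, pair_ensemble):
        for pair in pair_ensemble:
            sig = longitudinal_signal(pair, np.array([0.0, 1e4]))
            assert sig[0] == pytest.approx(0.0, abs=1e-10)
            assert sig[1] == pytest.approx(1.0, rel=1e-9)

    def test_coefficients_sum_to_one_for_saturation(self, pair_ensemble):
        for pair in pair_ensemble:
            sol = longitudinal_solution(pair)
            assert sol.a1s + sol.a1f == pytest.approx(1.0, abs=1e-12)

    def test_matches_ode_oracle(self, pair_ensemble):
        for pair in pair_ensemble:
            scale = pair.Mz_inf_A + pair.Mz_inf_B
            mz_a, mz_b = longitudinal_solution(pair).pools(TIMES)
            ode_a, ode_b = ode_reference(pair, TIMES, "longitudinal")
            assert np.allclose(mz_a, ode_a, rtol=1e-8, atol=1e-8 * scale)
            assert np.allclose(mz_b, ode_b, rtol=1e-8, atol=1e-8 * scale)

    def test_custom_initial_condition_matches_ode(self, pair_ensemble):
        for pair in pair_ensemble[:6]:
            m0 = (0.3 * pair.Mz_inf_A, 1.2 * pair.Mz_inf_B)
            scale = pair.Mz_inf_A + pair.Mz_inf_B
            mz_a, mz_b = longitudinal_solution(pair, m0).pools(TIMES)
            ode_a, ode_b = ode_reference(pair, TIMES, "longitudinal", initial=m0)
            assert np.allclose(mz_a, ode_a, rtol=1e-8, atol=1e-8 * scale)
            assert np.allclose(mz_b, ode_b, rtol=1e-8, atol=1e-8 * scale)

    def test_decoupled_signal_is_weighted_recovery_sum(self):
        pair = ExchangePair(R1_A=0.5, R1_B=2.0, k_ex=0.0, A_tot=8e3, B_tot=2e3)
        sig = longitudinal_signal(pair, TIMES)
        expected = 0.8 * (1 - np.exp(-0.5 * TIMES)) + 0.2 * (1 - np.exp(-2.0 * TIMES))
        assert np.allclose(sig, expected, rtol=1e-10)
        assert longitudinal_solution(pair).a1s == pytest.approx(0.8, rel=1e-9)

    def test_degenerate_eigenrates_flagged(self):
        pair = ExchangePair(R1_A=1.0, R1_B=1.0, k_ex=0.0, A_tot=1e3, B_tot=1e3)
        sol = longitudinal_solution(pair)
        assert sol.degenerate
        assert np.allclose(
            sol.total_signal(TIMES), 1 - np.exp(-1.0 * TIMES), rtol=1e-10)

    def test_empty_grid_rejected(self):
        pair = ExchangePair(R1_A=1.0, R1_B=1.0, k_ex=1e-4, A_tot=1e3, B_tot=1e3)
        with pytest.raises(ValueError):
            longitudinal_signal(pair, np.array([]))


class TestTransverseSolution:
    def test_amplitude_identity(self, pair_ensemble):
        for pair in pair_ensemble:
            sol = transverse_solution(pair)
            assert complex(sol.Theta1 + sol.Theta2) == pytest.approx(
                pair.Mxy0_A, rel=1e-12)

    def test_matches_ode_oracle_on_resonance(self, pair_ensemble):
        times = np.geomspace(1e-4, 2.0, 40)
        for pair in pair_ensemble:
            scale = pair.Mxy0_A + pair.Mxy0_B
            a, b = transverse_solution(pair).pools(times)
            oa, ob = ode_reference(pair, times, "transverse")
            assert np.allclose(a, oa, rtol=1e-8, atol=1e-8 * scale)
            assert np.allclose(b, ob, rtol=1e-8, atol=1e-8 * scale)

    def test_matches_ode_oracle_off_resonance(self, pair_ensemble):
        times = np.geomspace(1e-4, 1.0, 30)
        rng = np.random.default_rng(7)
        for pair in pair_ensemble[:6]:
            from dataclasses import replace
            pair = replace(pair, omega_A=float(rng.uniform(-200, 200)),
                           omega_B=float(rng.uniform(-200, 200)))
            scale = pair.Mxy0_A + pair.Mxy0_B
            a, b = transverse_solution(pair).pools(times)
            oa, ob = ode_reference(pair, times, "transverse")
            assert np.allclose(a, oa, rtol=1e-8, atol=1e-8 * scale)
            assert np.allclose(b, ob, rtol=1e-8, atol=1e-8 * scale)

    def test_on_resonance_solution_is_real_and_ordered(self, pair_ensemble):
        for pair in pair_ensemble:
            sol = transverse_solution(pair)
            assert abs(sol.theta1.imag) < 1e-10 * max(abs(sol.theta1), 1)
            assert sol.theta1.real <= sol.theta2.real
            assert sol.theta1.real >= -1e-12

    def test_decoupled_decays(self):
        pair = ExchangePair(R1_A=1, R1_B=1, R2_A=2.0, R2_B=8.0, k_ex=0.0,
                            A_tot=7e3, B_tot=3e3)
        times = np.geomspace(1e-4, 1.0, 30)
        sig = transverse_signal(pair, times, detection="real")
        expected = 7e3 * np.exp(-2.0 * times) + 3e3 * np.exp(-8.0 * times)
        assert np.allclose(sig, expected, rtol=1e-9)

    def test_signal_boundary_and_monotone_decay(self, pair_ensemble):
        times = np.linspace(0, 2, 200)
        for pair in pair_ensemble[:8]:
            sig = transverse_signal(pair, times)
            assert sig[0] == pytest.approx(pair.Mxy0_A + pair.Mxy0_B, rel=1e-12)
            assert np.all(np.diff(sig) <= 1e-9 * sig[0])
            assert sig[-1] < sig[0]


class TestFastExchange:
    def test_weighted_mean_rate_example(self):
        pair = ExchangePair(R1_A=0.5, R1_B=2.0, k_ex=1e-2, A_tot=9e3, B_tot=1e3)
        approx = fast_exchange_approx(pair)
        assert approx.lambda1 == pytest.approx(0.9 * 0.5 + 0.1 * 2.0, rel=1e-12)
        assert approx.lambda2 == pytest.approx(
            1e-2 * 1e4 + 0.1 * 0.5 + 0.9 * 2.0, rel=1e-12)

    def test_single_pool_limit(self):
        pair = ExchangePair(R1_A=0.7, R1_B=2.0, k_ex=1e-3, A_tot=1e4, B_tot=0.0)
        assert fast_exchange_approx(pair).lambda1 == pytest.approx(0.7)

    def test_relative_error_below_1pct_in_fast_regime(self):
        # whenever k_ex (A+B) > 100 max(R1) the weighted-mean rate is within 1%
        rng = np.random.default_rng(11)
        checked = 0
        for _ in range(200):
            r1a, r1b = np.exp(rng.uniform(np.log(0.1), np.log(5), 2))
            a, b = 10 ** rng.uniform(2.5, 5, 2)
            kex = 10 ** rng.uniform(-5, 0)
            if kex * (a + b) <= 100 * max(r1a, r1b):
                continue
            pair = ExchangePair(R1_A=r1a, R1_B=r1b, k_ex=kex, A_tot=a, B_tot=b)
            l1, _ = longitudinal_eigenrates(pair)
            approx = fast_exchange_approx(pair)
            assert abs(l1 - approx.lambda1) / l1 < 0.01
            _, a_fast = predicted_coefficients(pair, "T1")
            assert a_fast < 0.01
            checked += 1
        assert checked >= 30

    def test_inverse_fast_eigenrate_vanishes(self):
        pair = ExchangePair(R1_A=0.4, R1_B=1.5, k_ex=1e-2, A_tot=1e5, B_tot=1e4)
        _, l2 = longitudinal_eigenrates(pair)
        assert 1.0 / l2 < 1e-3  # far below the ~1 s relaxation times

    def test_zero_pool_total_rejected(self):
        pair = ExchangePair(R1_A=1.0, R1_B=1.0, k_ex=1e-2, A_tot=0.0, B_tot=0.0)
        with pytest.raises(ValueError):
            fast_exchange_approx(pair)


class TestPredictedCoefficients:
    def test_slow_component_dominates_at_fast_exchange(self):
        pair = ExchangePair(R1_A=0.5, R1_B=2.0, k_ex=1.0, A_tot=1e5, B_tot=1e4)
        a_s, a_f = predicted_coefficients(pair, "T1")
        assert a_s > 0.999 and a_f < 1e-3

    def test_decoupled_equal_pools_split_evenly(self):
        pair = ExchangePair(R1_A=0.5, R1_B=2.0, k_ex=0.0, A_tot=5e3, B_tot=5e3)
        a_s, a_f = predicted_coefficients(pair, "T1")
        assert (a_s, a_f) == pytest.approx((0.5, 0.5), rel=1e-9)

    @pytest.mark.parametrize("kex", [3e-5, 2e-4])
    def test_intermediate_exchange_fit_roundtrip(self, kex):
        # fitted coefficients of the noiseless model curve equal the predicted ones
        pair = ExchangePair(R1_A=0.4, R1_B=1.0, k_ex=kex, A_tot=5e4, B_tot=2e4)
        a_s, a_f = predicted_coefficients(pair, "T1")
        times = np.geomspace(4e-3, 30, 48)
        curve = DecayCurve(times, longitudinal_signal(pair, times), "saturation_recovery")
        res = fit_recovery(curve, FitConfig(model_order="bi"))
        assert res.a_slow == pytest.approx(a_s, abs=1e-6)
        assert res.a_fast == pytest.approx(a_f, abs=1e-6)


class TestObservedSignal:
    def test_limits_of_nonexchangeable_fraction(self):
        pair = ExchangePair(R1_A=0.4, R1_B=1.0, k_ex=1e-3, A_tot=5e4, B_tot=1e4)
        times = np.geomspace(4e-3, 30, 32)
        two_pool = longitudinal_signal(pair, times)
        assert np.allclose(observed_signal(pair, 5.0, 0.0, times, "T1"), two_pool)
        assert np.allclose(
            observed_signal(pair, 5.0, 1.0, times, "T1"), 1 - np.exp(-5.0 * times))

    def test_fast_exchange_fit_recovers_nonexchangeable_fraction(self):
        # the central interpretive claim: in fast exchange the fitted fast
        # coefficient equals the nonexchangeable proton fraction
        pair = ExchangePair(R1_A=0.4, R1_B=1.0, k_ex=1e-2, A_tot=9e4, B_tot=6e3)
        f_non = 0.23
        times = np.geomspace(4e-3, 30, 32)
        sig = observed_signal(pair, 1 / 0.25, f_non, times, "T1")
        res = fit_recovery(
            DecayCurve(times, sig, "saturation_recovery"), FitConfig(model_order="bi"))
        assert res.a_fast == pytest.approx(f_non, abs=0.01)
        assert res.a_slow == pytest.approx(1 - f_non, abs=0.01)


class TestOdeReference:
    def test_exchange_flux_antisymmetry(self):
        # with R1 = 0 the total longitudinal magnetization is conserved
        pair = ExchangePair(R1_A=0.0, R1_B=0.0, k_ex=1e-3, A_tot=4e3, B_tot=2e3,
                            Mz_inf_A=0.0, Mz_inf_B=0.0)
        times = np.geomspace(1e-3, 5, 20)
        a, b = ode_reference(pair, times, "longitudinal", initial=(3.0, 1.0))
        assert np.allclose(a + b, 4.0, rtol=1e-9)

    def test_single_pool_textbook_recovery(self):
        pair = ExchangePair(R1_A=0.8, R1_B=1.0, k_ex=0.0, A_tot=1e3, B_tot=0.0)
        times = np.geomspace(1e-3, 10, 20)
        a, _ = ode_reference(pair, times, "longitudinal")
        assert np.allclose(a, pair.Mz_inf_A * (1 - np.exp(-0.8 * times)), rtol=1e-8)

    def test_non_increasing_grid_rejected(self):
        pair = ExchangePair(R1_A=1.0, R1_B=1.0, k_ex=0.0, A_tot=1e3, B_tot=1e3)
        with pytest.raises(ValueError):
            ode_reference(pair, np.array([0.0, 1.0, 0.5]), "longitudinal")
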