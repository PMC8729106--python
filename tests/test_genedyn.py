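import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from grnsync.genedyn import (
    GeneState,
    advance_delay_chain,
    advance_deterministic,
    advance_stochastic,
    advance_two_state,
    check_step_criterion,
    delayed_output,
    draw_switch_time,
    partial_fraction_coeffs,
    sample_births,
    sample_survivors,
    stochastic_round,
)
from grnsync.promoter import EffectiveRates


def rates(lam, mu):
    return EffectiveRates(lam, mu, lam / (lam + mu))


class TestDeterministic:
    def test_pure_decay(self):
        assert advance_deterministic(10.0, 0.0, 5.0, 0.1, 7.0) == pytest.approx(
            10.0 * math.exp(-0.7)
        )

    def test_fixed_point(self):
        n_star = 1.0 * 2.0 / 0.1
        assert advance_deterministic(n_star, 1.0, 2.0, 0.1, 13.0) == pytest.approx(n_star)

    def test_matches_adaptive_integration(self):
        sol = solve_ivp(
            lambda t, n: 2.0 - 0.1 * n, (0, 10), [0.0], rtol=1e-12, atol=1e-12
        )
        assert advance_deterministic(0.0, 1.0, 2.0, 0.1, 10.0) == pytest.approx(
            sol.y[0, -1], abs=1e-9
        )

    def test_nonpositive_delta_rejected(self):
        with pytest.raises(ValueError):
            advance_deterministic(1.0, 0.5, 1.0, 0.0, 1.0)


class TestSwitchTimes:
    def test_unit_draw_gives_zero(self):
        assert draw_switch_time(3.0, 1.0) == 0.0

    def test_exact_log(self):
        assert draw_switch_time(2.0, math.exp(-2.0)) == pytest.approx(1.0)

    def test_sample_mean_is_inverse_rate(self, rng):
        draws = [draw_switch_time(0.5, 1.0 - rng.random()) for _ in range(100_000)]
        mean = np.mean(draws)
        se = np.std(draws) / np.sqrt(len(draws))
        assert abs(mean - 2.0) < 3 * se

    def test_zero_rate_rejected(self):
        with pytest.raises(ValueError):
            draw_switch_time(0.0, 0.5)


class TestBirthDeathDraws:
    def test_zero_window_means_zero_births(self, rng):
        assert sample_births(5.0, 0.0, rng) == 0

    def test_poisson_mean_and_variance(self, rng):
        draws = np.array([sample_births(1.5, 2.0, rng) for _ in range(100_000)])
        se = draws.std() / np.sqrt(draws.size)
        assert abs(draws.mean() - 3.0) < 3 * se
        assert abs(draws.var() - 3.0) < 3 * draws.var() * np.sqrt(2 / draws.size) + 0.05

    def test_no_decay_keeps_all(self, rng):
        assert sample_survivors(17, 0.0, 100.0, rng) == 17
        assert sample_survivors(0, 1.0, 1.0, rng) == 0

    def test_binomial_mean(self, rng):
        p = 0.8
        tau = -math.log(p)
        draws = np.array([sample_survivors(100, 1.0, tau, rng) for _ in range(100_000)])
        se = draws.std() / np.sqrt(draws.size)
        assert abs(draws.mean() - 80.0) < 3 * se

    def test_stochastic_round_preserves_mean(self, rng):
        draws = np.array([stochastic_round(3.7, rng) for _ in range(50_000)])
        assert set(draws) <= {3, 4}
        assert abs(draws.mean() - 3.7) < 0.01


class TestTwoState:
    def test_silent_gene_decays_deterministically(self, rng):
        st = GeneState(n=40.0, on=False)
        st, intervals = advance_two_state(st, rates(0.0, 1.0), 1.0, 0.01, 50.0, rng)
        assert intervals == [(50.0, False)]
        assert st.n == pytest.approx(40.0 * math.exp(-0.5))

    def test_instant_shutoff_limit(self, rng):
        st = GeneState(n=0.0, on=True)
        st, intervals = advance_two_state(
            st, EffectiveRates(0.0, 1e12, 0.0), 1.0, 0.01, 10.0, rng
        )
        assert intervals[0][1] is True and intervals[0][0] < 1e-10
        assert st.on is False

    def test_long_run_on_fraction_matches_p_on(self, rng):
        r = rates(0.01, 0.04)
        st = GeneState(n=0.0, on=False)
        on_time = total = 0.0
        for _ in range(20_000):
            st, intervals = advance_two_state(st, r, 0.0, 1e-9, 50.0, rng)
            on_time += sum(tau for tau, on in intervals if on)
            total += 50.0
        frac = on_time / total
        # effective number of on/off cycles governs the standard error
        n_cycles = total * (1 / (1 / 0.01 + 1 / 0.04))
        se = 0.2 / np.sqrt(n_cycles)
        assert abs(frac - 0.2) < 3 * se

    def test_scenario2_ensemble_mean_matches_deterministic(self, rng):
        """With stationary initialization the switching noise averages out."""
        r = rates(0.005, 0.005)
        nu, delta, dt = 0.5, 0.01, 10.0
        n_rep, n_steps = 2000, 40
        ensemble = np.zeros((n_rep, n_steps))
        for k in range(n_rep):
            st = GeneState(n=0.0, on=bool(rng.random() < r.p_on))
            for q in range(n_steps):
                st, _ = advance_two_state(st, r, nu, delta, dt, rng)
                ensemble[k, q] = st.n
        det = np.array([
            advance_deterministic(0.0, r.p_on, nu, delta, (q + 1) * dt)
            for q in range(n_steps)
        ])
        mean = ensemble.mean(axis=0)
        se = ensemble.std(axis=0) / np.sqrt(n_rep)
        assert np.all(np.abs(mean - det) < 3 * se + 1e-9)


class TestStochastic:
    def test_silent_empty_gene_stays_empty(self, rng):
        st = GeneState(n=0.0, on=False)
        st = advance_stochastic(st, rates(0.0, 1.0), 1.0, 0.01, 10.0, rng)
        assert st.n == 0.0

    def test_stationary_mean_of_scheme(self, rng):
        # permanently-on gene: the scheme preserves the nu/delta mean
        nu, delta, dt = 1.0, 0.01, 1.0
        st = GeneState(n=0.0, on=True)
        r = EffectiveRates(1.0, 1e-300, 1.0)
        samples = []
        for q in range(60_000):
            st = advance_stochastic(st, r, nu, delta, dt, rng)
            if q > 10_000:
                samples.append(st.n)
        samples = np.asarray(samples)
        n_eff = len(samples) * delta * dt * 2  # ~ one per correlation time
        se = samples.std() / np.sqrt(n_eff)
        assert abs(samples.mean() - nu / delta) < 3 * se + 1.0


class TestDelayChain:
    def test_partial_fractions_trivial_and_two_stage(self):
        assert partial_fraction_coeffs([2.0]) == pytest.approx([1.0])
        assert partial_fraction_coeffs([1.0, 2.0]) == pytest.approx([1.0, -1.0])

    @pytest.mark.parametrize("betas", [[0.5], [0.5, 1.1], [0.2, 0.9, 1.7, 3.0, 4.2]])
    def test_partial_fraction_sum_identity(self, betas):
        # steady state of the cascade with a == 1: sum alpha_i/beta_i = 1/beta_N
        alphas = partial_fraction_coeffs(betas)
        assert np.sum(alphas / np.asarray(betas)) == pytest.approx(
            1.0 / betas[-1], abs=1e-9
        )

    def test_near_equal_rates_rejected(self):
        with pytest.raises(ValueError, match="perturb"):
            partial_fraction_coeffs([1.0, 1.0 + 1e-12])

    def test_single_stage_steady_state(self):
        c = np.zeros(2)
        for _ in range(2000):
            c = advance_delay_chain(c, 1.0, 0.4, [0.02], 0.01, 50.0)
        assert c[0] == pytest.approx(0.4 / 0.02, rel=1e-6)
        assert c[1] == pytest.approx(0.4 / 0.01, rel=1e-6)

    def test_multi_stage_steady_state_all_stages(self):
        betas, delta, nu = [0.02, 0.05, 0.08], 0.01, 0.4
        c = np.zeros(4)
        for _ in range(3000):
            c = advance_delay_chain(c, 1.0, nu, betas, delta, 50.0)
        for i, b in enumerate(betas):
            assert c[i] == pytest.approx(nu / b, rel=1e-6)
        assert c[-1] == pytest.approx(nu / delta, rel=1e-6)

    def test_piecewise_activity_matches_adaptive_integration(self):
        betas, delta, nu = [0.05, 0.11, 0.23], 0.02, 1.0
        rates_all = betas + [delta]
        intervals = [(7.0, 1.0), (3.0, 0.0), (12.0, 1.0), (5.0, 0.0)]

        def rhs(t, c, a):
            dc = np.empty(4)
            dc[0] = a * nu - rates_all[0] * c[0]
            for i in range(1, 4):
                dc[i] = rates_all[i - 1] * c[i - 1] - rates_all[i] * c[i]
            return dc

        c_ref = np.array([1.0, 2.0, 0.5, 3.0])
        c_mine = c_ref.copy()
        for tau, a in intervals:
            sol = solve_ivp(rhs, (0, tau), c_ref, args=(a,), rtol=1e-11, atol=1e-12)
            c_ref = sol.y[:, -1]
        c_mine = advance_delay_chain(c_mine, intervals, nu, betas, delta, None)
        assert np.max(np.abs(c_mine - c_ref)) < 1e-6

    def test_flux_conservation_through_chain(self):
        # long-run integral of beta_N * c_N equals the integral of a*nu
        betas, delta, nu, dt = [0.03, 0.07], 0.02, 0.6, 20.0
        c = np.zeros(3)
        produced = transmitted = 0.0
        a_pattern = [1.0, 1.0, 0.0, 1.0, 0.0, 0.0, 1.0]
        for q in range(6000):
            a = a_pattern[q % len(a_pattern)]
            c_new = advance_delay_chain(c, a, nu, betas, delta, dt)
            produced += a * nu * dt
            transmitted += betas[-1] * 0.5 * (c[-2] + c_new[-2]) * dt
            c = c_new
        assert transmitted == pytest.approx(produced, rel=0.01)


class TestQueueAndCriterion:
    def test_empty_queue_is_passthrough(self):
        assert delayed_output([], 3.5) == 3.5

    def test_step_input_is_shifted_by_queue_length(self):
        queue = [0.0] * 10
        outputs = [delayed_output(queue, 1.0) for _ in range(15)]
        assert outputs[:10] == [0.0] * 10
        assert outputs[10:] == [1.0] * 5

    @pytest.mark.parametrize(
        "p_on,nu,dt,warn",
        [(0.5, 0.1, 1.0, False), (1.0, 2.0, 1.0, True), (1.0, 1.0, 1.0, True)],
    )
    def test_step_criterion_threshold(self, p_on, nu, dt, warn):
        assert (check_step_criterion(p_on, nu, dt) is not None) == warn
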