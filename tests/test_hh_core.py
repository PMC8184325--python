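"""Unit and property tests for the membrane model and its integrator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from ctmsmt import (
    HHParameters,
    MembraneState,
    SimulationConfig,
    StimulusWaveform,
    build_pulse,
    compute_rates,
    current_densities,
    derivatives,
    detect_spike,
    find_resting_state,
    integrate,
    steady_state_gating,
)
from ctmsmt.errors import InvalidInputError, NumericalBlowupError


def _rect_waveform(J_peak, width_us, dt=1.0):
    return StimulusWaveform(
        dt=dt, samples=np.full(int(width_us / dt), J_peak), phase_boundaries=(), spec="external"
    )


# -- independently coded rate expressions (oracle; expm1-based, different
#    algebraic arrangement from the implementation) -------------------------

def _oracle_rates(V, p):
    xm = V - p.V_T - 13.0
    am = 0.32 * xm / -np.expm1(-xm / 4.0) if xm != 0 else 1.28
    xb = V - p.V_T - 40.0
    bm = -0.28 * xb / -np.expm1(xb / 5.0) if xb != 0 else 1.4
    ah = 0.128 * math.exp(-(V - p.V_T - 17.0) / 18.0)
    bh = 4.0 / (1.0 + math.exp(-(V - p.V_T - 40.0) / 5.0))
    xn = V - p.V_T - 15.0
    an = 0.032 * xn / -np.expm1(-xn / 5.0) if xn != 0 else 0.16
    bn = 0.5 * math.exp(-(V - p.V_T - 10.0) / 40.0)
    p_inf = 1.0 / (1.0 + math.exp(-(V + 35.0) / 10.0))
    tau_p = p.tau_max / (3.3 * math.exp((V + 35.0) / 20.0) + math.exp(-(V + 35.0) / 20.0))
    return am, bm, ah, bh, an, bn, p_inf, tau_p


class TestRates:
    def test_logistic_midpoint_of_slow_potassium_activation(self, params):
        assert compute_rates(-35.0, params).p_inf == pytest.approx(0.5)

    def test_slow_potassium_time_constant_at_midpoint(self, params):
        # both exponentials are unity at -35 mV: tau_p = tau_max / 4.3
        assert compute_rates(-35.0, params).tau_p == pytest.approx(1123.5 / 4.3)

    @pytest.mark.parametrize(
        "offset, attr, limit",
        [(13.0, "alpha_m", 0.32 * 4.0), (40.0, "beta_m", 0.28 * 5.0), (15.0, "alpha_n", 0.032 * 5.0)],
    )
    def test_removable_singularities_return_analytic_limit(self, params, offset, attr, limit):
        V0 = params.V_T + offset
        assert getattr(compute_rates(V0, params), attr) == pytest.approx(limit)
        # continuity across the singular point
        for dv in (-1e-6, 1e-6):
            val = getattr(compute_rates(V0 + 2 * dv, params), attr)
            assert val == pytest.approx(limit, rel=1e-5)

    @pytest.mark.parametrize("V", [-95.0, -70.3, -48.5, -35.0, -10.0, 20.0, 45.0])
    def test_rates_match_independent_expressions(self, params, V):
        r = compute_rates(V, params)
        expected = _oracle_rates(V, params)
        got = (r.alpha_m, r.beta_m, r.alpha_h, r.beta_h, r.alpha_n, r.beta_n, r.p_inf, r.tau_p)
        assert got == pytest.approx(expected, rel=1e-9)

    def test_rates_nonnegative_over_physiological_range(self, params):
        for V in np.linspace(-120.0, 60.0, 181):
            r = compute_rates(float(V), params)
            assert min(r.alpha_m, r.beta_m, r.alpha_h, r.beta_h, r.alpha_n, r.beta_n) >= 0.0
            assert 0.0 <= r.p_inf <= 1.0 and r.tau_p > 0.0

    def test_nonfinite_voltage_rejected(self, params):
        with pytest.raises(InvalidInputError):
            compute_rates(float("nan"), params)


class TestSteadyStateGating:
    @pytest.mark.parametrize("V", [-90.0, -70.3, -50.0, -20.0, 10.0])
    def test_values_in_unit_interval(self, params, V):
        assert all(0.0 <= g <= 1.0 for g in steady_state_gating(V, params))

    def test_matches_settled_gate_odes_at_clamped_potential(self, params):
        # relax the gate ODEs for 4 s at clamped V = -70.3 mV and compare
        V = -70.3
        r = compute_rates(V, params)
        dt, n = 0.01, 400000
        m = h = n_g = p = 0.5
        for _ in range(n):
            m += dt * (r.alpha_m * (1 - m) - r.beta_m * m)
            h += dt * (r.alpha_h * (1 - h) - r.beta_h * h)
            n_g += dt * (r.alpha_n * (1 - n_g) - r.beta_n * n_g)
            p += dt * (r.p_inf - p) / r.tau_p
        assert steady_state_gating(V, params) == pytest.approx((m, h, n_g, p), abs=1e-6)


class TestDerivatives:
    def test_zero_at_resting_fixed_point(self, params, resting):
        dV, *dgates = derivatives(resting, 0.0, params)
        assert abs(dV) < 1e-6
        assert all(abs(d) < 1e-9 for d in dgates)

    def test_sodium_current_vanishes_at_reversal(self, params):
        state = MembraneState(V_m=params.E_Na, m=0.7, h=0.4, n=0.3, p=0.2)
        assert current_densities(state, params)["Na"] == 0.0

    def test_potassium_currents_vanish_at_reversal(self, params):
        state = MembraneState(V_m=params.E_K, m=0.7, h=0.4, n=0.3, p=0.2)
        J = current_densities(state, params)
        assert J["K"] == 0.0 and J["M"] == 0.0

    @pytest.mark.parametrize("V,J_stim", [(-65.0, 0.0), (-40.0, 300.0), (-80.0, -50.0)])
    def test_membrane_equation_matches_independent_expression(self, params, V, J_stim):
        state = MembraneState(V_m=V, m=0.3, h=0.8, n=0.2, p=0.1)
        dV = derivatives(state, J_stim, params)[0]
        p = params
        # independent evaluation: J_ion summed explicitly, stimulus sign per contract
        J_ion = (
            p.g_leak * (V - p.E_leak)
            + p.gbar_Na * state.m ** 3 * state.h * (V - p.E_Na)
            + p.gbar_K * state.n ** 4 * (V - p.E_K)
            + p.gbar_M * state.p * (V - p.E_K)
        )
        assert dV == pytest.approx((J_stim - J_ion) / p.C_m, rel=1e-12)

    def test_positive_stimulus_depolarizes_from_rest(self, params, resting):
        assert derivatives(resting, 100.0, params)[0] > 0.0


class TestRestingState:
    def test_rest_between_reversal_potentials(self, params, resting):
        assert params.E_K < resting.V_m < params.E_Na

    def test_algebraic_and_settle_methods_agree(self, params, config):
        v_alg = find_resting_state(params, config, method="algebraic").V_m
        v_settle = find_resting_state(params, config, method="settle").V_m
        assert abs(v_alg - v_settle) < 0.01

    def test_leak_only_membrane_rests_at_leak_reversal(self):
        p = HHParameters(gbar_Na=0.0, gbar_K=0.0, gbar_M=0.0)
        assert find_resting_state(p).V_m == pytest.approx(-70.3, abs=1e-9)


class TestIntegrate:
    def test_rest_is_invariant_over_full_window(self, params, config, resting):
        wf = _rect_waveform(0.0, 10.0)
        trace = integrate(resting, wf, config, params)
        assert not trace.spiked
        assert np.max(np.abs(trace.V_m - resting.V_m)) < 0.01

    def test_suprathreshold_rectangle_spikes_with_overshoot(self, params, config, resting):
        wf = _rect_waveform(3000.0, 100.0)
        trace = integrate(resting, wf, config, params)
        assert trace.spiked
        assert trace.V_m.max() > 0.0
        assert trace.spike_time is not None

    def test_blowup_reports_step_index(self, params, config, resting):
        samples = np.full(100, 500.0)
        samples[5] = np.nan
        wf = StimulusWaveform(dt=1.0, samples=samples, phase_boundaries=(), spec="external")
        with pytest.raises(NumericalBlowupError) as err:
            integrate(resting, wf, config, params)
        assert err.value.step == 5

    def test_euler_matches_adaptive_high_order_integration(self, params, config, resting, coupling, reference_pulse):
        """Independent oracle: solve the same ODEs with an adaptive RK method."""
        spec = reference_pulse.replace(amplitude=7.0)  # subthreshold
        wf = build_pulse(spec, coupling, config.dt)
        trace = integrate(resting, wf, config, params)
        assert not trace.spiked

        samples = wf.samples

        def rhs(t, y):
            V, m, h, n, p = y
            k = int(t * 1000.0)  # ms -> sample index on the us grid
            J = samples[k] if k < len(samples) else 0.0
            state = MembraneState(
                V_m=V, m=min(max(m, 0.0), 1.0), h=min(max(h, 0.0), 1.0),
                n=min(max(n, 0.0), 1.0), p=min(max(p, 0.0), 1.0),
            )
            return derivatives(state, float(J), params)

        y0 = [resting.V_m, resting.m, resting.h, resting.n, resting.p]
        t_grid = trace.times / 1000.0
        seg_edges = [0.0, 0.06, 0.36, 20.0]
        V_ref = [resting.V_m]
        for a, b in zip(seg_edges[:-1], seg_edges[1:]):
            t_eval = t_grid[(t_grid > a + 1e-12) & (t_grid <= b + 1e-12)]
            sol = solve_ivp(rhs, (a, b), y0, t_eval=t_eval, rtol=1e-8, atol=1e-9, max_step=0.05)
            assert sol.success
            V_ref.extend(sol.y[0])
            y0 = sol.y[:, -1]
        assert np.max(np.abs(trace.V_m - np.array(V_ref))) < 0.5


class TestDetectSpike:
    def test_constant_resting_trace_has_no_spike(self):
        spiked, t = detect_spike(np.full(100, -70.3), dt=1.0)
        assert not spiked and t is None

    def test_first_crossing_time_on_synthetic_trace(self):
        V = np.concatenate([np.linspace(-70, -5, 50), np.linspace(1.0, 30.0, 10)])
        spiked, t = detect_spike(V, dt=1.0, spike_voltage=0.0)
        assert spiked and t == 50.0

    def test_only_upward_crossings_count(self):
        V = np.concatenate([np.full(10, 20.0), np.full(10, -50.0)])
        spiked, _ = detect_spike(V, dt=1.0)
        assert not spiked

    def test_empty_trace_rejected(self):
        with pytest.raises(InvalidInputError):
            detect_spike(np.array([]), dt=1.0)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(
    amp=st.floats(min_value=-7560.0, max_value=7560.0),
    width=st.integers(min_value=1, max_value=2000),
)
def test_gates_bounded_and_voltage_finite_under_bounded_stimuli(amp, width):
    """Gating variables stay in [0, 1] and V stays finite for any bounded rectangle."""
    params = HHParameters()
    config = SimulationConfig(n_steps=5000)
    resting = find_resting_state(params, config)
    trace = integrate(resting, _rect_waveform(amp, width), config, params)
    assert np.all(np.isfinite(trace.V_m))
    for g in trace.gates.values():
        assert g.min() >= 0.0 and g.max() <= 1.0
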