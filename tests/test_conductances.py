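"""Gating kinetics, current formulas, integrator fidelity and instability."""

import math

import numpy as np
import pytest

from dynclamp import (
    ConductanceState,
    boltzmann_gate,
    conductance_current,
    epsc_conductance,
    epsc_step,
    gate_step_euler,
    gate_step_exact,
    gate_step_rk4,
    hcn_conductance,
    m_type_conductance,
    na_conductance,
    na_step_response,
    shunt_conductance,
    tabulated_gate,
)
from dynclamp.conductances import step_gates
from dynclamp.ou import gaussian_stream


@pytest.fixture(scope="module")
def na_spec():
    return na_conductance(20.0)


@pytest.fixture(scope="module")
def hcn_gate():
    return hcn_conductance(2.0).gates[0]


class TestCurrentFormula:
    @pytest.mark.parametrize(
        "spec,state",
        [
            (shunt_conductance(5.0, E_rev=-60.0), ConductanceState()),
            (hcn_conductance(4.0, E_rev=-30.0), ConductanceState(gate_values=(0.5,))),
            (na_conductance(20.0), ConductanceState(gate_values=(0.7, 0.4))),
            (epsc_conductance(2.0), ConductanceState(synapse_s=0.8)),
        ],
    )
    def test_zero_driving_force_gives_zero_current(self, spec, state):
        assert conductance_current(spec, state, spec.E_rev) == 0.0

    def test_shunt_arithmetic(self):
        spec = shunt_conductance(5.0, E_rev=-70.0)
        assert conductance_current(spec, ConductanceState(), -60.0) == pytest.approx(-50.0)

    def test_sodium_full_activation(self):
        # m=h=1, g=20 nS, V=−70, E=+50 → I = 20·120 = +2400 pA (depolarizing)
        spec = na_conductance(20.0)
        st = ConductanceState(gate_values=(1.0, 1.0))
        assert conductance_current(spec, st, -70.0) == pytest.approx(2400.0)

    def test_current_locally_linear_in_driving_force(self):
        spec = hcn_conductance(4.0)
        st = ConductanceState(gate_values=(0.25,))
        g_eff = 4.0 * 0.25
        for dv in (-10.0, 3.0, 25.0):
            I = conductance_current(spec, st, spec.E_rev + dv)
            assert I == pytest.approx(-g_eff * dv)

    def test_mismatched_state_rejected(self):
        spec = na_conductance(20.0)
        with pytest.raises(ValueError):
            conductance_current(spec, ConductanceState(gate_values=(0.5,)), -70.0)


class TestGateSteppers:
    def test_steady_state_is_fixed_point(self, hcn_gate):
        for V in (-100.0, -82.0, -60.0):
            s = hcn_gate.s_inf(V)
            assert gate_step_euler(s, V, 0.5, hcn_gate) == pytest.approx(s, abs=1e-14)
            assert gate_step_exact(s, V, 0.5, hcn_gate) == pytest.approx(s, abs=1e-14)

    def test_euler_one_step_arithmetic(self):
        # s=0, s_inf=1, dt=τ → s' = 1 in a single Euler step
        gate = boltzmann_gate(-1000.0, -1.0, lambda V: 7.0)  # s_inf ≈ 1 at V = 10
        tau = gate.tau(10.0)
        s1 = gate_step_euler(0.0, 10.0, tau, gate)
        assert s1 == pytest.approx(gate.s_inf(10.0), rel=1e-9)

    def test_exact_identity_and_limit(self, hcn_gate):
        assert gate_step_exact(0.3, -90.0, 0.0, hcn_gate) == 0.3
        assert gate_step_exact(0.3, -90.0, 1e9, hcn_gate) == pytest.approx(
            hcn_gate.s_inf(-90.0), abs=1e-12
        )

    def test_exact_semigroup_property(self, hcn_gate):
        # two half steps equal one full step to machine precision
        s0, V, dt = 0.12, -75.0, 3.7
        one = gate_step_exact(s0, V, dt, hcn_gate)
        two = gate_step_exact(gate_step_exact(s0, V, dt / 2, hcn_gate), V, dt / 2, hcn_gate)
        assert two == pytest.approx(one, rel=1e-14)

    def test_exact_stays_in_unit_interval(self, hcn_gate):
        for s0 in (0.0, 0.37, 1.0):
            s = s0
            for _ in range(200):
                s = gate_step_exact(s, -70.0, 0.9, hcn_gate)
                assert 0.0 <= s <= 1.0

    def test_exact_matches_closed_form_relaxation(self, hcn_gate):
        # oracle: s(t) = s_inf + (s0 − s_inf)·exp(−t/τ), single long step
        s0, V, t = 0.9, -60.0, 12.5
        s_inf, tau = hcn_gate.s_inf(V), hcn_gate.tau(V)
        expected = s_inf + (s0 - s_inf) * math.exp(-t / tau)
        assert gate_step_exact(s0, V, t, hcn_gate) == pytest.approx(expected, rel=1e-15)

    def test_euler_fine_step_tracks_exact(self, hcn_gate):
        # dt = 1 µs over 50 ms at fixed V: |Euler − exact| < 1e-4
        V, dt = -95.0, 0.001
        se = sx = hcn_gate.s_inf(-70.0)
        worst = 0.0
        for k in range(50000):
            se = gate_step_euler(se, V, dt, hcn_gate)
            sx = gate_step_exact(sx, V, dt, hcn_gate)
            worst = max(worst, abs(se - sx))
        assert worst < 1e-4

    def test_euler_error_is_first_order_in_dt(self, hcn_gate):
        """log–log slope of the global Euler error vs dt lies in [0.9, 1.1]."""
        V, horizon = -95.0, 20.0
        s0 = hcn_gate.s_inf(-70.0)
        exact = gate_step_exact(s0, V, horizon, hcn_gate)
        dts = np.array([0.02, 0.04, 0.08, 0.16])
        errs = []
        for dt in dts:
            s = s0
            for _ in range(int(round(horizon / dt))):
                s = gate_step_euler(s, V, float(dt), hcn_gate)
            errs.append(abs(s - exact))
        slope = np.polyfit(np.log(dts), np.log(errs), 1)[0]
        assert 0.9 <= slope <= 1.1

    def test_clamping_flag_restricts_to_unit_interval(self, hcn_gate):
        s = gate_step_euler(0.99, -120.0, 100.0, hcn_gate, clamp=True)
        assert 0.0 <= s <= 1.0

    def test_rk4_single_step_close_to_exact(self, hcn_gate):
        s0, V, dt = 0.2, -80.0, 0.5
        assert gate_step_rk4(s0, V, dt, hcn_gate) == pytest.approx(
            gate_step_exact(s0, V, dt, hcn_gate), abs=1e-10
        )


class TestNaStepResponse:
    """Voltage-clamp step −70 → 0 mV at t = 20 ms: integrator comparison."""

    def test_rk4_matches_exact_at_current_peak(self, na_spec):
        ex = na_step_response(method="exact", dt=0.01, spec=na_spec)
        rk = na_step_response(method="rk4", dt=0.01, spec=na_spec)
        peak = np.abs(ex["I_pA"]).max()
        rel = np.abs(rk["I_pA"] - ex["I_pA"]).max() / peak
        assert rel < 1e-3

    def test_euler_unstable_beyond_twice_min_tau(self, na_spec):
        """Forward Euler diverges when dt exceeds 2τ at the potential where the
        gate is relaxing (linear-stability bound |1 − dt/τ| > 1)."""
        m_gate = na_spec.gates[0]
        tr = na_step_response(method="euler", dt=2.5 * m_gate.tau(0.0), spec=na_spec)
        assert np.abs(tr["m"]).max() > 1e3  # grows without bound

    def test_euler_stable_below_twice_min_tau(self, na_spec):
        m_gate = na_spec.gates[0]
        tau_min = min(m_gate.tau(-70.0), m_gate.tau(0.0))
        tr = na_step_response(method="euler", dt=0.5 * tau_min, spec=na_spec)
        assert np.abs(tr["m"]).max() < 2.0

    def test_euler_12us_error_concentrates_near_peak(self, na_spec):
        eu = na_step_response(method="euler", dt=0.012, spec=na_spec)
        ex = na_step_response(method="exact", dt=0.012, spec=na_spec)
        err = np.abs(eu["I_pA"] - ex["I_pA"])
        t_err = eu.t[np.argmax(err)]
        t_peak = ex.t[np.argmax(np.abs(ex["I_pA"]))]
        assert abs(t_err - t_peak) < 1.0  # worst deviation sits near the peak
        # and away from the peak the solutions agree closely
        far = (eu.t < 19.0) | (eu.t > 30.0)
        assert err[far].max() < 0.02 * np.abs(ex["I_pA"]).max()

    def test_jittered_euler_runs_and_stays_bounded(self, na_spec):
        tr = na_step_response(
            method="euler", dt=0.012, jitter_sd=0.002,
            rng=gaussian_stream(11), spec=na_spec,
        )
        assert np.all(np.diff(tr.t) > 0)
        assert np.abs(tr["m"]).max() < 2.0

    def test_activation_gate_is_fast(self, na_spec):
        # τ_m along a physiologic trajectory is well under 0.5 ms
        m_gate = na_spec.gates[0]
        assert max(m_gate.tau(v) for v in (-70.0, -40.0, 0.0)) < 0.5

    def test_unknown_method_rejected(self, na_spec):
        with pytest.raises(ValueError):
            na_step_response(method="leapfrog", dt=0.01, spec=na_spec)


class TestEPSC:
    def test_rest_state_is_absorbing(self):
        spec = epsc_conductance(2.0)
        st = ConductanceState()
        for _ in range(100):
            st = epsc_step(st, 0, 0.1, spec)
        assert st.synapse_x == 0.0 and st.synapse_s == 0.0

    def test_spike_delta_increments_x_by_one(self):
        spec = epsc_conductance(2.0)
        st = epsc_step(ConductanceState(), 1, 0.01, spec)
        # x jumps to 1 at the spike, then decays within the same step
        assert st.synapse_x == pytest.approx(1.0 * (1 - 0.01 / 1.0))
        st2 = epsc_step(ConductanceState(), 3, 0.01, spec)
        assert st2.synapse_x == pytest.approx(3.0 * (1 - 0.01 / 1.0))

    def test_s_saturates_below_one(self):
        spec = epsc_conductance(2.0)
        st = ConductanceState()
        for k in range(5000):
            st = epsc_step(st, 1 if k % 50 == 0 else 0, 0.05, spec)
            assert st.synapse_s <= 1.0 + 1e-12

    def test_x_decays_with_tau_x_between_spikes(self):
        spec = epsc_conductance(2.0, tau_x=1.0)
        st = epsc_step(ConductanceState(), 1, 0.001, spec)
        x0 = st.synapse_x
        for _ in range(999):
            st = epsc_step(st, 0, 0.001, spec)
        # after 1 ms ≈ τ_x the rise variable has decayed to ≈ x0/e
        assert st.synapse_x == pytest.approx(x0 / math.e, rel=0.01)

    def test_50hz_train_summates(self):
        """Pre-spike troughs of s grow over the first spikes of a 50 Hz train."""
        spec = epsc_conductance(2.0)  # τ_s=10, τ_x=1, α_s=1
        dt, isi = 0.05, 20.0
        st = ConductanceState()
        troughs = []
        t = 0.0
        next_spike = 0.0
        spikes_left = 10
        while t < 220.0:
            n = 0
            if spikes_left and t <= next_spike < t + dt:
                n, spikes_left = 1, spikes_left - 1
                troughs.append(st.synapse_s)  # value just before the spike
                next_spike += isi
            st = epsc_step(st, n, dt, spec)
            t += dt
        assert len(troughs) == 10
        assert all(b > a for a, b in zip(troughs[:5], troughs[1:6]))

    def test_10hz_train_barely_summates(self):
        spec = epsc_conductance(2.0)
        dt, isi = 0.05, 100.0
        st = ConductanceState()
        troughs = []
        t, next_spike, spikes_left = 0.0, 0.0, 5
        while t < 520.0:
            n = 0
            if spikes_left and t <= next_spike < t + dt:
                n, spikes_left = 1, spikes_left - 1
                troughs.append(st.synapse_s)
                next_spike += isi
            st = epsc_step(st, n, dt, spec)
            t += dt
        # at 10 Hz the synapse nearly resets between spikes
        assert max(troughs[1:]) < 0.02


class TestConfigurableKinetics:
    def test_m_type_runs_through_generic_gate_machinery(self):
        """A potassium M conductance is pure configuration, not new code."""
        spec = m_type_conductance(3.0)
        st = spec.initial_state(-70.0)
        st = step_gates(spec, st, -40.0, 0.1)
        I = conductance_current(spec, st, -40.0)
        assert I < 0  # outward (hyperpolarizing) above E_K
        # steady state activates with depolarization
        assert spec.gates[0].s_inf(-20.0) > spec.gates[0].s_inf(-60.0)

    def test_tabulated_gate_interpolates_and_extrapolates_flat(self):
        V = [-100.0, -50.0, 0.0]
        gate = tabulated_gate(V, [1.0, 0.5, 0.0], [10.0, 20.0, 10.0])
        assert gate.s_inf(-75.0) == pytest.approx(0.75)
        assert gate.s_inf(-200.0) == 1.0  # flat extrapolation
        assert gate.tau(50.0) == 10.0

    def test_tabulated_gate_validation(self):
        with pytest.raises(ValueError):
            tabulated_gate([0.0, 0.0], [0.1, 0.2], [1.0, 1.0])
        with pytest.raises(ValueError):
            tabulated_gate([0.0, 1.0], [0.1, 0.2], [1.0, -1.0])

    def test_hcn_steady_state_increases_with_hyperpolarization(self):
        gate = hcn_conductance(2.0).gates[0]
        assert gate.s_inf(-110.0) > gate.s_inf(-82.0) > gate.s_inf(-50.0)
        assert gate.s_inf(-82.0) == pytest.approx(0.5, abs=1e-9)
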