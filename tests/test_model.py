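"""Gating kinetics, currents, vector field and Jacobian."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pacesim.model import (
    GateSpec,
    ModelParams,
    ModelState,
    ParameterError,
    gate_steady_state,
    gate_time_constant,
    ionic_currents,
    jacobian,
    steady_gates,
    vector_field,
)

GATE = GateSpec(half_voltage=-50.0, slope=6.0, tau_base=0.3,
                tau_amp=0.8, tau_vmid=-55.0, tau_width=12.0)


class TestGateSteadyState:
    def test_midpoint_is_half(self):
        assert gate_steady_state(GATE.half_voltage, GATE) == pytest.approx(0.5)

    def test_saturation_limits(self):
        assert gate_steady_state(1e3, GATE) == pytest.approx(1.0)
        assert gate_steady_state(-1e3, GATE) == pytest.approx(0.0, abs=1e-12)

    def test_one_slope_above_midpoint(self):
        # logistic evaluated one slope-factor past the midpoint
        expected = 1.0 / (1.0 + np.exp(-1.0))
        got = gate_steady_state(GATE.half_voltage + GATE.slope, GATE)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(0.7310586, rel=1e-6)

    @given(st.floats(-120, 80), st.floats(-120, 80))
    @settings(max_examples=50, deadline=None)
    def test_monotone_with_slope_sign(self, v1, v2):
        lo, hi = sorted([v1, v2])
        act = gate_steady_state(np.array([lo, hi]), GATE)
        assert act[0] <= act[1]
        inact = GateSpec(-50.0, -6.0, 0.3)
        iv = gate_steady_state(np.array([lo, hi]), inact)
        assert iv[0] >= iv[1]

    def test_zero_slope_rejected(self):
        with pytest.raises(ParameterError):
            GateSpec(half_voltage=-50.0, slope=0.0, tau_base=0.3)


class TestGateTimeConstant:
    def test_degenerate_bell_is_constant(self):
        flat = GateSpec(-50.0, 6.0, tau_base=0.4, tau_amp=0.0)
        v = np.linspace(-120, 80, 7)
        assert np.allclose(gate_time_constant(v, flat), 0.4)

    def test_peak_and_one_width_out(self):
        assert gate_time_constant(GATE.tau_vmid, GATE) == pytest.approx(
            GATE.tau_base + GATE.tau_amp)
        got = gate_time_constant(GATE.tau_vmid + GATE.tau_width, GATE)
        assert got == pytest.approx(GATE.tau_base + GATE.tau_amp * np.exp(-1.0),
                                    rel=1e-12)

    def test_positive_everywhere(self):
        v = np.linspace(-120, 80, 401)
        assert np.all(gate_time_constant(v, GATE) > 0)


class TestCurrents:
    def test_zero_driving_force_kills_current(self, canonical):
        st_ = steady_gates(canonical.E_Na, canonical)
        assert ionic_currents(st_, canonical)["Na"] == pytest.approx(0.0)

    def test_closed_gates_leave_only_leak(self, canonical):
        y = np.array([-40.0, 0, 0, 0, 0, 0, 0], dtype=float)
        cur = ionic_currents(y, canonical)
        assert cur["Ca"] == cur["Na"] == cur["K"] == 0.0
        assert cur["Leak"] == pytest.approx(
            canonical.G_Leak * (-40.0 - canonical.E_Leak))

    def test_sodium_current_arithmetic(self, leak_only):
        p = leak_only.replace(G_Na=1.0, E_Na=-50.0)
        y = np.array([-40.0, 0, 0, 0.5, 0.5, 0, 0])
        assert ionic_currents(y, p)["Na"] == pytest.approx(1.0 * 0.5 * 0.5 * 10.0)


class TestVectorField:
    def test_gate_derivatives_vanish_at_steady_state(self, canonical):
        for v in (-80.0, -55.0, -20.0):
            dydt = vector_field(steady_gates(v, canonical), canonical)
            assert np.allclose(dydt[1:], 0.0, atol=1e-15)

    def test_dv_is_negative_current_sum(self, canonical):
        y = np.array([-48.0, 0.2, 0.6, 0.4, 0.3, 0.5, 0.9])
        cur = ionic_currents(y, canonical)
        assert vector_field(y, canonical)[0] == pytest.approx(
            -(cur["Leak"] + cur["Ca"] + cur["Na"] + cur["K"]))

    def test_state_validation(self):
        with pytest.raises(ParameterError):
            ModelState(v=-50.0, b=1.2, g=0.5, m=0.5, h=0.5, n=0.5, q=0.5)


def _central_difference_jacobian(y, params, eps=1e-6):
    n = y.size
    J = np.empty((n, n))
    for j in range(n):
        yp, ym = y.copy(), y.copy()
        yp[j] += eps
        ym[j] -= eps
        J[:, j] = (vector_field(yp, params) - vector_field(ym, params)) / (2 * eps)
    return J


class TestJacobian:
    def test_leak_only_voltage_row(self, leak_only):
        y = np.array([-50.0, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5])
        J = jacobian(y, leak_only)
        assert J[0, 0] == pytest.approx(-leak_only.G_Leak)
        assert np.allclose(J[0, 1:], 0.0)

    def test_gate_diagonal_is_negative_inverse_tau(self, canonical):
        v = -52.0
        y = steady_gates(v, canonical).to_array()
        J = jacobian(y, canonical)
        for i, (gname, spec) in enumerate(canonical.gates(), start=1):
            assert J[i, i] == pytest.approx(-1.0 / gate_time_constant(v, spec))

    def test_matches_central_differences_at_random_states(self, canonical):
        rng = np.random.default_rng(42)
        for _ in range(20):
            y = np.concatenate([[rng.uniform(-90, 0)], rng.uniform(0.05, 0.95, 6)])
            J = jacobian(y, canonical)
            J_fd = _central_difference_jacobian(y, canonical)
            scale = np.max(np.abs(J_fd)) or 1.0
            assert np.max(np.abs(J - J_fd)) / scale < 1e-5


class TestTrajectoryInvariants:
    def test_gates_stay_in_unit_box(self, canonical_trace):
        assert canonical_trace.gates is not None
        assert canonical_trace.gates.min() >= 0.0
        assert canonical_trace.gates.max() <= 1.0

    def test_current_decomposition_bookkeeping(self, canonical, canonical_trace):
        """dv/dt + I_Leak + I_Ca + I_Na + I_K = 0 along the solution."""
        tr = canonical_trace
        i0 = int(60.0 / tr.dt)
        ys = np.vstack([tr.v[i0:i0 + 500], tr.gates[:, i0:i0 + 500]])
        dvdt_model = np.array([vector_field(ys[:, k], canonical)[0]
                               for k in range(ys.shape[1])])
        currents = [ionic_currents(ys[:, k], canonical) for k in range(ys.shape[1])]
        total = np.array([c["Leak"] + c["Ca"] + c["Na"] + c["K"] for c in currents])
        assert np.allclose(dvdt_model + total, 0.0, atol=1e-9)
        # and the vector-field dv/dt matches the sampled numerical derivative
        dvdt_num = np.gradient(tr.v[i0:i0 + 500], tr.dt)
        # interior points only: np.gradient is one-sided at the edges
        assert np.max(np.abs(dvdt_model - dvdt_num)[1:-1]) < 0.5
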