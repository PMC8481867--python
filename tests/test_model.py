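"""Forward model: exact solver, steady state, structural identifiability."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bvkinetics import (
    InputProtocol,
    ModelParams,
    TransferCoeffs,
    delta_vb_from_hematocrit,
    from_transfer_coeffs,
    simulate,
    simulate_ivp,
    steady_state,
    to_transfer_coeffs,
)
from conftest import random_params, random_protocol


class TestSimulate:
    def test_zero_input_stays_at_baseline(self, reference_params):
        proto = InputProtocol([(0, 180, 0, 0)])
        traj = simulate(reference_params, proto, np.linspace(0, 180, 50))
        assert np.allclose(traj.delta_vb, 0.0)
        assert np.allclose(traj.d_delta_vb, 0.0)

    def test_symmetric_gain_loss_cancels(self):
        # equal distribution ratios and identical input rates: no net change
        params = ModelParams(alpha_u=1.7, alpha_v=1.7, k_p=0.2)
        proto = InputProtocol([(0, 60, 12.0, 12.0), (60, 120, 3.0, 3.0)])
        traj = simulate(params, proto, np.linspace(0, 120, 200))
        assert np.allclose(traj.delta_vb, 0.0, atol=1e-10)

    def test_infusion_approaches_retained_fraction(self, reference_params):
        # 300 mL infused with alpha_u=3: 1/4 retained intravascularly
        proto = InputProtocol([(0, 30, 10.0, 0.0), (30, 400, 0.0, 0.0)])
        traj = simulate(reference_params, proto, np.array([0.0, 30.0, 400.0]))
        assert traj.delta_vb[0] == 0.0
        assert traj.delta_vb[-1] == pytest.approx(300.0 / 4.0, rel=1e-6)

    def test_closed_form_matches_generic_integrator(self, reference_params):
        proto = InputProtocol([(0, 30, 10.0, 0.0), (30, 400, 0.0, 0.0)])
        times = np.linspace(0, 400, 200)
        exact = simulate(reference_params, proto, times).delta_vb
        numeric = simulate_ivp(reference_params, proto, times).delta_vb
        scale = max(np.max(np.abs(exact)), 1.0)
        assert np.max(np.abs(exact - numeric)) < 1e-6 * scale

    def test_satisfies_governing_equation(self, reference_params, study_protocol):
        # finite-difference residual of the second-order form vanishes as the
        # grid refines, within one smooth segment
        params = reference_params
        residual_norm = []
        for n in (200, 400, 800):
            t = np.linspace(80.1, 170.0, n)  # interior of the final segment
            traj = simulate(params, study_protocol, t)
            y = traj.delta_vb
            h = t[1] - t[0]
            d1 = np.gradient(y, h)
            d2 = np.gradient(d1, h)
            u, v = study_protocol.rates_at(t)
            rhs = params.k_p / (1 + params.alpha_u) * u - params.k_p / (1 + params.alpha_v) * v
            res = d2 + params.k_p * d1 - rhs  # input-rate derivatives are 0 inside a segment
            residual_norm.append(np.max(np.abs(res[5:-5])))
        assert residual_norm[-1] < residual_norm[0]
        assert residual_norm[-1] < 1e-4

    def test_random_protocols_closed_form_vs_integrator(self):
        rng = np.random.default_rng(2024)
        for _ in range(20):
            params = random_params(rng)
            proto = random_protocol(rng)
            times = np.sort(rng.uniform(0, proto.t_final, 40))
            exact = simulate(params, proto, times).delta_vb
            numeric = simulate_ivp(params, proto, times).delta_vb
            scale = max(np.max(np.abs(exact)), 1.0)
            assert np.max(np.abs(exact - numeric)) < 1e-6 * scale

    def test_times_outside_protocol_rejected(self, reference_params):
        proto = InputProtocol([(0, 60, 1.0, 0.0)])
        with pytest.raises(ValueError, match="within"):
            simulate(reference_params, proto, np.array([0.0, 61.0]))


class TestSteadyState:
    def test_zero_totals(self, reference_params):
        assert steady_state(reference_params, 0.0, 0.0) == 0.0

    def test_formula_value(self):
        params = ModelParams(alpha_u=3.0, alpha_v=1.0, k_p=0.1)
        assert steady_state(params, 1000.0, 800.0) == pytest.approx(-150.0)

    def test_symmetric_equal_totals(self):
        params = ModelParams(alpha_u=2.2, alpha_v=2.2, k_p=0.05)
        assert steady_state(params, 500.0, 500.0) == pytest.approx(0.0)

    def test_matches_long_time_simulation(self):
        # simulate far past input cessation (10 relaxation times)
        params = ModelParams(alpha_u=3.0, alpha_v=1.0, k_p=0.1)
        t_end = 80.0 + 10.0 / params.k_p
        proto = InputProtocol([(0, 50, 20.0, 16.0), (50, 80, 0.0, 10.0), (80, t_end, 0, 0)])
        traj = simulate(params, proto, np.array([t_end]))
        expected = steady_state(params, proto.total_infused, proto.total_hemorrhaged)
        assert traj.delta_vb[-1] == pytest.approx(expected, rel=1e-4)


class TestTransferCoeffs:
    def test_reference_values_and_round_trip(self, reference_params):
        c = to_transfer_coeffs(reference_params)
        assert c.pole == pytest.approx(0.14)
        assert c.zero_u == pytest.approx(0.035)
        assert c.zero_v == pytest.approx(0.14 / 2.40)
        back = from_transfer_coeffs(c)
        assert back.alpha_u == pytest.approx(3.0, abs=1e-14)
        assert back.alpha_v == pytest.approx(1.40, abs=1e-14)
        assert back.k_p == pytest.approx(0.14, abs=1e-16)

    def test_alpha_u_zero_makes_zero_equal_pole(self):
        c = to_transfer_coeffs(ModelParams(alpha_u=0.0, alpha_v=1.0, k_p=0.2))
        assert c.zero_u == c.pole

    @given(
        alpha_u=st.floats(-0.9, 50.0),
        alpha_v=st.floats(-0.9, 50.0),
        k_p=st.floats(1e-3, 10.0),
    )
    @settings(max_examples=200, derandomize=True)
    def test_round_trip_identity(self, alpha_u, alpha_v, k_p):
        """The transfer-coefficient map is a bijection: the executable form
        of global structural identifiability."""
        params = ModelParams(alpha_u, alpha_v, k_p)
        back = from_transfer_coeffs(to_transfer_coeffs(params))
        assert back.alpha_u == pytest.approx(alpha_u, rel=1e-9, abs=1e-9)
        assert back.alpha_v == pytest.approx(alpha_v, rel=1e-9, abs=1e-9)
        assert back.k_p == pytest.approx(k_p, rel=1e-12)

    def test_inverse_rejects_bad_pole(self):
        with pytest.raises(ValueError, match="pole"):
            from_transfer_coeffs(TransferCoeffs(pole=0.0, zero_u=0.1, zero_v=0.1))

    def test_zero_channel_maps_to_infinite_alpha(self):
        params = from_transfer_coeffs(TransferCoeffs(pole=0.1, zero_u=0.0, zero_v=0.05))
        assert np.isinf(params.alpha_u)
        assert params.alpha_v == pytest.approx(1.0)


class TestHematocrit:
    @pytest.mark.parametrize(
        "bv0,hct0,hct_t,expected",
        [
            (3000.0, 0.30, 0.30, 0.0),
            (3000.0, 0.30, 0.25, 600.0),
            (3000.0, 0.30, 0.40, -750.0),
        ],
    )
    def test_constant_red_cell_volume_relation(self, bv0, hct0, hct_t, expected):
        assert delta_vb_from_hematocrit(bv0, hct0, hct_t) == pytest.approx(expected)

    @pytest.mark.parametrize("hct_t", [0.0, 1.0, -0.1, 1.5])
    def test_rejects_out_of_range_hematocrit(self, hct_t):
        with pytest.raises(ValueError):
            delta_vb_from_hematocrit(3000.0, 0.30, hct_t)


class TestProtocolAndParams:
    def test_param_invariants_enforced(self):
        with pytest.raises(ValueError):
            ModelParams(alpha_u=-1.0, alpha_v=0.0, k_p=0.1)
        with pytest.raises(ValueError):
            ModelParams(alpha_u=0.0, alpha_v=-1.2, k_p=0.1)
        with pytest.raises(ValueError):
            ModelParams(alpha_u=0.0, alpha_v=0.0, k_p=0.0)

    def test_protocol_must_be_contiguous(self):
        with pytest.raises(ValueError, match="contiguous"):
            InputProtocol([(0, 10, 1, 0), (20, 30, 1, 0)])
        with pytest.raises(ValueError, match="non-negative"):
            InputProtocol([(0, 10, -1.0, 0)])
        with pytest.raises(ValueError, match="start at t=0"):
            InputProtocol([(5, 10, 1, 0)])

    def test_cumulative_volumes_piecewise_linear(self, study_protocol):
        t = np.linspace(0, 180, 361)
        cu, cv = study_protocol.cumulative(t)
        assert np.all(np.diff(cu) >= -1e-12)
        assert np.all(np.diff(cv) >= -1e-12)
        assert cv[-1] == pytest.approx(35.0 * 30.0)
        assert cu[-1] == pytest.approx(35.0 * 30.0)
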