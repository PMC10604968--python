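"""Drug transport: transvascular exchange, kinetics, and the IMEX solver."""

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.special import erfc

from ipchemo import transport as tp
from ipchemo.errors import UnstableStepError
from ipchemo.meshing import TISSUE, rectangle_channel_mesh


class TestPeclet:
    def test_zero_exchange_gives_zero(self):
        assert tp.peclet(0.0, tp.DrugParams(), 2e4) == 0.0

    def test_full_reflection_gives_zero(self):
        assert tp.peclet(1e-3, tp.DrugParams(sigma_f=1.0), 2e4) == 0.0

    def test_tabulated_value(self):
        # phi_B = 6.174e-4 1/s, sigma_f = 0.9, P S/V = 6e-2 1/s
        pe = tp.peclet(6.174e-4, tp.DrugParams(), 2e4)
        assert pe == pytest.approx(1.029e-3, rel=1e-3)

    def test_pe_factor_series_limit(self):
        assert tp.pe_factor(0.0) == 1.0
        assert tp.pe_factor(1e-9) == pytest.approx(1.0, abs=1e-8)
        assert tp.pe_factor(1.0) == pytest.approx(1.0 / (np.e - 1.0), rel=1e-12)


class TestVascularExchange:
    def test_zero_everywhere(self):
        assert tp.vascular_exchange(0.0, 0.0, tp.DrugParams()) == 0.0

    def test_small_pe_limit_matches_linear_form(self):
        p = tp.DrugParams(C_P=0.5)
        phi_B = 1e-12  # Pe ~ 1.7e-12
        got = tp.vascular_exchange(phi_B, 0.2, p, 2e4)
        expect = phi_B * (1 - p.sigma_f) * p.C_P + p.P_wall * 2e4 * (p.C_P - 0.2)
        assert got == pytest.approx(expect, rel=1e-6)

    def test_vessels_act_as_sinks_for_ip_dosing(self):
        # C_P = 0, C_F = 0.8: net exchange is a sink of ~4.798e-2 mol/m^3/s
        got = tp.vascular_exchange(6.174e-4, 0.8, tp.DrugParams(), 2e4)
        assert got == pytest.approx(-4.798e-2, rel=1e-3)
        assert got < 0


class TestKinetics:
    def test_matrix_exponential_oracle(self):
        """Clamped C_F: (C_B, C_I) matches the 2x2 matrix exponential to 1e-6."""
        p = tp.DrugParams()
        lam = p.k_off_eff + p.K_INT
        A = np.array([[-lam, 0.0], [p.K_INT, 0.0]])
        g = np.array([p.k_on_eff * 0.8, 0.0])

        def oracle(t):
            # variation-of-constants with the exact matrix exponential
            E = expm(A * t)
            # integral of expm(A s) ds via the augmented-matrix trick
            Aug = np.zeros((4, 4))
            Aug[:2, :2] = A
            Aug[:2, 2:] = np.eye(2)
            I_int = expm(Aug * t)[:2, 2:]
            return I_int @ g

        B = np.array([0.0])
        I = np.array([0.0])
        for _ in range(3600):
            B, I = tp.kinetics_step(B, I, np.array([0.8]), p, 1.0)
        exact = oracle(3600.0)
        assert B[0] == pytest.approx(exact[0], rel=1e-6)
        assert I[0] == pytest.approx(exact[1], rel=1e-6)

    def test_effective_rates(self):
        p = tp.DrugParams()
        assert p.k_on_eff == pytest.approx(5e-3)
        assert p.k_off_eff == pytest.approx(2.667e-2, rel=1e-3)

    def test_no_decay_limit(self):
        p = tp.DrugParams(K_OFF=0.0, K_INT=0.0)
        B, I = tp.kinetics_step(np.array([0.1]), np.array([0.0]), np.array([1.0]), p, 2.0)
        assert B[0] == pytest.approx(0.1 + 2.0 * p.k_on_eff)
        assert I[0] == 0.0


class TestStepAndRun:
    def test_zero_state_stays_zero(self, strip_mesh):
        p = tp.DrugParams(C_surface=0.0)
        states, series, _ = tp.run_transport(strip_mesh, None, p, duration=10.0, dt=1.0)
        assert np.abs(states[-1].C_T).max() == 0.0

    def test_pure_diffusion_erfc_front(self, strip_mesh):
        """1D complementary-error-function front at t = 600 s within 2%."""
        p = tp.DrugParams(K_ON=0.0, K_OFF=0.0, K_INT=0.0)
        states, _, _ = tp.run_transport(
            strip_mesh, None, p, duration=600.0, dt=1.0, checkpoints=(600.0,)
        )
        x = strip_mesh.nodes[:, 0] * 1e-3
        exact = p.C_surface * erfc(x / (2.0 * np.sqrt(p.D_F * 600.0)))
        assert np.max(np.abs(states[-1].C_F - exact)) < 0.02 * p.C_surface

    def test_duration_zero_returns_initial_state(self, strip_mesh):
        states, series, _ = tp.run_transport(strip_mesh, None, tp.DrugParams(), duration=0.0)
        assert len(states) == 1 and states[0].t == 0.0
        assert len(series) == 1

    def test_mean_free_drug_nondecreasing_without_sinks(self, strip_mesh):
        _, series, _ = tp.run_transport(strip_mesh, None, tp.DrugParams(), duration=120.0, dt=1.0)
        assert np.all(np.diff(series["C_F"]) >= -1e-14)

    def test_halving_dt_changes_final_mean_little(self, strip_mesh):
        p = tp.DrugParams()
        _, s1, _ = tp.run_transport(strip_mesh, None, p, duration=300.0, dt=2.0)
        _, s2, _ = tp.run_transport(strip_mesh, None, p, duration=300.0, dt=1.0)
        a = s1["C_T"].iloc[-1]
        b = s2["C_T"].iloc[-1]
        assert abs(a - b) / b < 0.01

    def test_nonnegativity_and_monotone_internalized(self, network_mesh, network_flow):
        states, _, _ = tp.run_transport(
            network_mesh, network_flow, duration=60.0, dt=1.0,
            checkpoints=(20.0, 40.0, 60.0),
        )
        for s in states:
            assert s.C_F.min() >= -1e-10
            assert s.C_B.min() >= -1e-12
            assert s.C_I.min() >= -1e-14
        for a, b in zip(states, states[1:]):
            assert np.all(b.C_I - a.C_I >= -1e-14)

    def test_mass_budget_closes_per_step(self, network_mesh, network_flow):
        _, _, solver = tp.run_transport(network_mesh, network_flow, duration=60.0, dt=1.0)
        assert solver.max_budget_violation() < 0.01

    def test_unstable_dt_is_error(self, network_mesh, network_flow):
        with pytest.raises(UnstableStepError):
            tp.TransportSolver(network_mesh, network_flow, dt=1e6)
        with pytest.raises(UnstableStepError):
            tp.TransportSolver(network_mesh, network_flow, dt=-1.0)

    def test_step_transport_wrapper_advances_time(self, strip_mesh):
        solver = tp.TransportSolver(strip_mesh, None, tp.DrugParams(), dt=1.0)
        s0 = solver.initial_state()
        s1 = tp.step_transport(s0, None, tp.DrugParams(), 1.0, solver=solver)
        assert s1.t == 1.0
        assert s1.C_F.max() <= 0.8 + 1e-12

    def test_legacy_unbinding_sign_loses_mass(self, strip_mesh):
        """The as-printed sign variant removes the unbinding return flux."""
        p = tp.DrugParams()
        _, s_std, _ = tp.run_transport(strip_mesh, None, p, duration=200.0, dt=1.0)
        _, s_leg, _ = tp.run_transport(
            strip_mesh, None, p, duration=200.0, dt=1.0, legacy_unbinding_sign=True
        )
        assert s_leg["C_F"].iloc[-1] < s_std["C_F"].iloc[-1]
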