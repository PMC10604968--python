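"""Steady flow: unit conversion, Starling exchange, Stokes and Darcy solves."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import i0

from ipchemo import flow as fl
from ipchemo import meshing as ms
from ipchemo.errors import IsolatedLumenError, NotSolvedError
from ipchemo.units import mmhg_to_pa


@pytest.mark.parametrize(
    "mmhg,pa", [(0.0, 0.0), (25.0, 3333.06), (10.0, 1333.224)]
)
def test_mmhg_to_pa(mmhg, pa):
    assert mmhg_to_pa(mmhg) == pytest.approx(pa, abs=0.01)


class TestStarling:
    def test_tabulated_values_at_zero_pressure(self, tissue_params):
        # L_p (S/V) = 4.2e-7 1/(Pa s); driving pressure 2100 - 0.9*700 = 1470 Pa
        assert fl.starling_phi_B(0.0, tissue_params) == pytest.approx(6.174e-4, rel=1e-12)

    def test_equilibrium_pressure_gives_zero(self, tissue_params):
        assert fl.starling_phi_B(1470.0, tissue_params) == 0.0
        assert tissue_params.effective_pressure == 1470.0

    def test_no_osmotic_reflection(self):
        p = fl.TissueParams(sigma_s=0.0)
        assert fl.starling_phi_B(p.P_B, p) == 0.0

    def test_can_reverse_sign(self, tissue_params):
        assert fl.starling_phi_B(2000.0, tissue_params) < 0.0

    def test_parameter_ranges_enforced(self):
        with pytest.raises(ValueError):
            fl.TissueParams(sigma_s=1.5)
        with pytest.raises(ValueError):
            fl.TissueParams(K=0.0)


class TestIntravascularStokes:
    def test_plane_poiseuille_linear_pressure(self, channel_mesh):
        bcs = fl.FlowBCs()
        IBP, _, _ = fl.solve_intravascular(channel_mesh, bcs, mu=3e-3)
        x = channel_mesh.nodes[:, 0] * 1e-3
        expected = bcs.inlet_pressure + (bcs.outlet_pressure - bcs.inlet_pressure) * x / 1e-3
        drop = bcs.inlet_pressure - bcs.outlet_pressure
        assert np.max(np.abs(IBP - expected)) < 0.015 * drop

    def test_plane_poiseuille_centerline_speed(self, channel_mesh):
        bcs = fl.FlowBCs()
        _, _, UV = fl.solve_intravascular(channel_mesh, bcs, mu=3e-3)
        mid = np.isclose(channel_mesh.nodes[:, 0], 0.5)
        Q = fl.terminal_fluxes(channel_mesh, UV)
        mean_u = -Q["Inlet1"] / 0.1e-3
        assert UV[mid, 0].max() / mean_u == pytest.approx(1.5, rel=0.01)

    def test_inflow_equals_outflow(self, channel_mesh, network_mesh):
        for mesh in (channel_mesh, network_mesh):
            _, _, UV = fl.solve_intravascular(mesh, fl.FlowBCs(), mu=3e-3)
            Q = fl.terminal_fluxes(mesh, UV)
            qin = sum(v for k, v in Q.items() if k.startswith("Inlet"))
            qout = sum(v for k, v in Q.items() if k.startswith("Outlet"))
            assert abs(qin + qout) <= 1e-3 * max(abs(qin), abs(qout))

    def test_pressure_maximum_principle(self, network_mesh):
        bcs = fl.FlowBCs()
        IBP, _, _ = fl.solve_intravascular(network_mesh, bcs, mu=3e-3)
        fin = IBP[np.isfinite(IBP)]
        drop = bcs.inlet_pressure - bcs.outlet_pressure
        assert fin.max() <= bcs.inlet_pressure + 0.01 * drop
        assert fin.min() >= bcs.outlet_pressure - 0.01 * drop

    def test_straight_channel_ibp_ratio(self, channel_mesh):
        IBP, _, _ = fl.solve_intravascular(channel_mesh, fl.FlowBCs(), mu=3e-3)
        assert IBP.max() / IBP.min() == pytest.approx(2.5004, rel=0.01)

    def test_isolated_lumen_is_error(self):
        mesh = ms.rectangle_channel_mesh(
            1.0, 0.1, 0.025, left_tag="vessel_wall", right_tag="vessel_wall",
            terminal_roles={},
        )
        with pytest.raises(IsolatedLumenError):
            fl.solve_intravascular(mesh)


class TestInterstitialDarcy:
    def test_bessel_disc_oracle(self, disc_mesh, disc_flow, tissue_params):
        """Distributed-mode IFP matches P_e [1 - I0(ar)/I0(aR)] on the disc."""
        R = 1.755e-3
        r = np.hypot(disc_mesh.nodes[:, 0], disc_mesh.nodes[:, 1]) * 1e-3
        Pe = tissue_params.effective_pressure
        exact = Pe * (1 - i0(tissue_params.alpha * r) / i0(tissue_params.alpha * R))
        assert np.nanmax(np.abs(disc_flow.IFP - exact)) < 0.01 * Pe

    def test_bessel_disc_center_and_ceiling(self, disc_mesh, disc_flow, tissue_params):
        r = np.hypot(disc_mesh.nodes[:, 0], disc_mesh.nodes[:, 1])
        center = disc_flow.IFP[np.argmin(r)]
        assert center == pytest.approx(1457.0, abs=7.0)
        assert np.nanmax(disc_flow.IFP) <= tissue_params.effective_pressure
        assert np.nanmin(disc_flow.IFP) >= 0.0

    def test_sealed_walls_give_zero_field(self, disc_mesh):
        p = fl.TissueParams(L_p=0.0)
        sol = fl.solve_interstitial(disc_mesh, p, coupling_mode="distributed")
        assert np.nanmax(np.abs(sol.IFP)) < 1e-9
        assert np.abs(sol.IFV).max() < 1e-20

    def test_radial_monotone_decay(self, disc_mesh, disc_flow):
        r = np.hypot(disc_mesh.nodes[:, 0], disc_mesh.nodes[:, 1])
        order = np.argsort(r)
        binned = np.array_split(disc_flow.IFP[order], 40)
        means = np.array([np.nanmean(b) for b in binned])
        assert np.all(np.diff(means) <= 1e-6)

    def test_wall_coupled_exceeds_distributed_ceiling(self, network_flow, tissue_params):
        # lumen-pressure coupling can push IFP above the constant-P_B ceiling
        assert np.nanmax(network_flow.IFP) > tissue_params.effective_pressure

    def test_wall_coupled_fluid_balance(self, network_flow):
        assert network_flow.wall_inflow == pytest.approx(
            network_flow.surface_outflow, rel=0.01
        )

    def test_surface_pressure_boundary_condition(self, network_flow, network_mesh):
        surf = network_mesh.boundary_nodes("tumor_surface")
        assert np.abs(network_flow.IFP[surf]).max() < 1e-9


class TestFlowSummary:
    def test_uniform_field_trivial(self, disc_mesh, tissue_params):
        sol = fl.FlowSolution(
            mesh=disc_mesh, params=tissue_params, bcs=fl.FlowBCs(),
            coupling_mode="distributed",
            IFP=np.full(disc_mesh.n_nodes, 7.0),
            IFV=np.zeros((disc_mesh.n_triangles, 2)),
        )
        s = fl.flow_summary(sol)
        assert s["mean_IFP_Pa"] == pytest.approx(7.0)
        assert s["max_IFP_Pa"] == pytest.approx(7.0)
        assert s["max_IFV_m_per_s"] == 0.0

    def test_bessel_mean_matches_quadrature(self, disc_flow, tissue_params):
        R = 1.755e-3
        Pe = tissue_params.effective_pressure
        a = tissue_params.alpha
        exact_mean = quad(
            lambda rr: Pe * (1 - i0(a * rr) / i0(a * R)) * 2 * np.pi * rr, 0, R
        )[0] / (np.pi * R**2)
        assert fl.flow_summary(disc_flow)["mean_IFP_Pa"] == pytest.approx(
            exact_mean, rel=0.01
        )

    def test_ibp_ratio_reported_both_ways(self, network_flow):
        s = fl.flow_summary(network_flow)
        assert s["IBP_ratio_max_over_min"] == pytest.approx(
            1.0 / s["IBP_ratio_min_over_max"], rel=1e-9
        )

    def test_unsolved_is_error(self, disc_mesh, tissue_params):
        sol = fl.FlowSolution(
            mesh=disc_mesh, params=tissue_params, bcs=fl.FlowBCs(),
            coupling_mode="distributed",
        )
        with pytest.raises(NotSolvedError):
            fl.flow_summary(sol)
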