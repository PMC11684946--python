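"""Thin-film solver: analytic oracles, Stokes linearity, Carreau closure."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from alveoflow import geometry as geo
from alveoflow import sheetflow as sf
from alveoflow.errors import (EmptyBandError, InvalidGeometryError,
                              ResolutionError, SingularSystemError)


def strip_problem(Q=1.0418625e-13, mu=0.002, edge=1.0):
    strip = geo.make_strip_domain(width=10.0, length=100.0, sheet_height=6.3,
                                  target_edge_length=edge)
    return sf.SheetFlowProblem(
        domain=strip, fluid=sf.FluidModel.newtonian(mu),
        bc=sf.BoundaryConditions(outlet_pressure=0.0),
        friction_factor_mode="unity", vessel_stub_length=0.0,
        inlet_flux_override={"port_0": Q})


class TestStripOracle:
    def test_plane_poiseuille_closed_form(self):
        # Q = w h³ Δp / (12 µ L): injecting that flux must drop 100 Pa
        sol = sf.assemble_and_solve_newtonian(strip_problem())
        assert sol.pressure_drop_pa == pytest.approx(100.0, rel=0.01)

    def test_strip_mass_balance(self):
        sol = sf.assemble_and_solve_newtonian(strip_problem())
        assert sol.mass_balance_residual < 1e-8

    def test_uniform_speed_mean(self):
        sol = sf.assemble_and_solve_newtonian(strip_problem())
        # 1-D channel flow: every element carries the same depth-averaged speed
        assert sol.speed.std() / sol.speed.mean() < 1e-6
        prob = strip_problem()
        assert sf.mean_capillary_speed(sol, prob.domain) == pytest.approx(
            sol.speed.mean(), rel=1e-12)


class TestDefaultFlow:
    def test_mass_balance(self, newtonian_solution):
        assert newtonian_solution.mass_balance_residual < 1e-8

    def test_discrete_maximum_principle(self, newtonian_solution, default_domain):
        p = newtonian_solution.pressure
        rims = np.concatenate([default_domain.boundary_loops[pr.label]
                               for pr in default_domain.ports])
        dp = p.max() - p.min()
        assert p.min() >= p[rims].min() - 1e-8 * dp
        assert p.max() <= p[rims].max() + 1e-8 * dp

    def test_linearity_in_inlet_velocity(self, default_domain):
        sol1 = sf.assemble_and_solve_newtonian(sf.SheetFlowProblem(
            domain=default_domain, bc=sf.BoundaryConditions(inlet_velocity=0.0023)))
        sol2 = sf.assemble_and_solve_newtonian(sf.SheetFlowProblem(
            domain=default_domain, bc=sf.BoundaryConditions(inlet_velocity=0.0046)))
        assert sol2.mean_capillary_speed == pytest.approx(
            2 * sol1.mean_capillary_speed, rel=1e-10)

    def test_zero_inflow_is_hydrostatic(self, default_domain):
        sol = sf.assemble_and_solve_newtonian(sf.SheetFlowProblem(
            domain=default_domain, bc=sf.BoundaryConditions(inlet_velocity=0.0)))
        assert np.allclose(sol.pressure, 1127.0)
        assert np.allclose(sol.speed, 0.0)
        assert sol.pressure_drop_mmhg == 0.0

    def test_no_outlet_is_singular(self, base_no_venule):
        with pytest.raises(SingularSystemError):
            sf.assemble_and_solve_newtonian(sf.SheetFlowProblem(domain=base_no_venule))

    def test_position_speeds_structure(self, newtonian_solution):
        pos = newtonian_solution.position_speeds
        assert set(pos) == {"inlet", "near_arteriole", "center", "near_venule",
                            "outlet"}
        assert pos["inlet"] == pytest.approx(0.0023)
        # flow concentrates at the ports (Hele-Shaw source spreading)
        assert pos["near_arteriole"] > pos["center"]
        # symmetric default: the two near-port bands agree
        assert pos["near_arteriole"] == pytest.approx(pos["near_venule"], rel=0.10)


@pytest.fixture(scope="module")
def base_no_venule(params):
    base = params.solve_base()
    cfg = geo.ConnectivityConfig()
    R_mid = base.sphere_radius + params.sheet_height / 2
    ports = [p for p in geo.place_ports(base, cfg, mid_surface_radius=R_mid)
             if p.kind == "arteriole"]
    pores = geo.place_pores(base, 17, 12.3, seed=1, exclusions=ports)
    return geo.build_sheet_midsurface(base, pores, ports, 4.0,
                                      params.sheet_height)


class TestPressureDrop:
    def test_stub_loss_closed_form(self):
        prob = strip_problem()
        # 32 µ L v / d²: d=20 µm, L=100 µm, v=2.3 mm/s, µ=2 cP -> 36.8 Pa
        assert sf._stub_loss_pa(
            sf.SheetFlowProblem(domain=prob.domain,
                                fluid=sf.FluidModel.newtonian(0.002),
                                vessel_stub_length=100.0),
            20.0, 2.3e-3) == pytest.approx(36.8, rel=1e-12)

    def test_invariant_to_outlet_pressure(self, default_domain):
        sols = [sf.assemble_and_solve_newtonian(sf.SheetFlowProblem(
            domain=default_domain,
            bc=sf.BoundaryConditions(outlet_pressure=p))) for p in (500.0, 1500.0)]
        assert sols[0].pressure_drop_pa == pytest.approx(
            sols[1].pressure_drop_pa, rel=1e-9)

    def test_linear_in_viscosity(self, default_domain):
        dps = [sf.assemble_and_solve_newtonian(sf.SheetFlowProblem(
            domain=default_domain, fluid=sf.FluidModel.newtonian(mu),
            friction_factor_mode="unity")).pressure_drop_pa
            for mu in (0.002, 0.004)]
        assert dps[1] == pytest.approx(2 * dps[0], rel=1e-10)


class TestCarreau:
    def test_viscosity_limits(self):
        assert sf.carreau_viscosity(0.0) == pytest.approx(0.056)
        assert sf.carreau_viscosity(1e9) == pytest.approx(0.0035, rel=1e-3)

    def test_viscosity_at_reference_shear(self):
        assert sf.carreau_viscosity(380.0) == pytest.approx(4.26e-3, rel=0.01)

    @settings(max_examples=60, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=1e8))
    def test_viscosity_bounded_and_decreasing(self, gamma):
        eta = sf.carreau_viscosity(gamma)
        assert 0.0035 - 1e-15 <= eta <= 0.056 + 1e-15
        assert sf.carreau_viscosity(gamma * 2 + 1e-6) <= eta + 1e-18

    def test_speed_close_to_newtonian(self, newtonian_solution, carreau_solution):
        assert carreau_solution.mean_capillary_speed == pytest.approx(
            newtonian_solution.mean_capillary_speed, rel=0.03)

    def test_degenerates_to_newtonian(self, default_domain):
        mu = 0.002
        newton = sf.assemble_and_solve_newtonian(
            sf.SheetFlowProblem(domain=default_domain,
                                fluid=sf.FluidModel.newtonian(mu)))
        pseudo = sf.solve_carreau(sf.SheetFlowProblem(
            domain=default_domain,
            fluid=sf.FluidModel.carreau(eta0=mu, eta_inf=mu)))
        assert pseudo.mean_capillary_speed == pytest.approx(
            newton.mean_capillary_speed, rel=1e-6)
        assert pseudo.pressure_drop_pa == pytest.approx(
            newton.pressure_drop_pa, rel=1e-6)


class TestFrictionFactor:
    def test_vanishing_pillars(self):
        assert sf.estimate_friction_factor(0.0, 9.27) == 1.0
        assert sf.estimate_friction_factor(0.4, 9.27, resolution=241) == \
            pytest.approx(1.0, abs=0.01)

    def test_default_lattice_in_expected_band(self):
        f = sf.estimate_friction_factor(3.1, 9.27)
        assert 1.0 < f <= 2.0

    def test_monotone_in_pillar_diameter(self):
        fs = [sf.estimate_friction_factor(d, 9.27, resolution=81)
              for d in (1.5, 3.1, 5.0)]
        assert fs[0] < fs[1] < fs[2]

    def test_too_coarse_rejected(self):
        with pytest.raises(ResolutionError):
            sf.estimate_friction_factor(0.2, 9.27, resolution=41)


class TestReynolds:
    def test_reference_value(self):
        re = sf.reynolds_number(sf.FluidModel.newtonian(), 2.3e-3, 6.3e-6)
        assert re == pytest.approx(0.0076, abs=5e-5)

    def test_zero_velocity(self):
        assert sf.reynolds_number(sf.FluidModel.newtonian(), 0.0, 1.0) == 0.0

    def test_definition(self):
        fluid = sf.FluidModel(density=1000.0, rheology="newtonian", mu=1.0)
        assert sf.reynolds_number(fluid, 1.0, 1.0) == pytest.approx(1000.0)

    def test_carreau_uses_infinite_shear_viscosity(self):
        re = sf.reynolds_number(sf.FluidModel.carreau(), 2.3e-3, 6.3e-6)
        assert re == pytest.approx(1050 * 2.3e-3 * 6.3e-6 / 0.0035, rel=1e-12)
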