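"""Finite-element solver: analytic oracles and conservation invariants.

All solves here use short domains and coarse meshes so the suite stays
fast; the full-length bench geometry is exercised in the acceptance tests.
"""

import numpy as np
import pytest

from stentflow import geometry as geo
from stentflow import postprocess as post
from stentflow.solver import (BoundaryConditions, FluidProps,
                              convergence_study, solve_steady_flow)


@pytest.fixture(scope="module")
def fluid():
    return FluidProps()


@pytest.fixture(scope="module")
def bc():
    return BoundaryConditions()


@pytest.fixture(scope="module")
def short_channel():
    """Unstented channel with cones, 40 mm straight segment."""
    return geo.build_domain(geo.UreterSpec(length_L=40.0, cone_length=10.0))


@pytest.fixture(scope="module")
def short_channel_flow(short_channel, fluid, bc):
    mesh = geo.generate_mesh(short_channel, h_global=1.0, h_sh=0.25)
    return solve_steady_flow(mesh, fluid, bc)


@pytest.fixture(scope="module")
def short_stented():
    """Two-side-hole stent in a 70 mm ureter (same cross-section as bench)."""
    ureter = geo.UreterSpec(length_L=70.0)
    holes = (geo.SideHole(1, 12.8, 1.0), geo.SideHole(2, 47.8, 1.0))
    stent = geo.StentSpec(lumen_diameter_Ds=1.0, side_holes=holes)
    return geo.build_domain(ureter, stent)


@pytest.fixture(scope="module")
def short_stented_flow(short_stented, fluid, bc):
    mesh = geo.generate_mesh(short_stented, h_global=1.0, h_sh=0.1)
    return solve_steady_flow(mesh, fluid, bc)


class TestFluidProps:
    def test_mu_consistent(self, fluid):
        assert fluid.dynamic_viscosity_mu == pytest.approx(
            fluid.density_rho * fluid.kinematic_viscosity_nu, rel=1e-12)

    def test_invalid(self):
        with pytest.raises(ValueError):
            FluidProps(density_rho=-1.0)


class TestBaseFlow:
    def test_plane_poiseuille_recovered(self, short_channel_flow):
        """P2 elements contain the parabola: the straight-section profile
        matches plane Poiseuille essentially to solver precision."""
        dom = short_channel_flow.mesh.domain
        rr = np.linspace(-1.999, 1.999, 101)
        x = 0.5 * dom.ureter.length_L
        u, v = short_channel_flow.velocity(np.full(rr.shape, x), rr)
        uc = 1.5 * 0.235 * 30.0 / 4.0  # exact centerline from mass conservation
        ref = uc * (1 - (rr / 2.0) ** 2)
        prof = post.Profile(coords=rr, u=u, v=v, Uc=2.64)
        refp = post.Profile(coords=rr, u=ref, v=np.zeros_like(ref), Uc=2.64)
        err = post.poiseuille_error(prof, refp)
        assert err.eps_u <= 1e-3  # bench-model validation bound 0.1%
        assert err.eps_v <= 1e-4

    def test_mass_imbalance(self, short_channel_flow):
        assert short_channel_flow.mass_imbalance() < 2e-3

    def test_no_slip(self, short_channel_flow):
        assert short_channel_flow.no_slip_error() < 1e-12

    def test_outlet_pressure_anchored(self, short_channel_flow):
        dom = short_channel_flow.mesh.domain
        p = short_channel_flow.pressure(dom.x_max - 1e-6, 0.0)
        p_in = short_channel_flow.pressure(dom.x_min + 1e-6, 0.0)
        assert abs(p[0]) < 1e-3 * abs(p_in[0] - p[0]) + 1e-12

    def test_zero_inflow_gives_zero_field(self, short_channel, fluid):
        mesh = geo.generate_mesh(short_channel, h_global=2.0, h_sh=0.5)
        fld = solve_steady_flow(mesh, fluid,
                                BoundaryConditions(inlet_mean_velocity=0.0))
        assert np.max(np.abs(fld.ux)) < 1e-12
        assert np.max(np.abs(fld.uy)) < 1e-12

    def test_deterministic(self, short_channel, fluid, bc):
        mesh = geo.generate_mesh(short_channel, h_global=2.0, h_sh=0.5)
        a = solve_steady_flow(mesh, fluid, bc)
        b = solve_steady_flow(mesh, fluid, bc)
        assert np.array_equal(a.ux, b.ux)
        assert np.array_equal(a.p_kin, b.p_kin)

    def test_reynolds_warning(self, short_channel, fluid):
        """Operating far outside the laminar design regime warns."""
        import contextlib

        mesh = geo.generate_mesh(short_channel, h_global=2.0, h_sh=0.5)
        with pytest.warns(UserWarning, match="Reynolds"), \
                contextlib.suppress(RuntimeError):
            solve_steady_flow(mesh, fluid,
                              BoundaryConditions(inlet_mean_velocity=50.0),
                              max_iter=3)


class TestStentedFlow:
    def test_cross_section_mass_conservation(self, short_stented_flow):
        """int U dr over lumen + extraluminal bands equals the inlet flux at
        any straight-section station."""
        q0 = short_stented_flow.inlet_flux()
        for x in (5.0, 30.0, 65.0):
            q = short_stented_flow.cross_section_flux(x)
            assert q == pytest.approx(q0, rel=5e-3)

    def test_signed_flux_balance(self, short_stented_flow):
        """Lumen inlet flux plus signed side-hole inflows equals the lumen
        flux at the stent outlet."""
        dom = short_stented_flow.mesh.domain
        st = dom.stent
        q_in = post.luminal_flux(short_stented_flow, st, x=dom.stent_x_min)
        q_out = post.luminal_flux(short_stented_flow, st, x=dom.stent_x_max)
        q_sh = sum(post.sh_flux(short_stented_flow, sh).flux_Q_SH
                   for sh in st.side_holes)
        # positive Q_SH leaves the lumen
        assert q_in - q_sh == pytest.approx(q_out, rel=2e-2)

    def test_end_holes_active_opposite_signs(self, short_stented_flow):
        dom = short_stented_flow.mesh.domain
        st = dom.stent
        r1 = post.sh_flux(short_stented_flow, st.side_holes[0])
        r2 = post.sh_flux(short_stented_flow, st.side_holes[1])
        assert r1.flux_Q_SH < 0  # into the lumen near the inlet
        assert r2.flux_Q_SH > 0  # out of the lumen near the outlet

    def test_sample_line_in_solid_raises(self, short_stented_flow):
        with pytest.raises(ValueError, match="outside the fluid"):
            post.sample_line(short_stented_flow, (20.0, 25.0), -0.25, 50)

    def test_divergence_shrinks_under_refinement(self, short_stented, fluid,
                                                 bc, short_stented_flow):
        """Taylor-Hood enforces incompressibility only weakly; the
        element-integrated |div u| must vanish under refinement."""
        coarse = solve_steady_flow(
            geo.generate_mesh(short_stented, h_global=1.6, h_sh=0.2),
            fluid, bc)
        assert short_stented_flow.divergence_l1() < coarse.divergence_l1()


class TestConvergenceStudy:
    def test_monotone_refinement(self, short_stented, fluid, bc):
        rep = convergence_study(short_stented, fluid, bc,
                                [(2.0, 0.4), (1.4, 0.2), (1.0, 0.1)])
        assert rep.n_elements == sorted(rep.n_elements)
        assert np.isfinite(rep.uncertainty)
        # fine-pair changes no larger than coarse-pair changes for the flux
        ch = rep.rel_changes["sh1_flux"]
        assert ch[-1] <= ch[0] * 1.5  # Richardson-like decay, some slack

    def test_repeated_level_zero_change(self, short_channel, fluid, bc):
        rep = convergence_study(short_channel, fluid, bc,
                                [(2.0, 0.5), (2.0, 0.5)])
        assert rep.rel_changes["centerline_u"][-1] == pytest.approx(0.0, abs=1e-12)

    def test_needs_two_levels(self, short_channel, fluid, bc):
        with pytest.raises(ValueError):
            convergence_study(short_channel, fluid, bc, [(2.0, 0.5)])
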