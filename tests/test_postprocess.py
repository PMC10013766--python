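"""Post-processing operations against closed-form fixtures.

Every operation is exercised on analytic fields whose fluxes and shear
rates are known exactly, independent of the finite-element solver.
"""

import numpy as np
import pytest

from stentflow import postprocess as post
from stentflow import synthetic
from stentflow.geometry import SideHole
from stentflow.solver import FluidProps


@pytest.fixture
def plane_field():
    return synthetic.plane_poiseuille_field(2.64, 4.0)


class TestSampleLine:
    def test_plane_poiseuille_midline(self, plane_field):
        prof = post.sample_line(plane_field, (0.0, 10.0), 0.0, 51, Uc=2.64)
        assert prof.u == pytest.approx(np.full(51, 2.64))
        assert np.all(prof.v == 0)

    def test_normalization(self, plane_field):
        prof = post.sample_line(plane_field, (0.0, 1.0), 1.0, 11, Uc=2.64)
        assert prof.u_tilde == pytest.approx(prof.u / 2.64)


class TestShFlux:
    def test_exact_bump_integral(self):
        """Recovers the closed-form crossflow integral to quadrature accuracy."""
        sh = SideHole(index=1, x_center=12.8, diameter_DSH=1.0)
        f = synthetic.crossflow_patch(0.5, 1.6, 12.8)
        res = post.sh_flux(f, sh, q0=7.05, n=1001)
        assert res.flux_Q_SH == pytest.approx(0.5, abs=1e-8)
        assert res.q_tilde == pytest.approx(0.5 / post.UC_NORMALIZATION, abs=1e-8)
        assert res.active

    def test_zero_crossflow_inactive(self, plane_field):
        sh = SideHole(index=3, x_center=82.8, diameter_DSH=1.0)
        res = post.sh_flux(plane_field, sh, q0=7.05)
        assert res.flux_Q_SH == 0.0
        assert not res.active

    def test_sign_convention(self):
        """Downward (into-lumen) crossflow gives a negative flux."""
        sh = SideHole(index=1, x_center=0.0, diameter_DSH=1.0)
        f = synthetic.crossflow_patch(-0.25, 1.0, 0.0)
        res = post.sh_flux(f, sh, q0=7.05)
        assert res.flux_Q_SH == pytest.approx(-0.25, abs=1e-8)

    def test_resolution_floor(self, plane_field):
        sh = SideHole(index=1, x_center=0.0, diameter_DSH=1.0)
        with pytest.raises(ValueError):
            post.sh_flux(plane_field, sh, n=50)

    def test_activation_threshold_fraction(self):
        sh = SideHole(index=2, x_center=0.0, diameter_DSH=0.5)
        f = synthetic.crossflow_patch(0.01, 1.0, 0.0)  # 0.14% of Q0
        res = post.sh_flux(f, sh, q0=7.05)
        assert not res.active
        res2 = post.sh_flux(f, sh, q0=7.05, activation_fraction=0.001)
        assert res2.active


class TestLuminalFlux:
    def test_parabola_strip_closed_form(self, plane_field):
        """Integral of the parabola over the default 1 mm lumen strip."""
        from stentflow.geometry import default_case

        _, stent = default_case(1.0, 1.0)
        q = post.luminal_flux(plane_field, stent, x=5.0)
        # int_{-1.5}^{-0.5} Uc (1 - (r/2)^2) dr = Uc * (1 - 13/48) * 1
        exact = 2.64 * (1 - 13 / 48)
        assert q == pytest.approx(exact, rel=1e-6)


class TestTotalTransverseFlux:
    def test_zero(self):
        rs = [post.SHFluxResult(i, 0.0, 0.0, False) for i in range(1, 9)]
        assert post.total_transverse_flux(rs) == 0.0

    def test_magnitude_sum(self):
        rs = [post.SHFluxResult(1, -1.0, -0.38, True),
              post.SHFluxResult(8, 1.0, 0.38, True)]
        assert post.total_transverse_flux(rs) == pytest.approx(2.0)


class TestShWallShear:
    def test_linear_field_exact(self):
        """V = V0 (x - xw)/a gives tau = mu V0 / a uniformly on the wall."""
        sh = SideHole(index=1, x_center=10.0, diameter_DSH=1.0)
        xw = sh.x_min
        V0, a = 0.8, 0.25
        f = synthetic.ReferenceField(
            kind="linear_shear",
            u_fn=lambda x, r: np.zeros_like(x),
            v_fn=lambda x, r: V0 * (x - xw) / a,
            exact={},
        )
        fluid = FluidProps()
        st = post.sh_wall_shear(f, sh, fluid, n_samples=10)
        mu = fluid.dynamic_viscosity_mu
        # left wall exact; right wall sees the same |slope|
        assert st.samples == pytest.approx(np.full(20, mu * V0 / a), rel=1e-9)
        assert st.median == pytest.approx(mu * V0 / a, rel=1e-9)

    def test_quadratic_field_exact(self):
        """The one-sided 3-point stencil differentiates quadratics exactly."""
        sh = SideHole(index=2, x_center=0.0, diameter_DSH=0.8)
        xw = sh.x_min
        f = synthetic.ReferenceField(
            kind="quadratic",
            u_fn=lambda x, r: np.zeros_like(x),
            v_fn=lambda x, r: 3.0 * (x - xw) ** 2 + 2.0 * (x - xw) + 0.0 * r,
            exact={},
        )
        st = post.sh_wall_shear(f, sh, 1.0, n_samples=5)  # mu = 1
        left = st.samples[:5]
        assert left == pytest.approx(np.full(5, 2.0), rel=1e-9)

    def test_quartiles_ordered(self):
        sh = SideHole(index=1, x_center=0.0, diameter_DSH=1.0)
        f = synthetic.crossflow_patch(0.5, 1.0, 0.0)
        st = post.sh_wall_shear(f, sh, FluidProps())
        assert st.q1 <= st.median <= st.q3

    def test_stencil_guard(self):
        sh = SideHole(index=1, x_center=0.0, diameter_DSH=1.0)
        f = synthetic.crossflow_patch(0.5, 1.0, 0.0)
        with pytest.raises(ValueError):
            post.sh_wall_shear(f, sh, FluidProps(), delta=0.6)


class TestRankSum:
    def test_identical_samples(self):
        a = np.ones(30)
        assert post.rank_sum_compare(a, a) == pytest.approx(1.0)

    def test_disjoint_support(self):
        a = np.linspace(0.0, 1.0, 20)
        b = np.linspace(10.0, 11.0, 20)
        assert post.rank_sum_compare(a, b) < 1e-3

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            post.rank_sum_compare([], [1.0])


class TestPoiseuilleError:
    def _profiles(self):
        r = np.linspace(-2, 2, 101)
        ref = synthetic.pipe_poiseuille_profile(2.64, 4.0, r)
        return r, ref

    def test_identical_is_zero(self):
        _, ref = self._profiles()
        err = post.poiseuille_error(ref, ref)
        assert err.eps_u == 0.0 and err.eps_v == 0.0

    def test_constant_transverse_error(self):
        r, ref = self._profiles()
        prof = post.Profile(coords=r, u=ref.u.copy(),
                            v=np.full_like(ref.u, 0.01 * 2.64), Uc=2.64)
        err = post.poiseuille_error(prof, ref)
        assert err.eps_v == pytest.approx(0.01, rel=1e-12)

    def test_uniform_shift_scales(self):
        """A uniform 1% shift of U~ gives eps_u of exactly 1%."""
        r, ref = self._profiles()
        prof = post.Profile(coords=r, u=ref.u + 0.01 * 2.64,
                            v=np.zeros_like(ref.u), Uc=2.64)
        err = post.poiseuille_error(prof, ref)
        assert err.eps_u == pytest.approx(0.01, rel=1e-12)

    def test_mismatched_grids_raise(self):
        r, ref = self._profiles()
        other = synthetic.pipe_poiseuille_profile(2.64, 4.0, r[:-1])
        with pytest.raises(ValueError):
            post.poiseuille_error(other, ref)


class TestAggregate:
    def test_one_case_eight_rows(self):
        from stentflow.geometry import default_case

        _, stent = default_case(1.0, 1.0)
        fluxes = [post.SHFluxResult(h.index, 0.1 * h.index, 0.03, True)
                  for h in stent.side_holes]
        shears = [post.ShearStats.from_samples(h.index, np.array([1.0, 2.0, 3.0]))
                  for h in stent.side_holes]
        df = post.aggregate_flux_shear([(stent, fluxes, shears)])
        assert len(df) == 8
        assert set(df.columns) >= {"Ds", "DSH", "sh_index", "Q_SH",
                                   "tau_median", "active"}

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            post.aggregate_flux_shear([])
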