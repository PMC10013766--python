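"""Analytic 0D hydraulics: closed forms, limits and consistency identities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import simpson

from stentflow import lumped
from stentflow.synthetic import annular_poiseuille_profile


class TestAnnularFlowRate:
    def test_pipe_limit(self):
        """Do = 0 recovers Hagen-Poiseuille."""
        D, dpdx, mu = 0.004, -10.0, 1e-3
        q = lumped.annular_flow_rate(D, 0.0, dpdx, mu)
        assert q == pytest.approx(math.pi * D**4 * (-dpdx) / (128 * mu))

    @pytest.mark.parametrize("Do_mm, expected", [(1.0, 92.697), (3.0, 4.673)])
    def test_bracket_values(self, Do_mm, expected):
        # D^4 - Do^4 - (D^2-Do^2)^2/ln(D/Do) for D = 4 mm, in mm^4
        assert lumped.annular_bracket(4.0, Do_mm) == pytest.approx(expected, abs=5e-4)

    def test_flow_drop_over_90_percent(self):
        """Do 1 -> 3 mm at constant gradient cuts the flow by >= 90%."""
        q1 = lumped.annular_flow_rate(0.004, 0.001, -10.0, 1e-3)
        q3 = lumped.annular_flow_rate(0.004, 0.003, -10.0, 1e-3)
        assert 1 - q3 / q1 >= 0.90

    def test_matches_profile_quadrature(self):
        """Closed form equals 2 pi int u r dr of the analytic profile."""
        D, Do, dpdx, mu = 0.004, 0.001, -25.0, 1.005e-3
        r = np.linspace(Do / 2, D / 2, 2001)
        prof = annular_poiseuille_profile(dpdx, mu, D, Do, r)
        q_quad = 2 * math.pi * simpson(prof.u * r, x=r)
        q = lumped.annular_flow_rate(D, Do, dpdx, mu)
        assert q_quad == pytest.approx(q, rel=1e-8)

    def test_invalid_geometry(self):
        with pytest.raises(ValueError):
            lumped.annular_flow_rate(0.004, 0.004, -1.0, 1e-3)


class TestFrictionZeta:
    @pytest.mark.parametrize("Do, expected", [(1.0, 1.4564), (3.0, 1.4980)])
    def test_values(self, Do, expected):
        assert lumped.friction_zeta(4.0, Do) == pytest.approx(expected, abs=5e-4)

    def test_pipe_limit(self):
        """zeta -> 1 as Do -> 0; the approach is logarithmically slow."""
        assert lumped.friction_zeta(4.0, 0.0) == 1.0
        vals = [lumped.friction_zeta(4.0, d) for d in (1e-3, 1e-6, 1e-9)]
        assert vals == sorted(vals, reverse=True)
        assert vals[-1] == pytest.approx(1.0, abs=0.05)

    def test_plane_channel_limit(self):
        # f Re -> 96 as the annulus becomes a thin gap
        assert lumped.friction_zeta(4.0, 4.0 - 1e-3) == pytest.approx(1.5, abs=1e-4)

    def test_degenerate_raises(self):
        with pytest.raises(ValueError):
            lumped.friction_zeta(4.0, 4.0)

    @given(st.floats(0.01, 0.99))
    @settings(max_examples=50, deadline=None)
    def test_bounds(self, ratio):
        """zeta lies in (1, 1.5) for any annulus."""
        z = lumped.friction_zeta(1.0, ratio)
        assert 1.0 < z < 1.5


class TestFrictionFactor:
    def test_unit_case(self):
        assert lumped.friction_factor(1.0, 64.0) == 1.0

    def test_halves_with_doubled_re(self):
        assert lumped.friction_factor(1.2, 100.0) == 2 * lumped.friction_factor(1.2, 200.0)

    def test_do_sweep_triples_f(self):
        """Do 1 -> 3 mm at constant mean velocity: f up by ~209%."""
        f1 = lumped.friction_zeta(4.0, 1.0) / 3.0
        f3 = lumped.friction_zeta(4.0, 3.0) / 1.0
        assert f3 / f1 == pytest.approx(3.086, abs=0.01)


class TestPressureLoss:
    def _case(self, **kw):
        base = dict(D=0.004, Do=0.001, L=0.27, mu=1.005e-3, rho=1000.0,
                    mean_velocity=1e-3)
        base.update(kw)
        return lumped.LumpedCase(**base)

    @given(st.floats(0.05, 0.95))
    @settings(max_examples=50, deadline=None)
    def test_darcy_annulus_round_trip(self, ratio):
        """Eq. form of zeta makes the Darcy loss exactly the annular dp."""
        D, L, mu, rho = 0.004, 0.27, 1.005e-3, 1000.0
        Do = ratio * D
        dpdx = -37.0
        q = lumped.annular_flow_rate(D, Do, dpdx, mu)
        area = math.pi * (D**2 - Do**2) / 4
        case = self._case(Do=Do, mean_velocity=q / area)
        pl, p_visc, p_minor = lumped.pressure_loss(case)
        assert p_minor == 0.0
        assert p_visc == pytest.approx(-dpdx * L, rel=1e-12)

    def test_minor_losses_increase_loss(self):
        base, _, _ = lumped.pressure_loss(self._case())
        with_k, _, pm = lumped.pressure_loss(self._case(K=(0.4, 0.88)))
        assert with_k > base and pm > 0

    def test_zero_velocity(self):
        pl, *_ = lumped.pressure_loss(self._case(mean_velocity=0.0))
        assert pl == 0.0


class TestLossCoefficients:
    def test_no_contraction(self):
        kc, ke = lumped.loss_coefficients(4.0, 4.0)
        assert kc == 0.0 and ke == 0.0

    def test_expansion_value(self):
        _, ke = lumped.loss_coefficients(1.0, 4.0)
        assert ke == pytest.approx((15 / 16) ** 2, rel=1e-12)

    @given(st.floats(0.1, 0.9), st.floats(0.11, 0.99))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_ds(self, a, b):
        if a == b:
            return
        lo, hi = sorted((a, b))
        kc_lo, ke_lo = lumped.loss_coefficients(lo, 1.0)
        kc_hi, ke_hi = lumped.loss_coefficients(hi, 1.0)
        assert kc_hi < kc_lo and ke_hi < ke_lo


class TestStentSizeSweep:
    def test_reference_point(self):
        df = lumped.stent_size_sweep(4.0, [1.0, 2.0, 3.0])
        assert df.Q_ratio.iloc[0] == 1.0 and df.f_ratio.iloc[0] == 1.0

    def test_do_1_to_3(self):
        df = lumped.stent_size_sweep(4.0, [1.0, 3.0])
        assert df.Q_ratio.iloc[1] == pytest.approx(4.673 / 92.697, abs=2e-4)
        assert df.f_ratio.iloc[1] == pytest.approx(3.086, abs=0.01)

    def test_monotone(self):
        df = lumped.stent_size_sweep(4.0, np.linspace(0.2, 3.8, 30))
        assert np.all(np.diff(df.Q_ratio) < 0)
        assert np.all(np.diff(df.f_ratio) > 0)

    def test_bad_grid(self):
        with pytest.raises(ValueError):
            lumped.stent_size_sweep(4.0, [1.0, 5.0])


class TestPigtailScale:
    def test_values(self):
        assert lumped.pigtail_loss_scale(0.0, 1.0)[0] == 0.0
        scale, flag = lumped.pigtail_loss_scale(14.7, 1.0)
        assert scale == pytest.approx(14.7)
        assert "protrusion" in flag


class TestDesignNumbers:
    def test_physiological_reynolds(self):
        dn = lumped.design_numbers(Uc=2.65e-3, D=4e-3, nu=1.005e-6,
                                   dp=20e-6, rho_p=1180.0, mu=1.005e-3)
        assert dn.reynolds == pytest.approx(10.55, rel=0.01)

    def test_particle_response_and_stokes(self):
        mu_exp = 1150.0 * 9.98e-6  # glycerol-water working fluid
        dn = lumped.design_numbers(Uc=26.6e-3, D=4e-3, nu=9.98e-6,
                                   dp=20e-6, rho_p=1180.0, mu=mu_exp)
        assert dn.particle_response_time == pytest.approx(2.28e-6, rel=0.01)
        assert dn.stokes == pytest.approx(1.52e-5, rel=0.01)

    def test_uc_from_flow_rate(self):
        # 1 ml/min through a 4 mm pipe gives ~2.65 mm/s centerline
        dn = lumped.design_numbers(Uc=0.0, D=4e-3, nu=1.005e-6, dp=20e-6,
                                   rho_p=1180.0, mu=1.005e-3, Q=1e-6 / 60)
        assert dn.centerline_velocity == pytest.approx(2.653e-3, rel=1e-3)


class TestMatchExperimentFlow:
    def test_bench_fluid(self):
        """Re matching with the glycerol-water fluid needs ~10 ml/min."""
        q = lumped.match_experiment_flow(10.55, 4e-3, 9.98e-6)
        assert q == pytest.approx(9.92, rel=0.005)

    def test_physiological_fluid(self):
        q = lumped.match_experiment_flow(10.55, 4e-3, 1.005e-6)
        assert q == pytest.approx(1.0, rel=0.01)

    def test_linear_in_nu(self):
        q1 = lumped.match_experiment_flow(10.55, 4e-3, 2e-6)
        q2 = lumped.match_experiment_flow(10.55, 4e-3, 4e-6)
        assert q2 == pytest.approx(2 * q1, rel=1e-12)
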