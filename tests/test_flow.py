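"""1D glottal flow: Bernoulli limit, losses, separation, conservation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import vfsim as vf
from vfsim.flow import (MU_EFF_DEFAULT, POISEUILLE_SLOT_COEFF,
                        continuity_residual, find_separation)

from conftest import profile_from_area, run_to_steady, uniform_profile


class TestEffectiveArea:
    def test_factor_one_is_identity(self):
        a = np.array([3.0, 2.0, 1.0, 2.0])
        assert np.array_equal(vf.effective_area(a, 1.0), a)

    def test_contraction_scaled_downstream_untouched(self):
        a = np.array([3.0, 2.0, 1.0, 2.0, 3.0])
        out = vf.effective_area(a, 0.8)
        assert np.allclose(out[:3], 0.8 * a[:3])
        assert np.array_equal(out[3:], a[3:])
        assert vf.effective_area(np.array([1e-6]), 0.8)[0] \
            == pytest.approx(8e-7)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.floats(0.05, 1.0))
    def test_downstream_invariant_for_any_factor(self, factor):
        a = np.array([3.0, 1.0, 2.0, 4.0])
        out = vf.effective_area(a, factor)
        assert np.array_equal(out[2:], a[2:])

    def test_invalid_inputs_rejected(self):
        with pytest.raises(vf.VfsimError):
            vf.effective_area(np.array([1.0, -1.0]), 1.0)
        with pytest.raises(vf.VfsimError):
            vf.effective_area(np.array([1.0]), 1.5)


class TestReynolds:
    def test_zero_velocity(self):
        assert vf.reynolds_number(0.0, 1e-3) == 0.0

    def test_arithmetic(self):
        re = vf.reynolds_number(30.0, 1e-3, rho=1.0, mu_eff=7.2e-5)
        assert re == pytest.approx(416.67, rel=1e-3)

    def test_quadrupled_viscosity_quarters_reynolds(self):
        re1 = vf.reynolds_number(10.0, 1e-3, mu_eff=1.8e-5)
        re4 = vf.reynolds_number(10.0, 1e-3, mu_eff=4 * 1.8e-5)
        assert re1 / re4 == pytest.approx(4.0)


class TestSteadyBernoulli:
    def test_constant_area_is_quiescent(self):
        u, p = vf.steady_bernoulli(np.full(10, 1e-5), 500.0)
        assert np.allclose(u, 0.0) and np.allclose(p, 500.0)

    def test_driving_pressure_sets_peak_velocity(self):
        # large inlet, dP = 720 Pa, rho = 1 -> u = sqrt(2*720) at the throat
        a = np.linspace(1e-3, 2e-6, 50)
        u, p = vf.steady_bernoulli(a, 720.0, rho=1.0)
        assert u[-1] == pytest.approx(np.sqrt(2 * 720.0), rel=1e-3)
        assert p[0] == pytest.approx(720.0, rel=1e-3)

    def test_continuity_at_fixed_flux(self):
        a = np.array([1e-3, 8e-6, 4e-6])
        u, _ = vf.steady_bernoulli(a, 300.0)
        assert u[2] == pytest.approx(2 * u[1], rel=1e-12)


class TestStepFlow:
    def test_transient_converges_to_bernoulli(self):
        x = np.linspace(0, 0.02, 200)
        area = 1e-5 - (1e-5 - 2e-6) * (x / 0.02)
        prof = profile_from_area(x, area)
        state = run_to_steady(prof, 720.0, vf.no_loss_model(), n_steps=3000)
        u_b, p_b = vf.steady_bernoulli(area, 720.0)
        assert np.max(np.abs(state.p - p_b)) / 720.0 < 0.005
        # total pressure constant along the attached duct
        assert np.ptp(state.p_total) / 720.0 < 0.005

    def test_conservative_continuity_residual(self):
        prof = uniform_profile(n=60, area=1e-5)
        a0 = prof.area.copy()
        state = vf.init_flow_state(prof, P_in=200.0)
        dt, omega = 1e-6, 2 * np.pi * 200
        loss = vf.default_loss_model()
        for k in range(1, 200):
            a_new = a0 * (1 + 0.1 * np.sin(omega * k * dt)
                          * np.sin(np.pi * prof.x / prof.x[-1]))
            prev = state.copy()
            prof2 = profile_from_area(prof.x, a_new)
            prof2.area_dot = (a_new - prev.area) / dt
            state = vf.step_flow(state, prof2, loss, dt)
            assert continuity_residual(prev, state, dt) < 1e-10

    def test_impulsive_start_monotone_no_overshoot(self):
        x = np.linspace(0, 0.02, 120)
        area = 1e-5 - (1e-5 - 2e-6) * (x / 0.02)
        prof = profile_from_area(x, area)
        state = vf.init_flow_state(prof, P_in=500.0)
        loss = vf.default_loss_model()
        qs = []
        for _ in range(4000):
            state = vf.step_flow(state, prof, loss, dt=1e-6)
            qs.append(state.Q)
        qs = np.array(qs)
        assert np.all(np.diff(qs) > -1e-12 * qs.max())
        assert qs.max() <= 1.05 * qs[-1]

    def test_cfl_violation_suggests_dt(self):
        x = np.linspace(0, 0.02, 200)
        area = 1e-5 - (1e-5 - 2e-6) * (x / 0.02)
        prof = profile_from_area(x, area)
        state = run_to_steady(prof, 720.0, vf.no_loss_model(), n_steps=500)
        with pytest.raises(vf.CFLError, match="reduce dt"):
            vf.step_flow(state, prof, vf.no_loss_model(), dt=5e-4)

    def test_negative_area_rejected(self):
        prof = uniform_profile()
        state = vf.init_flow_state(prof)
        bad = profile_from_area(prof.x, prof.area.copy())
        bad.area[3] = -1e-7
        with pytest.raises(vf.VfsimError):
            vf.step_flow(state, bad, None, 1e-6)


class TestDefaultLossModel:
    def test_no_flow_no_loss(self):
        prof = uniform_profile()
        state = vf.init_flow_state(prof, P_in=0.0)
        state = vf.step_flow(state, prof, vf.default_loss_model(), 1e-6)
        assert np.allclose(state.tau, 0.0) and np.allclose(state.u, 0.0)

    def test_plane_poiseuille_closed_form(self):
        """Steady pressure drop along a uniform narrow slot matches the
        plane-Poiseuille law within 2%."""
        span, half_gap, L = 6e-3, 2e-4, 1e-2
        prof = uniform_profile(n=100, area=2 * half_gap * span,
                               length=L, span=span)
        state = run_to_steady(prof, 30.0, vf.default_loss_model(),
                              n_steps=20000)
        u = state.u[-1]
        dp_pois = 12 * state.mu_eff * u * L / (2 * half_gap) ** 2
        dp_meas = state.p[0] - state.p[-1]
        assert dp_meas == pytest.approx(dp_pois, rel=0.02)

    def test_separation_clamps_pressure_no_recovery(self):
        x = np.linspace(0, 0.01, 120)
        area = np.where(x < 0.005,
                        1e-5 - (1e-5 - 2e-6) * (x / 0.005),
                        2e-6 + (x - 0.005) * 4e-3)
        prof = profile_from_area(x, area)
        i_sep = find_separation(prof, 10.0)
        assert i_sep > np.argmin(area)
        state = run_to_steady(prof, 720.0, vf.default_loss_model(),
                              n_steps=3000)
        assert np.allclose(state.p[i_sep:], 0.0, atol=1e-9)
        pt = state.p_total
        i_min = np.argmin(area)
        assert np.all(np.diff(pt[i_min:]) <= 1e-9 * 720.0)

    def test_loss_model_never_raises_total_pressure(self):
        x = np.linspace(0, 0.01, 120)
        area = np.where(x < 0.005,
                        1e-5 - (1e-5 - 2e-6) * (x / 0.005),
                        2e-6 + (x - 0.005) * 4e-3)
        prof = profile_from_area(x, area)
        lossy = run_to_steady(prof, 720.0, vf.default_loss_model(), n_steps=3000)
        ideal = run_to_steady(prof, 720.0, vf.no_loss_model(), n_steps=3000)
        assert np.all(lossy.p_total <= ideal.p_total + 1e-6 * 720.0)

    def test_closed_glottis_kills_downstream_total_pressure(self):
        """With the gap at the area floor the flux shuts off and the
        downstream total pressure collapses to a few percent of P_in."""
        P_in = 720.0
        floor = 0.01 * 2.4e-6
        x = np.linspace(0, 0.01, 120)
        area = np.where(x < 0.005,
                        1e-5 - (1e-5 - floor) * (x / 0.005),
                        floor + (x - 0.005) * 4e-3)
        prof = profile_from_area(x, area)
        state = run_to_steady(prof, P_in, vf.default_loss_model(),
                              n_steps=3000)
        i_min = np.argmin(area)
        assert np.all(state.p_total[i_min + 1:] < 0.05 * P_in)
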