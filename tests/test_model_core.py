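"""Parameter transforms, vector fields and the trajectory simulator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lvtumor as lv
from lvtumor import (
    DimensionlessParams,
    KineticParams,
    TherapySpec,
    from_dimensionless,
    rhs_dimensionless,
    rhs_original,
    simulate,
    simulate_dimensionless,
    state_from_dimensionless,
    state_to_dimensionless,
    to_dimensionless,
)


class TestDimensionlessTransform:
    def test_reference_sets_reproduce_reported_triples(self, fx):
        dp1 = fx["regime1"]["dimensionless"]
        assert dp1.c == pytest.approx(0.1237 / 0.075, rel=1e-14)
        assert round(dp1.c, 2) == 1.65
        assert dp1.d == pytest.approx(0.75, rel=1e-14)
        assert dp1.f == pytest.approx(0.45, rel=1e-14)
        dp2 = fx["regime2"]["dimensionless"]
        assert (dp2.c, dp2.d, dp2.f) == pytest.approx((1.0, 0.9, 0.788), rel=1e-14)

    def test_symmetric_species_give_unit_triple(self):
        p = KineticParams(rx=0.2, ry=0.2, Kx=1.0, Ky=1.0, alpha_xy=0.2, alpha_yx=0.2)
        dp = to_dimensionless(p)
        assert (dp.c, dp.d, dp.f) == pytest.approx((1.0, 1.0, 1.0))

    def test_zero_growth_rate_rejected(self):
        p = KineticParams(rx=0.0, ry=0.1, Kx=1.0, Ky=1.0, alpha_xy=0.1, alpha_yx=0.1)
        with pytest.raises(ValueError):
            to_dimensionless(p)

    @given(
        c=st.floats(0.1, 5.0),
        d=st.floats(0.1, 3.0),
        f=st.floats(0.1, 3.0),
        rx=st.floats(0.01, 10.0),
        Kx=st.floats(0.1, 10.0),
        Ky=st.floats(0.1, 10.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_round_trip_with_scale_info(self, c, d, f, rx, Kx, Ky):
        dp = DimensionlessParams(c=c, d=d, f=f)
        back = to_dimensionless(from_dimensionless(dp, rx=rx, Kx=Kx, Ky=Ky))
        assert back.c == pytest.approx(c, rel=1e-12)
        assert back.d == pytest.approx(d, rel=1e-12)
        assert back.f == pytest.approx(f, rel=1e-12)

    def test_strict_validation_enforces_interaction_bound(self):
        p = KineticParams(rx=0.1, ry=0.1, Kx=1.0, Ky=1.0, alpha_xy=0.05, alpha_yx=0.1)
        with pytest.raises(ValueError, match="alpha_xy"):
            p.validate_strict()
        p2 = KineticParams(rx=0.1, ry=0.1, Kx=1.0, Ky=1.0, alpha_xy=0.1, alpha_yx=0.1)
        p2.validate_strict()  # bound met exactly


class TestStateTransform:
    def test_scaling_identity(self, fx):
        p = fx["regime2"]["kinetics"]
        tau, u, v = state_to_dimensionless(p.Kx, p.rx * p.Ky / p.ry, p, t=0.0)
        assert (tau, u, v) == pytest.approx((0.0, 1.0, 1.0))
        assert state_to_dimensionless(0.0, 0.0, p)[1:] == pytest.approx((0.0, 0.0))

    def test_round_trip_machine_precision(self, fx):
        p = fx["regime1"]["kinetics"]
        t, x, y = 3.7, 0.42, 0.77
        tau, u, v = state_to_dimensionless(x, y, p, t)
        t2, x2, y2 = state_from_dimensionless(u, v, p, tau)
        assert (t2, x2, y2) == pytest.approx((t, x, y), rel=1e-14)

    def test_coexistence_point_maps_to_nullcline_solution(self, fx):
        # The original-coordinate interior equilibrium must land on the
        # solution of u + c*v = 1, f*u + v = d.
        p = fx["regime2"]["kinetics"]
        dp = to_dimensionless(p)
        u4 = (1 - dp.c * dp.d) / (1 - dp.c * dp.f)
        v4 = (dp.d - dp.f) / (1 - dp.c * dp.f)
        _, x4, y4 = state_from_dimensionless(u4, v4, p)
        deriv = rhs_original(0.0, (x4, y4), p)
        assert deriv == pytest.approx((0.0, 0.0), abs=1e-15)


class TestVectorFields:
    def test_dimensionless_equilibria_are_zeros(self):
        dp = DimensionlessParams(c=1.0, d=0.9, f=0.788)
        assert rhs_dimensionless(0.0, (0.0, 0.0), dp) == pytest.approx((0.0, 0.0))
        assert rhs_dimensionless(0.0, (1.0, 0.0), dp) == pytest.approx((0.0, 0.0))

    def test_dimensionless_direct_substitution(self):
        dp = DimensionlessParams(c=1.0, d=0.9, f=0.788)
        du, dv = rhs_dimensionless(0.0, (0.5, 0.5), dp)
        assert du == pytest.approx(0.5 - 0.25 - 0.25, abs=1e-15)
        assert dv == pytest.approx(0.45 - 0.25 - 0.788 * 0.25, abs=1e-15)

    def test_original_no_host_at_capacity(self, fx):
        p = fx["regime4"]["kinetics"]
        assert rhs_original(0.0, (p.Kx, 0.0), p) == pytest.approx((0.0, 0.0))

    def test_periodic_forcing_vanishes_at_t_zero(self, fx):
        p = fx["regime4_forced"]["kinetics"]
        therapy = TherapySpec(mode="periodic_additive", D=1.0, beta_y=-0.025,
                              omega=1.0 / 14.0)
        assert rhs_original(0.0, (0.5, 0.5), p, therapy) == pytest.approx(
            rhs_original(0.0, (0.5, 0.5), p)
        )

    def test_proportional_extinction_dose_forces_decay(self, fx):
        # At D = rx/beta_x the rescaled tumor growth rate vanishes and
        # dx/dt = -rx x^2 / Kx < 0 when no host is present.
        p = fx["regime4"]["kinetics"]
        beta_x = 0.05
        therapy = TherapySpec(mode="proportional_constant", D=p.rx / beta_x,
                              beta_x=beta_x, beta_y=0.0)
        for x in (0.1, 0.5, 2.0):
            dx, _ = rhs_original(0.0, (x, 0.0), p, therapy)
            assert dx == pytest.approx(-p.rx * x**2 / p.Kx)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="unknown therapy mode"):
            TherapySpec(mode="bolus", D=1.0)


class TestSimulate:
    def test_regime1_converges_to_tumor_free_node(self, fx):
        dp = fx["regime1"]["dimensionless"]
        traj = simulate_dimensionless((0.8, 0.2), dp, (0.0, 400.0))
        assert traj.final_state == pytest.approx((0.0, dp.d), abs=1e-6)

    def test_regime2_converges_to_coexistence(self, fx):
        dp = fx["regime2"]["dimensionless"]
        u4 = (1 - dp.c * dp.d) / (1 - dp.c * dp.f)
        v4 = (dp.d - dp.f) / (1 - dp.c * dp.f)
        traj = simulate_dimensionless((0.5, 0.5), dp, (0.0, 400.0))
        assert traj.final_state == pytest.approx((u4, v4), abs=1e-4)

    def test_start_at_equilibrium_stays(self, fx):
        dp = fx["regime2"]["dimensionless"]
        traj = simulate_dimensionless((0.0, dp.d), dp, (0.0, 100.0))
        assert np.max(np.abs(traj.states - [0.0, dp.d])) < 1e-8

    def test_quadrant_invariance_random_starts(self, rng):
        # Random valid parameters and non-negative starts never leave
        # the positive quadrant beyond solver tolerance.
        worst = 0.0
        for _ in range(300):
            dp = DimensionlessParams(*rng.uniform([0.2, 0.3, 0.2], [2.5, 1.5, 2.0]))
            start = rng.uniform(0.0, 1.5, size=2)
            traj = simulate_dimensionless(start, dp, (0.0, 60.0),
                                          n_samples=40, rtol=1e-8, atol=1e-10)
            worst = min(worst, float(traj.states.min()))
        assert worst >= -1e-8

    def test_boundedness_inside_simplex(self, rng):
        # x + gamma*y <= K(1 + eps) along unperturbed orbits started
        # inside the capacity simplex.  The invariance requires the
        # interactions to contain the shared-capacity term (alpha >=
        # r/K with non-negative kill coefficients); on the line
        # x + gamma*y = K the load derivative is then
        # -(delta_xy + gamma*delta_yx)*x*y <= 0.
        p = KineticParams(rx=0.1, ry=0.075, Kx=1.0, Ky=1.0,
                          alpha_xy=0.15, alpha_yx=0.12,
                          delta_xy=0.05, delta_yx=0.045)
        p.validate_strict()
        for _ in range(20):
            x0 = rng.uniform(0.0, 1.0)
            y0 = rng.uniform(0.0, (p.Kx - x0) / p.gamma)
            traj = simulate((x0, y0), p, (0.0, 800.0), n_samples=200)
            load = traj.states[:, 0] + p.gamma * traj.states[:, 1]
            assert np.max(load) <= p.Kx * (1.0 + 1e-6)

    def test_proportional_mode_equals_rescaled_unperturbed(self, fx):
        # Dose-rescaled growth rates and capacities reproduce the
        # therapy simulation state-for-state.
        p = fx["regime4"]["kinetics"]
        D, bx, by = 0.4, 0.05, 0.01
        therapy = TherapySpec(mode="proportional_constant", D=D, beta_x=bx, beta_y=by)
        rx_eff, ry_eff = p.rx - D * bx, p.ry - D * by
        rescaled = KineticParams(
            rx=rx_eff, ry=ry_eff,
            Kx=p.Kx * rx_eff / p.rx, Ky=p.Ky * ry_eff / p.ry,
            alpha_xy=p.alpha_xy, alpha_yx=p.alpha_yx,
        )
        t_eval = np.linspace(0.0, 500.0, 100)
        a = simulate((0.5, 0.5), p, (0.0, 500.0), therapy=therapy, t_eval=t_eval)
        b = simulate((0.5, 0.5), rescaled, (0.0, 500.0), t_eval=t_eval)
        assert np.max(np.abs(a.states - b.states)) < 1e-6

    def test_degenerate_span_rejected(self, fx):
        with pytest.raises(ValueError):
            simulate((0.5, 0.5), fx["regime4"]["kinetics"], (1.0, 1.0))

    def test_trajectory_validates_lengths(self):
        with pytest.raises(ValueError):
            lv.Trajectory(np.array([0.0, 1.0]), np.zeros((3, 2)), "original")
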