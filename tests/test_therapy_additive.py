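"""Constant host-directed therapy: amplitudes, Q-points, bifurcations."""

import numpy as np
import pytest

import lvtumor as lv
from lvtumor import DimensionlessParams, KineticParams


@pytest.fixture(scope="module")
def dp_iv():
    # Regime IV with c*f > 1 (the aggressive-tumor benchmark triple).
    return DimensionlessParams(c=1.0, d=0.66, f=1.1)


def _random_params(rng):
    return KineticParams(
        rx=rng.uniform(0.05, 5.0),
        ry=rng.uniform(0.05, 5.0),
        Kx=rng.uniform(0.5, 5.0),
        Ky=rng.uniform(0.5, 5.0),
        alpha_xy=rng.uniform(0.01, 2.0),
        alpha_yx=rng.uniform(0.01, 2.0),
    )


class TestForcingAmplitude:
    def test_zero_dose(self, fx):
        assert lv.forcing_amplitude(0.0, -0.025, fx["regime4_forced"]["kinetics"]) == 0.0

    def test_benchmark_value(self, fx):
        p = fx["regime4_forced"]["kinetics"]
        assert lv.forcing_amplitude(1.0, -1 / 40, p) == pytest.approx(0.165, rel=1e-12)

    def test_linearity_in_dose(self, fx):
        p = fx["regime4_forced"]["kinetics"]
        assert lv.forcing_amplitude(2.0, -0.025, p) == pytest.approx(
            2 * lv.forcing_amplitude(1.0, -0.025, p)
        )

    def test_nonnegative_beta_rejected(self, fx):
        with pytest.raises(ValueError):
            lv.forcing_amplitude(1.0, 0.025, fx["regime4_forced"]["kinetics"])


class TestQEquilibria:
    def test_zero_amplitude_reduces_to_natural_points(self, dp_iv):
        reports = {r.label: r for r in lv.q_equilibria(dp_iv, 0.0)}
        assert reports["Q2"].location == pytest.approx((0.0, dp_iv.d))
        interior = sorted(
            [reports["Q3"].location, reports["Q4"].location], key=lambda p: p[1]
        )
        assert interior[0] == pytest.approx((1.0, 0.0))  # P3
        denom = 1 - dp_iv.c * dp_iv.f
        p4 = ((1 - dp_iv.c * dp_iv.d) / denom, (dp_iv.d - dp_iv.f) / denom)
        assert interior[1] == pytest.approx(p4)

    def test_discriminant_positive_pair_real(self, dp_iv):
        reports = [r.label for r in lv.q_equilibria(dp_iv, 0.1)]
        # Delta = 0.44^2 - 4*0.1*0.1 = 0.1536 > 0
        assert "Q3" in reports and "Q4" in reports

    def test_q1_below_axis_and_unstable(self, rng, dp_iv):
        for A in rng.uniform(0.01, 1.0, size=25):
            q1 = next(r for r in lv.q_equilibria(dp_iv, float(A)) if r.label == "Q1")
            assert q1.location[1] < 0
            assert not q1.physical
            assert max(e.real for e in q1.eigenvalues) > 0  # always unstable

    def test_q2_stabilizes_above_a1(self, dp_iv):
        amps = lv.bifurcation_amplitudes(dp_iv)
        for A, stable in ((amps.A1 * 0.9, False), (amps.A1 * 1.1, True)):
            q2 = next(r for r in lv.q_equilibria(dp_iv, A) if r.label == "Q2")
            assert (max(e.real for e in q2.eigenvalues) < 0) is stable

    def test_fixed_points_annihilate_field(self, rng, dp_iv):
        from lvtumor.dynamics import rhs_dimensionless

        for A in (0.05, 0.3, 0.484):
            for r in lv.q_equilibria(dp_iv, A):
                du, dv = rhs_dimensionless(0.0, r.location, dp_iv, forcing=A)
                assert abs(du) < 1e-10 and abs(dv) < 1e-10


class TestBifurcationAmplitudes:
    def test_benchmark_values(self, dp_iv):
        amps = lv.bifurcation_amplitudes(dp_iv)
        assert amps.A1 == pytest.approx(0.34, rel=1e-12)
        assert amps.A2 == pytest.approx(0.484, rel=1e-12)
        assert amps.A2_is_bifurcation

    def test_a1_vanishes_on_cd_boundary(self):
        dp = DimensionlessParams(c=1.25, d=0.8, f=1.0)
        assert lv.bifurcation_amplitudes(dp).A1 == 0.0

    def test_collision_at_a2(self, dp_iv):
        """Q3 and Q4 merge at A2 with a zero eigenvalue (saddle-node)."""
        amps = lv.bifurcation_amplitudes(dp_iv)
        merged = [r for r in lv.q_equilibria(dp_iv, amps.A2) if "Q3" in r.label]
        assert len(merged) == 1 and merged[0].label == "Q3=Q4"
        assert min(abs(e) for e in merged[0].eigenvalues) < 1e-6

    def test_pair_distance_shrinks_toward_a2(self, dp_iv):
        """The Q3-Q4 gap closes like sqrt(A2 - A), the saddle-node
        signature."""
        amps = lv.bifurcation_amplitudes(dp_iv)
        fracs = (0.9, 0.99, 0.999, 0.9999)
        gaps = []
        for frac in fracs:
            reps = {r.label: r for r in lv.q_equilibria(dp_iv, frac * amps.A2)}
            gaps.append(
                np.linalg.norm(
                    np.array(reps["Q3"].location) - np.array(reps["Q4"].location)
                )
            )
        assert np.all(np.diff(gaps) < 0)
        # Successive gap ratios follow sqrt(1 - frac) scaling.
        for g_next, g_prev in zip(gaps[1:], gaps[:-1]):
            assert g_next / g_prev == pytest.approx(np.sqrt(0.1), rel=0.05)


class TestDoseThresholds:
    def test_duality_with_amplitudes(self, rng):
        """forcing_amplitude(Di) == Ai to 1e-12 relative, 200 draws."""
        count = 0
        while count < 200:
            p = _random_params(rng)
            beta_y = -rng.uniform(0.005, 1.0)
            dp = lv.to_dimensionless(p)
            if abs(dp.c * dp.f - 1.0) < 1e-6:
                continue
            amps = lv.bifurcation_amplitudes(dp)
            D1, D2 = lv.dose_thresholds_additive(p, beta_y)
            a1 = lv.forcing_amplitude(abs(D1), beta_y, p) * np.sign(D1)
            a2 = lv.forcing_amplitude(abs(D2), beta_y, p) * np.sign(D2)
            assert a1 == pytest.approx(amps.A1, rel=1e-12, abs=1e-15)
            assert a2 == pytest.approx(amps.A2, rel=1e-12, abs=1e-15)
            count += 1


class TestPlanner:
    def test_decision_list_cf_above_one(self, dp_iv):
        # A1 = 0.34, A2 = 0.484, c(f-d) = 0.44 > 2(cf-1) = 0.2.
        assert lv.plan_outcome_additive(dp_iv, 0.5) == "I*"
        assert lv.plan_outcome_additive(dp_iv, 0.4) == "I*"
        assert lv.plan_outcome_additive(dp_iv, 0.2) == "II*"
        assert lv.plan_outcome_additive(dp_iv, 0.0) == "IV"

    def test_decision_list_interior_pair_survives(self):
        # c(f-d) < 2(cf-1): between A1 and A2 the system goes to III*.
        dp = DimensionlessParams(c=1.0, d=0.9, f=1.6)
        amps = lv.bifurcation_amplitudes(dp)
        assert amps.A1 < 0.15 < amps.A2
        assert lv.plan_outcome_additive(dp, 0.15) == "III*"

    def test_decision_list_other_baselines(self, fx):
        dp2 = fx["regime2"]["dimensionless"]
        a1 = lv.bifurcation_amplitudes(dp2).A1
        assert lv.plan_outcome_additive(dp2, 1.1 * a1) == "I*"
        assert lv.plan_outcome_additive(dp2, 0.9 * a1) == "II*"
        dp3 = fx["regime3"]["dimensionless"]
        a2 = lv.bifurcation_amplitudes(dp3).A2
        assert lv.plan_outcome_additive(dp3, 1.1 * a2) == "I*"
        assert lv.plan_outcome_additive(dp3, 0.9 * a2) == "III*"

    @pytest.mark.parametrize(
        "A, outcome",
        [(0.5, "I*"), (0.4, "I*"), (0.2, "II*")],
    )
    def test_simulation_reaches_predicted_structure(self, dp_iv, A, outcome):
        traj = lv.simulate_dimensionless((0.6, 0.3), dp_iv, (0.0, 1500.0),
                                         A=A, n_samples=50)
        u_end, v_end = traj.final_state
        if outcome == "I*":
            assert u_end < 1e-6  # tumor eliminated
        else:
            assert u_end > 0.05 and v_end > 0.05  # coexistence point

    def test_host_never_vanishes(self, rng):
        """y stays bounded away from 0 under additive forcing."""
        for _ in range(25):
            dp = DimensionlessParams(*rng.uniform([0.2, 0.3, 0.2], [2.5, 1.5, 2.0]))
            A = rng.uniform(0.01, 0.6)
            start = rng.uniform(0.05, 1.0, size=2)
            traj = lv.simulate_dimensionless(start, dp, (0.0, 400.0),
                                             A=float(A), n_samples=100)
            tail = traj.states[50:, 1]
            assert np.min(tail) > 1e-3
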