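"""Equilibria, regime classification, separatrix, Dulac certificate."""

import numpy as np
import pytest

import lvtumor as lv
from lvtumor import DimensionlessParams, Regime
from lvtumor.dynamics import rhs_dimensionless
from lvtumor.stability import jacobian


def _find(reports, label):
    return next(r for r in reports if r.label == label)


class TestEquilibria:
    def test_origin_always_unstable_node(self, rng):
        for _ in range(20):
            dp = DimensionlessParams(*rng.uniform([0.2, 0.3, 0.2], [2.5, 1.5, 2.0]))
            p1 = _find(lv.equilibria(dp), "P1")
            eigs = sorted(e.real for e in p1.eigenvalues)
            assert eigs == pytest.approx([min(1.0, dp.d), max(1.0, dp.d)])
            assert p1.stability_class == "unstable node"

    def test_tumor_free_node_eigenvalues_regime1(self):
        dp = DimensionlessParams(c=1.65, d=0.75, f=0.45)
        p2 = _find(lv.equilibria(dp), "P2")
        eigs = sorted(e.real for e in p2.eigenvalues)
        assert eigs == pytest.approx([-0.75, -0.2375])
        assert p2.stability_class == "stable node"

    def test_coexistence_location_regime2(self, fx):
        dp = fx["regime2"]["dimensionless"]
        p4 = _find(lv.equilibria(dp), "P4")
        assert p4.location == pytest.approx((0.4716981132, 0.5283018868), rel=1e-9)
        assert p4.stability_class == "stable node"
        assert p4.physical

    def test_p4_absent_on_cf_unity(self):
        dp = DimensionlessParams(c=2.0, d=0.8, f=0.5)  # c*f = 1
        labels = [r.label for r in lv.equilibria(dp)]
        assert "P4" not in labels

    def test_finite_difference_jacobian_oracle(self, rng):
        """Analytic-Jacobian eigenvalues agree with finite differences."""
        eps = 1e-6
        for _ in range(500):
            dp = DimensionlessParams(*rng.uniform([0.2, 0.3, 0.2], [2.5, 1.5, 2.0]))
            for rep in lv.equilibria(dp):
                u, v = rep.location
                if max(abs(u), abs(v)) > 50:
                    continue
                J = np.empty((2, 2))
                for j, dvec in enumerate(np.eye(2)):
                    plus = rhs_dimensionless(0.0, np.array([u, v]) + eps * dvec, dp)
                    minus = rhs_dimensionless(0.0, np.array([u, v]) - eps * dvec, dp)
                    J[:, j] = (plus - minus) / (2 * eps)
                fd = np.sort_complex(np.linalg.eigvals(J))
                an = np.sort_complex(np.array(rep.eigenvalues))
                assert np.allclose(fd, an, atol=1e-5 * max(1.0, abs(u), abs(v)))


class TestClassification:
    def test_reference_triples(self, fx):
        assert lv.classify_regime(fx["regime1"]["dimensionless"]) is Regime.I
        assert lv.classify_regime(fx["regime2"]["dimensionless"]) is Regime.II
        assert lv.classify_regime(fx["regime3"]["dimensionless"]) is Regime.III
        assert lv.classify_regime(fx["regime4"]["dimensionless"]) is Regime.IV

    def test_boundaries_map_to_degenerate(self):
        assert lv.classify_regime(DimensionlessParams(2.0, 0.5, 0.4)) is Regime.DEGENERATE
        assert lv.classify_regime(DimensionlessParams(1.2, 0.7, 0.7)) is Regime.DEGENERATE

    def test_flow_reaches_predicted_attractor(self, rng):
        """Long simulations end at the stable structure of each regime."""
        suite = lv.generate_scenario_suite(seed=7, n_per_regime=10)
        for sc in suite:
            dp = sc["dimensionless"]
            start = rng.uniform(0.05, 1.2, size=2)
            traj = lv.simulate_dimensionless(start, dp, (0.0, 600.0),
                                             rtol=1e-8, n_samples=50)
            u_end, v_end = traj.final_state
            if sc["regime"] == "I":
                assert u_end < 1e-4 and v_end == pytest.approx(dp.d, abs=1e-4)
            elif sc["regime"] == "II":
                u4 = (1 - dp.c * dp.d) / (1 - dp.c * dp.f)
                v4 = (dp.d - dp.f) / (1 - dp.c * dp.f)
                assert (u_end, v_end) == pytest.approx((u4, v4), abs=1e-3)
            elif sc["regime"] == "IV":
                assert (u_end, v_end) == pytest.approx((1.0, 0.0), abs=1e-4)
            else:  # bistable: one of the two boundary nodes
                d_p2 = np.hypot(u_end - 0.0, v_end - dp.d)
                d_p3 = np.hypot(u_end - 1.0, v_end - 0.0)
                assert min(d_p2, d_p3) < 1e-3

    def test_p2_eigenvalue_flips_exactly_at_cd_boundary(self):
        """Crossing c*d = 1 changes the sign of one P2 eigenvalue."""
        d, f = 0.8, 0.5
        for c in (1.0 / d * 0.99, 1.0 / d * 1.01):
            p2 = _find(lv.equilibria(DimensionlessParams(c, d, f)), "P2")
            eigs = sorted(e.real for e in p2.eigenvalues)
            assert eigs[0] == pytest.approx(-d)
            assert np.sign(eigs[1]) == np.sign(1 - c * d)


class TestSeparatrix:
    def test_requires_regime_three(self, fx):
        with pytest.raises(ValueError, match="Regime III"):
            lv.separatrix(fx["regime2"]["dimensionless"])

    def test_passes_through_saddle(self, fx):
        dp = fx["regime3"]["dimensionless"]
        sep = lv.separatrix(dp)
        denom = 1 - dp.c * dp.f
        p4 = np.array([(1 - dp.c * dp.d) / denom, (dp.d - dp.f) / denom])
        assert np.min(np.linalg.norm(sep - p4, axis=1)) < 1e-9

    def test_offset_seeds_reach_opposite_nodes(self, fx):
        """Seeds on either side of the curve flow to different nodes."""
        dp = fx["regime3"]["dimensionless"]
        sep = lv.separatrix(dp)
        # Normal offset at a mid-curve point inside the quadrant.
        interior = sep[(sep[:, 0] > 0.05) & (sep[:, 1] > 0.05)]
        i = len(interior) // 2
        tangent = interior[i + 1] - interior[i - 1]
        normal = np.array([-tangent[1], tangent[0]])
        normal /= np.linalg.norm(normal)
        finals = []
        for sign in (+1, -1):
            seed = np.clip(interior[i] + sign * 5e-3 * normal, 1e-9, None)
            traj = lv.simulate_dimensionless(seed, dp, (0.0, 2000.0), n_samples=50)
            finals.append(traj.final_state)
        p2 = np.array([0.0, dp.d])
        p3 = np.array([1.0, 0.0])
        dists = [
            sorted([(np.linalg.norm(fx_ - p2), "P2"), (np.linalg.norm(fx_ - p3), "P3")])[0][1]
            for fx_ in finals
        ]
        assert set(dists) == {"P2", "P3"}


class TestDulac:
    def test_regime2_certificate_conclusive_negative(self, fx):
        cert = lv.dulac_certificate(fx["regime2"]["dimensionless"])
        assert cert.kappa < 0
        assert cert.conclusive and not cert.degenerate_case

    def test_regime1_certificate_conclusive(self):
        cert = lv.dulac_certificate(DimensionlessParams(1.65, 0.75, 0.45))
        assert cert.conclusive

    def test_exponent_formulas(self, fx):
        dp = fx["regime2"]["dimensionless"]
        cert = lv.dulac_certificate(dp)
        cf = dp.c * dp.f
        assert cert.m == pytest.approx((cf + dp.f - 2) / (1 - cf))
        assert cert.n == pytest.approx((cf + dp.c - 2) / (1 - cf))

    def test_degenerate_manifold_flagged(self):
        # c*d - 1 = d - f  <=>  kappa numerator vanishes.
        c, d = 1.2, 0.9
        f = d - (c * d - 1)
        cert = lv.dulac_certificate(DimensionlessParams(c, d, f))
        assert cert.degenerate_case and not cert.conclusive

    def test_undefined_at_cf_unity(self):
        with pytest.raises(ValueError):
            lv.dulac_certificate(DimensionlessParams(2.0, 0.9, 0.5))
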