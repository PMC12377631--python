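"""Constant host-directed therapy with constant effect.

With beta_x = 0 and beta_y < 0 the therapy feeds the host at a constant
rate; in dimensionless form the host equation gains the amplitude

    A = -D * beta_y * ry / (rx^2 * Ky) > 0.

The forced system  u' = u - u^2 - c u v,  v' = d v - v^2 - f u v + A
has equilibria

    Q1 = (0, (d - sqrt(d^2+4A))/2),  Q2 = (0, (d + sqrt(d^2+4A))/2)
    Q3, Q4 = (1 - c*v, v),  v = (f - d -/+ sqrt(Delta)) / (2(c*f - 1))

with Delta = (f-d)^2 - 4A(c*f-1).  Q1 is always unstable and Q2
becomes stable for A > A1 = (1-c*d)/c^2; when c*f > 1 the interior
pair Q3/Q4 collides in a saddle-node bifurcation at
A2 = (f-d)^2 / (4(c*f-1)).  Because (x, 0) is never an equilibrium of
the forced system, the host population cannot vanish.  Outcome labels
carry a star to mark perturbed-system regimes.
"""

from __future__ import annotations

import math
from typing import NamedTuple

from .params import DimensionlessParams, KineticParams, to_dimensionless
from .stability import EquilibriumReport, Regime, classify_eigenvalues, classify_regime, jacobian

import numpy as np

__all__ = [
    "BifurcationAmplitudes",
    "forcing_amplitude",
    "amplitude_to_dose",
    "q_equilibria",
    "bifurcation_amplitudes",
    "dose_thresholds_additive",
    "plan_outcome_additive",
]


class BifurcationAmplitudes(NamedTuple):
    A1: float
    A2: float
    # A2 marks a saddle-node only when c*f > 1; otherwise Q3/Q4 exist
    # for every A >= 0 and the raw formula value has no bifurcation
    # meaning.
    A2_is_bifurcation: bool


def forcing_amplitude(D: float, beta_y: float, params: KineticParams) -> float:
    """Dimensionless amplitude A = -D*beta_y*ry/(rx^2*Ky)."""
    if beta_y >= 0:
        raise ValueError("host-directed additive therapy requires beta_y < 0")
    if D < 0:
        raise ValueError("D must be non-negative")
    return -D * beta_y * params.ry / (params.rx**2 * params.Ky)


def amplitude_to_dose(A: float, beta_y: float, params: KineticParams) -> float:
    """Inverse of :func:`forcing_amplitude`."""
    if beta_y >= 0:
        raise ValueError("host-directed additive therapy requires beta_y < 0")
    return A * params.rx**2 * params.Ky / (abs(beta_y) * params.ry)


def _q_report(label: str, u: float, v: float, dp: DimensionlessParams) -> EquilibriumReport:
    eigs = np.linalg.eigvals(jacobian(u, v, dp))
    order = np.lexsort((eigs.imag, -eigs.real))
    eigs = eigs[order]
    return EquilibriumReport(
        label=label,
        location=(u, v),
        eigenvalues=(complex(eigs[0]), complex(eigs[1])),
        stability_class=classify_eigenvalues(eigs),
        physical=bool(u >= -1e-12 and v >= -1e-12),
    )


def q_equilibria(dp: DimensionlessParams, A: float) -> list[EquilibriumReport]:
    """Equilibria Q1..Q4 of the constant-forced system.

    Q1/Q2 always exist on the u = 0 axis.  The interior pair is real
    only while Delta >= 0; at Delta = 0 the collided point is reported
    once under the label ``Q3=Q4`` (it carries a zero eigenvalue).
    Non-physical points (negative coordinates) are retained with
    ``physical=False``.
    """
    if A < 0:
        raise ValueError("A must be non-negative")
    root = math.sqrt(dp.d * dp.d + 4.0 * A)
    out = [
        _q_report("Q1", 0.0, 0.5 * (dp.d - root), dp),
        _q_report("Q2", 0.0, 0.5 * (dp.d + root), dp),
    ]
    cf1 = dp.c * dp.f - 1.0
    if cf1 == 0.0:
        # Quadratic degenerates to linear: one interior root.
        if dp.f != dp.d:
            v = A / (dp.f - dp.d)
            out.append(_q_report("Q3", 1.0 - dp.c * v, v, dp))
        return out
    delta = (dp.f - dp.d) ** 2 - 4.0 * A * cf1
    # Collision detection must tolerate roundoff when A sits exactly
    # at the saddle-node amplitude.
    collision_tol = 1e-12 * max(1.0, (dp.f - dp.d) ** 2)
    if abs(delta) <= collision_tol:
        v = (dp.f - dp.d) / (2.0 * cf1)
        out.append(_q_report("Q3=Q4", 1.0 - dp.c * v, v, dp))
    elif delta > 0.0:
        sq = math.sqrt(delta)
        v3 = (dp.f - dp.d - sq) / (2.0 * cf1)
        v4 = (dp.f - dp.d + sq) / (2.0 * cf1)
        out.append(_q_report("Q3", 1.0 - dp.c * v3, v3, dp))
        out.append(_q_report("Q4", 1.0 - dp.c * v4, v4, dp))
    return out


def bifurcation_amplitudes(dp: DimensionlessParams) -> BifurcationAmplitudes:
    """Amplitudes A1 (Q2 stabilization) and A2 (Q3/Q4 collision)."""
    cf1 = dp.c * dp.f - 1.0
    if cf1 == 0.0:
        raise ValueError("A2 is undefined at c*f = 1")
    A1 = (1.0 - dp.c * dp.d) / dp.c**2
    A2 = (dp.f - dp.d) ** 2 / (4.0 * cf1)
    return BifurcationAmplitudes(A1=A1, A2=A2, A2_is_bifurcation=bool(cf1 > 0))


def dose_thresholds_additive(
    params: KineticParams, beta_y: float
) -> tuple[float, float]:
    """Doses (D1, D2) mapping to (A1, A2) in original units.

    D1 = rx*ry(rx - Ky*axy) / (Ky*axy^2 |beta_y|)
    D2 = rx*Ky(ry - Kx*ayx)^2 / (4|beta_y|(Ky*Kx*axy*ayx - rx*ry))

    Each satisfies forcing_amplitude(Di) = Ai identically.
    """
    if beta_y >= 0:
        raise ValueError("host-directed additive therapy requires beta_y < 0")
    axy, ayx = params.alpha_xy, params.alpha_yx
    d1_den = params.Ky * axy**2 * abs(beta_y)
    d2_den = 4.0 * abs(beta_y) * (params.Ky * params.Kx * axy * ayx - params.rx * params.ry)
    if d1_den == 0.0 or d2_den == 0.0:
        raise ValueError("threshold denominator vanishes (boundary case)")
    D1 = params.rx * params.ry * (params.rx - params.Ky * axy) / d1_den
    D2 = params.rx * params.Ky * (params.ry - params.Kx * ayx) ** 2 / d2_den
    return D1, D2


def plan_outcome_additive(
    dp: DimensionlessParams, A: float, boundary_tol: float = 1e-12
) -> str:
    """Predicted perturbed regime under constant host forcing A.

    Implements the per-regime decision lists; outcomes are "I*"
    (tumor eliminated), "II*" / "III*" (coexistence structures of the
    forced system) or "DEGENERATE" on a threshold.
    """
    if A < 0:
        raise ValueError("A must be non-negative")
    baseline = classify_regime(dp)
    if baseline is Regime.DEGENERATE:
        return "DEGENERATE"
    if A == 0.0:
        return baseline.value
    if baseline is Regime.I:
        # Host forcing only reinforces tumor elimination.
        return "I*"

    amps = bifurcation_amplitudes(dp)
    near = lambda a, b: abs(a - b) <= boundary_tol * max(1.0, abs(b))  # noqa: E731
    cf = dp.c * dp.f

    if baseline is Regime.IV:
        if cf > 1:
            if near(A, amps.A2) or near(A, amps.A1):
                return "DEGENERATE"
            if A > amps.A2:
                return "I*"
            if amps.A1 < A < amps.A2:
                side = dp.c * (dp.f - dp.d) - 2.0 * (cf - 1.0)
                return "I*" if side > 0 else "III*"
            return "II*"
        if near(A, amps.A1):
            return "DEGENERATE"
        return "I*" if A > amps.A1 else "II*"
    if baseline is Regime.III:
        if near(A, amps.A2):
            return "DEGENERATE"
        return "I*" if A > amps.A2 else "III*"
    # Regime II
    if near(A, amps.A1):
        return "DEGENERATE"
    return "I*" if A > amps.A1 else "II*"
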