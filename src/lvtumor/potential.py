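"""One-dimensional potential of the particle analogy.

Eliminating the host variable turns the tumor equation into the motion
of a damped particle in a potential V(u).  The force is

    -dV/du = (1/c - d) u + (d + f - 2/c) u^2 + (1/c - f) u^3

so V is a quartic (normalized here with V(0) = 0) whose extrema are
u1* = 0, u2* = 1 and u3* = (1-c*d)/(1-c*f).  Minima of V sit under the
stable equilibria of the planar system, and the curvature at a minimum
defines the characteristic (angular) frequency Omega = sqrt(V'').  At
u* = 1 this reduces to Omega = sqrt(f - d).
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np

from .params import DimensionlessParams

__all__ = ["PotentialProfile", "potential_profile", "characteristic_frequency"]


@dataclass(frozen=True)
class PotentialProfile:
    """Quartic potential, its extrema and the sub-case label."""

    dp: DimensionlessParams
    # Coefficients of V(u) = c2*u^2 + c3*u^3 + c4*u^4 (V(0)=0, V'(0)=0).
    coefficients: tuple[float, float, float]
    # (u_star, "min"|"max"|"inflection", curvature) for each real extremum.
    extrema: tuple[tuple[float, str, float], ...]
    case_label: str

    def value(self, u):
        c2, c3, c4 = self.coefficients
        u = np.asarray(u, dtype=float)
        return c2 * u**2 + c3 * u**3 + c4 * u**4

    def gradient(self, u):
        c2, c3, c4 = self.coefficients
        u = np.asarray(u, dtype=float)
        return 2 * c2 * u + 3 * c3 * u**2 + 4 * c4 * u**3

    def curvature(self, u):
        c2, c3, c4 = self.coefficients
        u = np.asarray(u, dtype=float)
        return 2 * c2 + 6 * c3 * u + 12 * c4 * u**2

    def minima(self) -> list[float]:
        return [u for u, kind, _ in self.extrema if kind == "min"]


def _case_label(dp: DimensionlessParams) -> str:
    cd, cf = dp.c * dp.d, dp.c * dp.f
    if cd > 1 and dp.f < dp.d:
        return "I-cf>1" if cf > 1 else "I-cf<1"
    if cd < 1 and dp.f < dp.d:
        return "II"
    if cd > 1 and dp.f > dp.d:
        return "III"
    if cd < 1 and dp.f > dp.d:
        return "IV-cf>1" if cf > 1 else "IV-cf<1"
    return "DEGENERATE"


def potential_profile(dp: DimensionlessParams) -> PotentialProfile:
    """Build V(u), locate its extrema in closed form and label the case.

    dV/du factors as u * (a*u^2 + b*u + g) with a = f - 1/c,
    b = 2/c - d - f, g = d - 1/c; u = 1 is always a root of the
    quadratic factor and the third extremum is g/a = (1-c*d)/(1-c*f).
    Extrema are classified by the sign of the actual curvature there
    (at u=0 it equals (c*d-1)/c, at u=1 it equals f - d).
    """
    inv_c = 1.0 / dp.c
    g = dp.d - inv_c
    b = 2.0 * inv_c - dp.d - dp.f
    a = dp.f - inv_c
    coeffs = (g / 2.0, b / 3.0, a / 4.0)

    roots = [0.0, 1.0]
    if a != 0.0:
        roots.append(g / a)  # = (1-c*d)/(1-c*f)

    profile_stub = PotentialProfile(dp, coeffs, (), "")
    extrema = []
    for u_star in roots:
        curv = float(profile_stub.curvature(u_star))
        if curv > 0:
            kind = "min"
        elif curv < 0:
            kind = "max"
        else:
            kind = "inflection"
        extrema.append((float(u_star), kind, curv))

    return PotentialProfile(dp, coeffs, tuple(extrema), _case_label(dp))


def characteristic_frequency(profile: PotentialProfile, u_star: float) -> float:
    """Omega = sqrt(d^2V/du^2) at a minimum of V.

    Raises if the curvature is negative (a maximum has no oscillation
    frequency); a vanishing curvature on a regime boundary gives 0.
    """
    curv = float(profile.curvature(u_star))
    if curv < 0:
        raise ValueError(
            f"curvature {curv} at u*={u_star} is negative; "
            "Omega is defined only at minima of V"
        )
    return math.sqrt(curv)
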