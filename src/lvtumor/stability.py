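"""Equilibria, regime classification, separatrix and Dulac certificate.

The unperturbed dimensionless system

    du/dtau = u - u^2 - c*u*v
    dv/dtau = d*v - v^2 - f*u*v

has fixed points P1=(0,0), P2=(0,d), P3=(1,0) and, when c*f != 1, the
coexistence point P4=((1-c*d)/(1-c*f), (d-f)/(1-c*f)).  The sign
pattern of (c*d-1, f-d, c*f-1) selects one of four dynamical regimes:

I   (c*d>1, f<d)          -- tumor eliminated, P2 attracts everything
II  (c*f<1, c*d<1, f<d)   -- stable coexistence at P4
III (c*f>1, c*d>1, f>d)   -- bistable; the stable manifold of the
                             saddle P4 separates the basins of P2, P3
IV  (c*d<1, f>d)          -- tumor wins, P3 attracts everything

A Dulac function R = u^m v^n rules out closed orbits away from the
degenerate manifold c*d - 1 = d - f.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .params import DimensionlessParams

__all__ = [
    "Regime",
    "EquilibriumReport",
    "DulacCertificate",
    "jacobian",
    "equilibria",
    "classify_regime",
    "classify_eigenvalues",
    "separatrix",
    "dulac_certificate",
]


class Regime(enum.Enum):
    I = "I"
    II = "II"
    III = "III"
    IV = "IV"
    DEGENERATE = "DEGENERATE"


@dataclass(frozen=True)
class EquilibriumReport:
    label: str
    location: tuple[float, float]
    eigenvalues: tuple[complex, complex]
    stability_class: str
    physical: bool


@dataclass(frozen=True)
class DulacCertificate:
    """Exponents of R = u^m v^n and the sign coefficient of Gamma.

    ``kappa = (c*d - 1 + f - d)/(1 - c*f)`` multiplies u^m v^n in the
    divergence of the rescaled field; a nonzero kappa certifies the
    absence of closed orbits inside the open quadrant.
    """

    m: float
    n: float
    kappa: float
    conclusive: bool
    degenerate_case: bool


def jacobian(u: float, v: float, dp: DimensionlessParams) -> np.ndarray:
    """Analytic Jacobian of the (possibly additively forced) field.

    Additive forcing enters the field as a state-independent term, so
    the Jacobian is the same with or without it.
    """
    return np.array(
        [
            [1.0 - 2.0 * u - dp.c * v, -dp.c * u],
            [-dp.f * v, dp.d - 2.0 * v - dp.f * u],
        ]
    )


def classify_eigenvalues(eigs, tol: float = 1e-9) -> str:
    """Name the stability class from a pair of eigenvalues."""
    l1, l2 = eigs
    re = np.array([l1.real, l2.real])
    im = np.array([l1.imag, l2.imag])
    if np.any(np.abs(re) <= tol):
        return "degenerate"
    if np.all(np.abs(im) > tol):
        return "stable spiral" if np.all(re < 0) else "unstable spiral"
    if np.all(re < 0):
        return "stable node"
    if np.all(re > 0):
        return "unstable node"
    return "saddle"


def _report(label: str, u: float, v: float, dp: DimensionlessParams) -> EquilibriumReport:
    eigs = np.linalg.eigvals(jacobian(u, v, dp))
    # Deterministic ordering: descending real part, then imaginary.
    order = np.lexsort((eigs.imag, -eigs.real))
    eigs = eigs[order]
    return EquilibriumReport(
        label=label,
        location=(u, v),
        eigenvalues=(complex(eigs[0]), complex(eigs[1])),
        stability_class=classify_eigenvalues(eigs),
        physical=bool(u >= -1e-12 and v >= -1e-12),
    )


def equilibria(dp: DimensionlessParams) -> list[EquilibriumReport]:
    """All fixed points of the unperturbed system with their stability.

    Eigenvalues are computed numerically from the analytic Jacobian at
    each point.  When ``c*f = 1`` the coexistence point escapes to
    infinity and only P1-P3 are returned.
    """
    out = [
        _report("P1", 0.0, 0.0, dp),
        _report("P2", 0.0, dp.d, dp),
        _report("P3", 1.0, 0.0, dp),
    ]
    denom = 1.0 - dp.c * dp.f
    if denom != 0.0:
        u4 = (1.0 - dp.c * dp.d) / denom
        v4 = (dp.d - dp.f) / denom
        out.append(_report("P4", u4, v4, dp))
    return out


def classify_regime(dp: DimensionlessParams, tol: float = 1e-12) -> Regime:
    """Classify (c, d, f) into Regime I-IV.

    Points within ``tol`` of the boundary manifolds c*d=1, f=d or
    c*f=1 (when the latter decides) are mapped to DEGENERATE rather
    than silently picking a side.
    """
    cd = dp.c * dp.d
    cf = dp.c * dp.f
    if abs(cd - 1.0) <= tol or abs(dp.f - dp.d) <= tol:
        return Regime.DEGENERATE
    if cd > 1.0 and dp.f < dp.d:
        return Regime.I
    if cd < 1.0 and dp.f > dp.d:
        return Regime.IV
    if cd < 1.0 and dp.f < dp.d:
        # Here c*f < c*d < 1 automatically; Regime II.
        return Regime.II
    # cd > 1 and f > d: c*f > c*d > 1 automatically; Regime III.
    return Regime.III


def separatrix(
    dp: DimensionlessParams,
    arc_time: float = 60.0,
    n_points: int = 400,
    eps: float = 1e-6,
    bound: float = 5.0,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> np.ndarray:
    """Stable manifold of the Regime-III saddle P4, as an (n, 2) array.

    Both branches are grown by integrating the field backward in time
    from ``P4 +/- eps * e_s`` where ``e_s`` is the stable eigenvector.
    Integration stops after ``arc_time`` backward time units or when
    the curve leaves the box [0, bound]^2.  Points are ordered along
    the curve (branch, P4, other branch).
    """
    if classify_regime(dp) is not Regime.III:
        raise ValueError("the separatrix is defined only in Regime III")
    denom = 1.0 - dp.c * dp.f
    p4 = np.array([(1.0 - dp.c * dp.d) / denom, (dp.d - dp.f) / denom])
    J = jacobian(p4[0], p4[1], dp)
    w, vecs = np.linalg.eig(J)
    stable_idx = int(np.argmin(w.real))
    if w.real[stable_idx] >= 0:
        raise ValueError("P4 is not a saddle; no stable manifold to grow")
    e_s = np.real(vecs[:, stable_idx])
    e_s /= np.linalg.norm(e_s)

    def backward(t, s):
        u, v = s
        return [
            -(u - u * u - dp.c * u * v),
            -(dp.d * v - v * v - dp.f * u * v),
        ]

    def leave_box(t, s):
        return min(s[0], s[1], bound - s[0], bound - s[1])

    leave_box.terminal = True
    leave_box.direction = -1

    branches = []
    for sign in (+1.0, -1.0):
        sol = solve_ivp(
            backward,
            (0.0, arc_time),
            p4 + sign * eps * e_s,
            t_eval=np.linspace(0.0, arc_time, n_points // 2),
            events=leave_box,
            rtol=rtol,
            atol=atol,
        )
        branches.append(sol.y.T)
    # Order: far end of branch 0 -> P4 -> far end of branch 1.
    return np.vstack([branches[0][::-1], p4[None, :], branches[1]])


def dulac_certificate(dp: DimensionlessParams, tol: float = 1e-12) -> DulacCertificate:
    """Exponents and sign coefficient of the Dulac function u^m v^n."""
    cf = dp.c * dp.f
    if abs(1.0 - cf) <= tol:
        raise ValueError("Dulac exponents are undefined at c*f = 1")
    m = (cf + dp.f - 2.0) / (1.0 - cf)
    n = (cf + dp.c - 2.0) / (1.0 - cf)
    kappa = (dp.c * dp.d - 1.0 + dp.f - dp.d) / (1.0 - cf)
    degenerate = abs((dp.c * dp.d - 1.0) - (dp.d - dp.f)) <= tol
    return DulacCertificate(
        m=m,
        n=n,
        kappa=kappa,
        conclusive=bool(kappa != 0.0 and not degenerate),
        degenerate_case=degenerate,
    )
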