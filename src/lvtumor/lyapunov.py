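"""Lyapunov spectrum of the forced tumor-host system.

The maximum Lyapunov exponent is estimated with the classic
renormalization scheme: a reference trajectory of

    u' = u - u^2 - c*u*v
    v' = d*v - v^2 - f*u*v + A*(1 - cos(omega*tau))

is integrated together with tangent vectors obeying the linearized
system  dw/dtau = M(r(tau)) w,  where M is the Jacobian of the field.
Every renormalization interval ``tau_renorm`` the leading tangent
vector is rescaled to unit norm and its stretch factor d_k recorded;
the running estimate after n intervals is

    sigma_n = (1 / (n * tau_renorm)) * sum_k ln(d_k).

The second exponent uses the same stretches of a companion vector
after Gram-Schmidt orthogonalization against the leading one.  The
scheme is invariant to the initial tangent scale: the first
renormalization resets the norm, so only the unit-vector dynamics
matter.

Integration uses a fixed-step classical 4th-order Runge-Kutta on the
augmented 6-dimensional system, with defaults tau_renorm = 0.1 and
h = 0.02.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LyapunovSettings",
    "LyapunovResult",
    "lyapunov_spectrum",
    "sigma_sequence",
    "search_max_lce",
    "lce_parameter_sweep",
    "DEFAULT_SEARCH_BOX",
]


@dataclass(frozen=True)
class LyapunovSettings:
    """Numerical settings of the renormalization scheme.

    ``tau_renorm`` is the interval between tangent rescalings (in
    dimensionless time; not the time variable itself), ``h`` the RK4
    step, ``n_steps`` the number of renormalizations, ``d0`` the
    initial tangent norm (the estimate is invariant to it).
    """

    tau_renorm: float = 0.1
    h: float = 0.02
    n_steps: int = 20000
    d0: float = 1.0
    convergence_tol: float = 1e-3

    def __post_init__(self) -> None:
        if self.tau_renorm <= 0:
            raise ValueError("tau_renorm must be positive")
        if not 0 < self.h <= self.tau_renorm:
            raise ValueError("h must satisfy 0 < h <= tau_renorm")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")


@dataclass(frozen=True)
class LyapunovResult:
    sigma_sequence: np.ndarray  # running sigma_n for the leading exponent
    sigma2_sequence: np.ndarray
    spectrum: tuple[float, float]  # descending
    max_exponent: float
    converged: bool
    params: dict
    settings: LyapunovSettings


class TrajectoryEscapeError(RuntimeError):
    """The reference trajectory left the working domain (overflow)."""


def _benettin(c, d, f, A, omega, u, v, n_renorm, tau, h, w1, w2):
    """Core renormalization loop.  Pure Python for tight inner loop.

    State: reference (u, v) plus tangent vectors w1, w2 as 4 floats.
    Returns (log-stretch arrays for both vectors).
    """
    steps = max(1, round(tau / h))
    h = tau / steps  # make the renormalization time exact
    w1u, w1v = w1
    w2u, w2v = w2
    t = 0.0
    logs1 = np.empty(n_renorm)
    logs2 = np.empty(n_renorm)
    cos = math.cos
    for k in range(n_renorm):
        for _ in range(steps):
            # RK4 on the augmented system (u, v, w1, w2).
            a1 = A * (1.0 - cos(omega * t)) if A != 0.0 else 0.0
            ku1 = u - u * u - c * u * v
            kv1 = d * v - v * v - f * u * v + a1
            j11 = 1.0 - 2.0 * u - c * v
            j12 = -c * u
            j21 = -f * v
            j22 = d - 2.0 * v - f * u
            kw1u1 = j11 * w1u + j12 * w1v
            kw1v1 = j21 * w1u + j22 * w1v
            kw2u1 = j11 * w2u + j12 * w2v
            kw2v1 = j21 * w2u + j22 * w2v

            th = t + 0.5 * h
            a2 = A * (1.0 - cos(omega * th)) if A != 0.0 else 0.0
            u2 = u + 0.5 * h * ku1
            v2 = v + 0.5 * h * kv1
            ku2 = u2 - u2 * u2 - c * u2 * v2
            kv2 = d * v2 - v2 * v2 - f * u2 * v2 + a2
            j11 = 1.0 - 2.0 * u2 - c * v2
            j12 = -c * u2
            j21 = -f * v2
            j22 = d - 2.0 * v2 - f * u2
            x = w1u + 0.5 * h * kw1u1
            y = w1v + 0.5 * h * kw1v1
            kw1u2 = j11 * x + j12 * y
            kw1v2 = j21 * x + j22 * y
            x = w2u + 0.5 * h * kw2u1
            y = w2v + 0.5 * h * kw2v1
            kw2u2 = j11 * x + j12 * y
            kw2v2 = j21 * x + j22 * y

            u3 = u + 0.5 * h * ku2
            v3 = v + 0.5 * h * kv2
            ku3 = u3 - u3 * u3 - c * u3 * v3
            kv3 = d * v3 - v3 * v3 - f * u3 * v3 + a2
            j11 = 1.0 - 2.0 * u3 - c * v3
            j12 = -c * u3
            j21 = -f * v3
            j22 = d - 2.0 * v3 - f * u3
            x = w1u + 0.5 * h * kw1u2
            y = w1v + 0.5 * h * kw1v2
            kw1u3 = j11 * x + j12 * y
            kw1v3 = j21 * x + j22 * y
            x = w2u + 0.5 * h * kw2u2
            y = w2v + 0.5 * h * kw2v2
            kw2u3 = j11 * x + j12 * y
            kw2v3 = j21 * x + j22 * y

            tf = t + h
            a4 = A * (1.0 - cos(omega * tf)) if A != 0.0 else 0.0
            u4 = u + h * ku3
            v4 = v + h * kv3
            ku4 = u4 - u4 * u4 - c * u4 * v4
            kv4 = d * v4 - v4 * v4 - f * u4 * v4 + a4
            j11 = 1.0 - 2.0 * u4 - c * v4
            j12 = -c * u4
            j21 = -f * v4
            j22 = d - 2.0 * v4 - f * u4
            x = w1u + h * kw1u3
            y = w1v + h * kw1v3
            kw1u4 = j11 * x + j12 * y
            kw1v4 = j21 * x + j22 * y
            x = w2u + h * kw2u3
            y = w2v + h * kw2v3
            kw2u4 = j11 * x + j12 * y
            kw2v4 = j21 * x + j22 * y

            sixth = h / 6.0
            u += sixth * (ku1 + 2.0 * ku2 + 2.0 * ku3 + ku4)
            v += sixth * (kv1 + 2.0 * kv2 + 2.0 * kv3 + kv4)
            w1u += sixth * (kw1u1 + 2.0 * kw1u2 + 2.0 * kw1u3 + kw1u4)
            w1v += sixth * (kw1v1 + 2.0 * kw1v2 + 2.0 * kw1v3 + kw1v4)
            w2u += sixth * (kw2u1 + 2.0 * kw2u2 + 2.0 * kw2u3 + kw2u4)
            w2v += sixth * (kw2v1 + 2.0 * kw2v2 + 2.0 * kw2v3 + kw2v4)
            t = tf

        if not (abs(u) < 1e8 and abs(v) < 1e8):
            raise TrajectoryEscapeError(
                f"trajectory escaped at tau={t:.3f}: u={u}, v={v}"
            )
        # Renormalize w1 to unit norm; record the stretch.
        d1 = math.sqrt(w1u * w1u + w1v * w1v)
        logs1[k] = math.log(d1)
        w1u /= d1
        w1v /= d1
        # Gram-Schmidt: remove the w1 component of w2, then rescale.
        proj = w2u * w1u + w2v * w1v
        w2u -= proj * w1u
        w2v -= proj * w1v
        d2 = math.sqrt(w2u * w2u + w2v * w2v)
        logs2[k] = math.log(d2)
        w2u /= d2
        w2v /= d2
    return logs1, logs2


def lyapunov_spectrum(
    dp,
    A: float,
    omega: float,
    settings: Optional[LyapunovSettings] = None,
    initial_state: Sequence[float] = (0.5, 0.5),
    initial_tangents: Optional[np.ndarray] = None,
) -> LyapunovResult:
    """Two-exponent Lyapunov spectrum of the forced dimensionless system.

    ``dp`` is a DimensionlessParams (or any object with c, d, f).
    Convergence is declared when the drift of sigma_n over the last
    quartile of the run is below ``settings.convergence_tol``.
    """
    settings = settings or LyapunovSettings()
    if initial_tangents is None:
        w1, w2 = (1.0, 0.0), (0.0, 1.0)
    else:
        w1 = (float(initial_tangents[0][0]), float(initial_tangents[0][1]))
        w2 = (float(initial_tangents[1][0]), float(initial_tangents[1][1]))
    # Scale invariance: normalize whatever was supplied (d0 drops out
    # after the first renormalization anyway).
    n1 = math.hypot(*w1)
    n2 = math.hypot(*w2)
    w1 = (w1[0] / n1, w1[1] / n1)
    w2 = (w2[0] / n2, w2[1] / n2)

    u0, v0 = float(initial_state[0]), float(initial_state[1])
    logs1, logs2 = _benettin(
        dp.c, dp.d, dp.f, A, omega, u0, v0,
        settings.n_steps, settings.tau_renorm, settings.h, w1, w2,
    )
    denom = settings.tau_renorm * np.arange(1, settings.n_steps + 1)
    sig1 = np.cumsum(logs1) / denom
    sig2 = np.cumsum(logs2) / denom
    q = max(1, settings.n_steps // 4)
    drift = float(np.max(sig1[-q:]) - np.min(sig1[-q:]))
    spectrum = (float(sig1[-1]), float(sig2[-1]))
    spectrum = tuple(sorted(spectrum, reverse=True))
    return LyapunovResult(
        sigma_sequence=sig1,
        sigma2_sequence=sig2,
        spectrum=spectrum,
        max_exponent=spectrum[0],
        converged=bool(drift < settings.convergence_tol),
        params={"c": dp.c, "d": dp.d, "f": dp.f, "A": A, "omega": omega},
        settings=settings,
    )


def sigma_sequence(result: LyapunovResult) -> np.ndarray:
    """Running estimate as an (n, 2) array of (n, sigma_n) pairs."""
    n = np.arange(1, len(result.sigma_sequence) + 1)
    return np.column_stack([n, result.sigma_sequence])


DEFAULT_SEARCH_BOX = {
    "c": (0.5, 2.0),
    "d": (0.5, 1.5),
    "f": (0.5, 1.5),
    "A": (0.0, 0.5),
    "omega": (0.05, 5.0),
}

_PARAM_ORDER = ("c", "d", "f", "A", "omega")


class _Point:
    __slots__ = ("c", "d", "f")

    def __init__(self, c, d, f):
        self.c, self.d, self.f = c, d, f


def _evaluate(point: dict, settings: LyapunovSettings, initial_state) -> float:
    res = lyapunov_spectrum(
        _Point(point["c"], point["d"], point["f"]),
        point["A"],
        point["omega"],
        settings=settings,
        initial_state=initial_state,
    )
    return res.max_exponent


def search_max_lce(
    box: Optional[dict] = None,
    budget: int = 60,
    seed: int = 0,
    settings: Optional[LyapunovSettings] = None,
    initial_state: Sequence[float] = (0.5, 0.5),
) -> tuple[dict, LyapunovResult]:
    """Monte-Carlo search for local maxima of the maximum exponent.

    Uniform sampling over the 5-parameter box (c, d, f, A, omega) for
    half the budget, then Gaussian proposals shrinking around the
    incumbent best.  Deterministic for a fixed seed.  Returns the best
    point and its full spectrum.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    box = dict(DEFAULT_SEARCH_BOX if box is None else box)
    settings = settings or LyapunovSettings(n_steps=4000)
    rng = np.random.default_rng(seed)
    lo = np.array([box[k][0] for k in _PARAM_ORDER])
    hi = np.array([box[k][1] for k in _PARAM_ORDER])
    best_point, best_val = None, -np.inf
    n_explore = max(1, budget // 2)
    failures = 0
    for i in range(budget):
        if best_point is None or i < n_explore:
            vec = rng.uniform(lo, hi)
        else:
            # Local refinement: shrink the proposal width over time.
            frac = (i - n_explore) / max(1, budget - n_explore)
            width = (hi - lo) * 0.25 * (1.0 - frac) + 1e-3
            center = np.array([best_point[k] for k in _PARAM_ORDER])
            vec = np.clip(center + rng.normal(0.0, width), lo, hi)
        point = dict(zip(_PARAM_ORDER, map(float, vec)))
        if point["c"] <= 0 or point["d"] <= 0 or point["f"] <= 0:
            continue
        try:
            val = _evaluate(point, settings, initial_state)
        except TrajectoryEscapeError:
            failures += 1
            continue
        if val > best_val:
            best_point, best_val = point, val
    if best_point is None:
        raise RuntimeError(f"all {failures} evaluations failed in the search box")
    best_result = lyapunov_spectrum(
        _Point(best_point["c"], best_point["d"], best_point["f"]),
        best_point["A"],
        best_point["omega"],
        settings=settings,
        initial_state=initial_state,
    )
    return best_point, best_result


def lce_parameter_sweep(
    base_point: dict,
    name: str,
    grid: Sequence[float],
    settings: Optional[LyapunovSettings] = None,
    initial_state: Sequence[float] = (0.5, 0.5),
) -> pd.DataFrame:
    """One-at-a-time sweep of the maximum exponent over one parameter.

    Holds the other four parameters of ``base_point`` fixed; failed
    evaluations appear as NaN gaps.
    """
    if name not in _PARAM_ORDER:
        raise ValueError(f"unknown parameter {name!r}; expected one of {_PARAM_ORDER}")
    settings = settings or LyapunovSettings(n_steps=4000)
    rows = []
    for value in grid:
        point = dict(base_point)
        point[name] = float(value)
        try:
            val = _evaluate(point, settings, initial_state)
        except (TrajectoryEscapeError, ValueError):
            val = float("nan")
        rows.append({name: float(value), "max_exponent": val})
    return pd.DataFrame(rows)
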