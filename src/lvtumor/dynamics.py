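"""Vector fields and trajectory simulation for the tumor-host model."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
from scipy.integrate import solve_ivp

from .params import (
    DimensionlessParams,
    KineticParams,
    TherapySpec,
)

__all__ = [
    "Trajectory",
    "SimulationError",
    "rhs_original",
    "rhs_dimensionless",
    "simulate",
    "simulate_dimensionless",
]

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10


class SimulationError(RuntimeError):
    """Raised when the ODE solver fails; carries the last accepted time."""

    def __init__(self, message: str, last_time: float | None = None):
        super().__init__(message)
        self.last_time = last_time


@dataclass(frozen=True)
class Trajectory:
    """A simulated orbit: times, states and solver metadata.

    ``states`` has shape (n, 2) with columns (x, y) or (u, v) depending
    on the ``coordinates`` tag.
    """

    times: np.ndarray
    states: np.ndarray
    coordinates: str  # "original" | "dimensionless"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.times) != len(self.states):
            raise ValueError("times and states must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]


def rhs_original(
    t: float,
    state: Sequence[float],
    params: KineticParams,
    therapy: Optional[TherapySpec] = None,
) -> np.ndarray:
    """Right-hand side in original coordinates, with optional therapy.

    The therapy term depends on the mode: proportional-constant
    subtracts ``D*beta_x*x`` / ``D*beta_y*y``; additive-constant
    subtracts the constant ``D*beta_x`` / ``D*beta_y``; periodic
    additive modulates the constant effect by ``(1 - cos(omega*t))``.
    With ``D = 0`` all modes coincide with the unperturbed field.
    """
    x, y = state
    dx = params.rx * x * (1.0 - x / params.Kx) - params.alpha_xy * x * y
    dy = params.ry * y * (1.0 - y / params.Ky) - params.alpha_yx * x * y
    if therapy is not None and therapy.D > 0:
        if therapy.mode == "proportional_constant":
            dx -= therapy.D * therapy.beta_x * x
            dy -= therapy.D * therapy.beta_y * y
        elif therapy.mode == "additive_constant":
            dx -= therapy.D * therapy.beta_x
            dy -= therapy.D * therapy.beta_y
        elif therapy.mode == "periodic_additive":
            pulse = therapy.D * (1.0 - math.cos(therapy.omega * t))
            dx -= pulse * therapy.beta_x
            dy -= pulse * therapy.beta_y
        else:  # pragma: no cover - TherapySpec validates the mode
            raise ValueError(f"unknown therapy mode {therapy.mode!r}")
    return np.array([dx, dy])


def rhs_dimensionless(
    tau: float,
    state: Sequence[float],
    dp: DimensionlessParams,
    forcing: Union[float, Callable[[float], float]] = 0.0,
) -> np.ndarray:
    """Dimensionless field (u - u^2 - c*u*v, d*v - v^2 - f*u*v + A(tau)).

    ``forcing`` is the additive amplitude A applied to the host
    equation: a constant, or a callable A(tau) for periodic forcing.
    """
    u, v = state
    a = forcing(tau) if callable(forcing) else forcing
    du = u - u * u - dp.c * u * v
    dv = dp.d * v - v * v - dp.f * u * v + a
    return np.array([du, dv])


def _integrate(fun, t_span, y0, t_eval, rtol, atol, method, max_step):
    sol = solve_ivp(
        fun,
        t_span,
        y0,
        method=method,
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
        max_step=max_step,
        dense_output=False,
    )
    if not sol.success:
        last = sol.t[-1] if len(sol.t) else t_span[0]
        raise SimulationError(f"ODE solver failed: {sol.message}", last_time=last)
    return sol


def simulate(
    initial_state: Sequence[float],
    params: KineticParams,
    t_span: tuple[float, float],
    therapy: Optional[TherapySpec] = None,
    t_eval: Optional[np.ndarray] = None,
    n_samples: int = 500,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = "RK45",
    max_step: float = np.inf,
) -> Trajectory:
    """Simulate the original-coordinate system, optionally under therapy.

    Non-negative initial states stay in the positive quadrant up to
    solver tolerance for the proportional and unperturbed fields; the
    solution is not clipped.
    """
    t0, t1 = t_span
    if not t1 > t0:
        raise ValueError("t_span must be non-degenerate with t1 > t0")
    x0, y0 = initial_state
    if x0 < 0 or y0 < 0:
        raise ValueError("initial state must be non-negative")
    if t_eval is None:
        t_eval = np.linspace(t0, t1, n_samples)
    # Resolve the forcing period for the periodic mode.
    if (
        therapy is not None
        and therapy.mode == "periodic_additive"
        and therapy.D > 0
        and therapy.omega > 0
    ):
        period = 2 * math.pi / therapy.omega
        max_step = min(max_step, period / 20.0)
    sol = _integrate(
        lambda t, s: rhs_original(t, s, params, therapy),
        (t0, t1),
        [x0, y0],
        t_eval,
        rtol,
        atol,
        method,
        max_step,
    )
    meta = {
        "rtol": rtol,
        "atol": atol,
        "method": method,
        "nfev": int(sol.nfev),
        "therapy_mode": therapy.mode if therapy is not None else None,
    }
    return Trajectory(sol.t, sol.y.T, "original", meta)


def simulate_dimensionless(
    initial_state: Sequence[float],
    dp: DimensionlessParams,
    tau_span: tuple[float, float],
    A: float = 0.0,
    omega: float = 0.0,
    periodic: bool = False,
    t_eval: Optional[np.ndarray] = None,
    n_samples: int = 500,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = "RK45",
    max_step: float = np.inf,
) -> Trajectory:
    """Simulate the dimensionless system with constant or periodic forcing.

    With ``periodic=True`` the host equation receives
    ``A*(1 - cos(omega*tau))``; otherwise the constant amplitude ``A``.
    """
    t0, t1 = tau_span
    if not t1 > t0:
        raise ValueError("tau_span must be non-degenerate")
    u0, v0 = initial_state
    if u0 < 0 or v0 < 0:
        raise ValueError("initial state must be non-negative")
    if t_eval is None:
        t_eval = np.linspace(t0, t1, n_samples)
    if periodic:
        if omega <= 0:
            raise ValueError("periodic forcing requires omega > 0")
        forcing = lambda tau: A * (1.0 - math.cos(omega * tau))  # noqa: E731
        max_step = min(max_step, 2 * math.pi / omega / 20.0)
    else:
        forcing = A
    sol = _integrate(
        lambda t, s: rhs_dimensionless(t, s, dp, forcing),
        (t0, t1),
        [u0, v0],
        t_eval,
        rtol,
        atol,
        method,
        max_step,
    )
    meta = {
        "rtol": rtol,
        "atol": atol,
        "method": method,
        "nfev": int(sol.nfev),
        "A": A,
        "omega": omega,
        "periodic": periodic,
    }
    return Trajectory(sol.t, sol.y.T, "dimensionless", meta)
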