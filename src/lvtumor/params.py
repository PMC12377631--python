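"""Parameter and state containers for the tumor-host Lotka-Volterra model.

Two interacting populations -- tumor cells ``x`` and host cells ``y`` --
each grow logistically and inhibit one another::

    dx/dt = rx * x * (1 - x/Kx) - alpha_xy * x * y
    dy/dt = ry * y * (1 - y/Ky) - alpha_yx * x * y

Rescaling time and the populations (tau = rx*t, x = Kx*u,
y = (rx*Ky/ry)*v) collapses the six kinetic parameters into the
dimensionless triple ``(c, d, f)``::

    c = Ky*alpha_xy / ry,   d = ry / rx,   f = Kx*alpha_yx / rx

which alone decides the dynamical regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "KineticParams",
    "DimensionlessParams",
    "TherapySpec",
    "THERAPY_MODES",
    "to_dimensionless",
    "from_dimensionless",
    "state_to_dimensionless",
    "state_from_dimensionless",
]


@dataclass(frozen=True)
class KineticParams:
    """Original-coordinate kinetic parameters.

    Parameters
    ----------
    rx, ry
        Intrinsic growth rates of tumor and host, per day.
    Kx, Ky
        Carrying capacities (cells, or cm^3 when fitting volumes).
    alpha_xy
        Inhibition of the tumor by the host, per day per cell.
    alpha_yx
        Inhibition of the host by the tumor, per day per cell.
    delta_xy, delta_yx
        Optional pure kill coefficients; ``alpha_xy = delta_xy + rx/Kx``
        when supplied.
    """

    rx: float
    ry: float
    Kx: float
    Ky: float
    alpha_xy: float
    alpha_yx: float
    delta_xy: Optional[float] = None
    delta_yx: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("rx", "ry", "Kx", "Ky", "alpha_xy", "alpha_yx"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.Kx <= 0 or self.Ky <= 0:
            raise ValueError("carrying capacities must be positive")

    @property
    def gamma(self) -> float:
        """Capacity ratio Ky/Kx."""
        return self.Ky / self.Kx

    def validate_strict(self) -> None:
        """Enforce the interaction lower bound alpha_xy >= rx/Kx.

        The logistic self-limitation contributes rx/Kx to the cross
        term, so any non-negative kill coefficient implies this bound.
        """
        if self.alpha_xy < self.rx / self.Kx:
            raise ValueError(
                f"alpha_xy={self.alpha_xy} violates the lower bound "
                f"rx/Kx={self.rx / self.Kx}"
            )


@dataclass(frozen=True)
class DimensionlessParams:
    """The dimensionless triple (c, d, f) driving all regime logic."""

    c: float
    d: float
    f: float

    def __post_init__(self) -> None:
        if not (self.c > 0 and self.d > 0 and self.f > 0):
            raise ValueError("c, d, f must all be positive")


THERAPY_MODES = ("proportional_constant", "additive_constant", "periodic_additive")


@dataclass(frozen=True)
class TherapySpec:
    """Specification of an external perturbation (therapy).

    ``D`` is the relative dose (applied dose over the maximum
    permissible dose, dimensionless).  The meaning of the effect
    coefficients depends on the mode:

    - ``proportional_constant``: the therapy kills ``D*beta_x*x`` tumor
      cells and ``D*beta_y*y`` host cells per day (betas are per-day
      rates).
    - ``additive_constant``: constant kill terms ``D*beta_x`` and
      ``D*beta_y`` (betas in cells/day).  Host-directed stimulation
      requires ``beta_x = 0`` and ``beta_y < 0``.
    - ``periodic_additive``: as additive but modulated by
      ``(1 - cos(omega*t))``, which is non-negative and averages to 1
      over a forcing period.
    """

    mode: str
    D: float = 0.0
    beta_x: float = 0.0
    beta_y: float = 0.0
    omega: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in THERAPY_MODES:
            raise ValueError(
                f"unknown therapy mode {self.mode!r}; expected one of {THERAPY_MODES}"
            )
        if self.D < 0:
            raise ValueError("relative dose D must be non-negative")
        if self.mode in ("additive_constant", "periodic_additive") and self.D > 0:
            if self.beta_x != 0 or self.beta_y >= 0:
                raise ValueError(
                    "host-directed additive therapy requires beta_x = 0 and beta_y < 0"
                )
        if self.mode == "periodic_additive" and self.D > 0 and self.omega <= 0:
            raise ValueError("periodic therapy requires omega > 0")


def to_dimensionless(params: KineticParams) -> DimensionlessParams:
    """Map kinetic parameters to the dimensionless triple (c, d, f)."""
    if params.rx <= 0 or params.ry <= 0:
        raise ValueError("rx and ry must be positive for nondimensionalization")
    return DimensionlessParams(
        c=params.Ky * params.alpha_xy / params.ry,
        d=params.ry / params.rx,
        f=params.Kx * params.alpha_yx / params.rx,
    )


def from_dimensionless(
    dp: DimensionlessParams, rx: float = 1.0, Kx: float = 1.0, Ky: float = 1.0
) -> KineticParams:
    """Reconstruct kinetic parameters from (c, d, f) and scale choices.

    The inverse of :func:`to_dimensionless` is underdetermined; the
    time scale ``rx`` and the capacities fix the remaining freedom.
    """
    if rx <= 0:
        raise ValueError("rx must be positive")
    ry = dp.d * rx
    return KineticParams(
        rx=rx,
        ry=ry,
        Kx=Kx,
        Ky=Ky,
        alpha_xy=dp.c * ry / Ky,
        alpha_yx=dp.f * rx / Kx,
    )


def state_to_dimensionless(
    x: float, y: float, params: KineticParams, t: float = 0.0
) -> tuple[float, float, float]:
    """Transform an original-coordinate state to (tau, u, v)."""
    if params.rx <= 0 or params.ry <= 0:
        raise ValueError("rx and ry must be positive")
    tau = params.rx * t
    u = x / params.Kx
    v = y * params.ry / (params.rx * params.Ky)
    return tau, u, v


def state_from_dimensionless(
    u: float, v: float, params: KineticParams, tau: float = 0.0
) -> tuple[float, float, float]:
    """Inverse of :func:`state_to_dimensionless`; returns (t, x, y)."""
    if params.rx <= 0 or params.ry <= 0:
        raise ValueError("rx and ry must be positive")
    t = tau / params.rx
    x = u * params.Kx
    y = v * params.rx * params.Ky / params.ry
    return t, x, y
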