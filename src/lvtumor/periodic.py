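"""Periodically forced tumor-host dynamics and stroboscopic analysis.

A host-directed dose applied as D(t) = D*(1 - cos(omega*t)) turns the
system non-autonomous.  Sampling the trajectory once per forcing
period T = 2*pi/omega (the stroboscopic, or Poincare, map) classifies
the long-run attractor: a fixed point of the map with a finite
within-period excursion is a period-1 limit cycle; when the excursion
shrinks below a floor the orbit is reported as a small-loop attractor
(the high-frequency limit); subharmonics would appear as period-k
fixed points of the k-fold map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dynamics import simulate, simulate_dimensionless, Trajectory
from .params import DimensionlessParams, KineticParams, TherapySpec

__all__ = [
    "StroboscopicResult",
    "simulate_forced",
    "stroboscopic_classify",
    "amplitude_vs_frequency",
]


@dataclass(frozen=True)
class StroboscopicResult:
    omega: float
    period: float
    strobe_points: np.ndarray  # (n_sample, 2)
    converged: bool
    detected_period: Optional[int]
    attractor_class: str  # period-1 limit cycle | period-k cycle | small-loop attractor | unresolved
    amplitude: tuple[float, float]  # max-min excursion per coordinate, final period
    transient_time: float


def simulate_forced(
    params: KineticParams,
    therapy: TherapySpec,
    initial_state: Sequence[float],
    t_span: tuple[float, float],
    **kwargs,
) -> Trajectory:
    """Simulate the periodically forced system in original coordinates."""
    if therapy.mode != "periodic_additive":
        raise ValueError("simulate_forced expects a periodic_additive therapy")
    return simulate(initial_state, params, t_span, therapy=therapy, **kwargs)


def stroboscopic_classify(
    initial_state: Sequence[float],
    *,
    params: Optional[KineticParams] = None,
    therapy: Optional[TherapySpec] = None,
    dp: Optional[DimensionlessParams] = None,
    A: float = 0.0,
    omega: Optional[float] = None,
    n_transient_periods: int = 50,
    min_transient_time: float = 0.0,
    n_sample_periods: int = 24,
    tol: float = 1e-7,
    amplitude_floor: float = 1e-3,
    max_detect_period: int = 8,
    samples_per_period: int = 64,
    rtol: float = 1e-9,
    atol: float = 1e-11,
) -> StroboscopicResult:
    """Classify the long-run attractor of the forced system.

    Accepts either original-coordinate inputs (``params`` +
    ``therapy``) or dimensionless ones (``dp``, ``A``, ``omega``).
    A transient of ``max(n_transient_periods * T, min_transient_time)``
    is discarded, then ``n_sample_periods`` strobe points are tested
    for convergence of the k-fold map, k = 1..``max_detect_period``.
    The amplitude is the max-min excursion of each coordinate over the
    final forcing period; ``amplitude_floor`` (relative to the host
    carrying capacity, or 1 in dimensionless form) separates a genuine
    limit cycle from the shrunken high-frequency attractor.
    """
    if params is not None:
        if therapy is None or therapy.omega <= 0:
            raise ValueError("original-coordinate input requires a periodic therapy")
        w = therapy.omega
        scales = (params.Kx, params.Ky)
        dimensionless = False
    else:
        if dp is None or omega is None or omega <= 0:
            raise ValueError("dimensionless input requires dp and omega > 0")
        w = omega
        scales = (1.0, 1.0)
        dimensionless = True
    scale = max(scales)
    period = 2.0 * math.pi / w

    # Transient: integrate in one sweep, keeping only the final state.
    t_transient = max(n_transient_periods * period, min_transient_time)
    # Round up to an integer number of periods so strobe phases align.
    n_trans = int(math.ceil(t_transient / period))
    state = np.asarray(initial_state, dtype=float)
    t0 = 0.0
    if n_trans > 0:
        t1 = n_trans * period
        if dimensionless:
            traj = simulate_dimensionless(state, dp, (t0, t1), A=A, omega=w,
                                          periodic=True, t_eval=np.array([t0, t1]),
                                          rtol=rtol, atol=atol)
        else:
            traj = simulate(state, params, (t0, t1), therapy=therapy,
                            t_eval=np.array([t0, t1]), rtol=rtol, atol=atol)
        state = traj.final_state
        t0 = t1

    # Sampling window with dense output for strobe points and amplitude.
    t_eval = t0 + np.linspace(0.0, n_sample_periods * period,
                              n_sample_periods * samples_per_period + 1)
    if dimensionless:
        traj = simulate_dimensionless(state, dp, (t0, t_eval[-1]), A=A, omega=w,
                                      periodic=True, t_eval=t_eval,
                                      rtol=rtol, atol=atol)
    else:
        traj = simulate(state, params, (t0, t_eval[-1]), therapy=therapy,
                        t_eval=t_eval, rtol=rtol, atol=atol)
    strobe = traj.states[::samples_per_period]  # n_sample_periods + 1 points

    # Detect the smallest k with converged k-fold strobe map.
    detected = None
    for k in range(1, max_detect_period + 1):
        pts = strobe[::k]
        if len(pts) < 3:
            break
        tail = pts[-3:]
        gaps = np.linalg.norm(np.diff(tail, axis=0), axis=1)
        if np.all(gaps < tol * max(1.0, scale)):
            detected = k
            break
    converged = detected is not None

    last_period = traj.states[-(samples_per_period + 1):]
    amp = tuple(np.max(last_period, axis=0) - np.min(last_period, axis=0))

    rel_amp = max(amp[0] / scales[0], amp[1] / scales[1])
    if not converged:
        klass = "unresolved"
    elif detected > 1:
        klass = f"period-{detected} cycle"
    elif rel_amp >= amplitude_floor:
        klass = "period-1 limit cycle"
    else:
        klass = "small-loop attractor"

    return StroboscopicResult(
        omega=w,
        period=period,
        strobe_points=strobe,
        converged=converged,
        detected_period=detected,
        attractor_class=klass,
        amplitude=(float(amp[0]), float(amp[1])),
        transient_time=n_trans * period,
    )


def amplitude_vs_frequency(
    initial_state: Sequence[float],
    omegas: Sequence[float],
    *,
    params: Optional[KineticParams] = None,
    D: float = 0.0,
    beta_y: float = 0.0,
    dp: Optional[DimensionlessParams] = None,
    A: float = 0.0,
    **kwargs,
) -> pd.DataFrame:
    """One stroboscopic summary per forcing frequency.

    Returns a DataFrame with columns (omega, attractor_class,
    amplitude_x, amplitude_y, converged), omegas taken in increasing
    order.
    """
    omegas = np.asarray(omegas, dtype=float)
    if np.any(omegas <= 0) or np.any(np.diff(omegas) <= 0):
        raise ValueError("omega grid must be positive and strictly increasing")
    rows = []
    for w in omegas:
        if params is not None:
            therapy = TherapySpec(mode="periodic_additive", D=D, beta_x=0.0,
                                  beta_y=beta_y, omega=float(w))
            res = stroboscopic_classify(initial_state, params=params,
                                        therapy=therapy, **kwargs)
        else:
            res = stroboscopic_classify(initial_state, dp=dp, A=A,
                                        omega=float(w), **kwargs)
        rows.append(
            {
                "omega": float(w),
                "attractor_class": res.attractor_class,
                "amplitude_x": res.amplitude[0],
                "amplitude_y": res.amplitude[1],
                "converged": res.converged,
            }
        )
    return pd.DataFrame(rows)
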