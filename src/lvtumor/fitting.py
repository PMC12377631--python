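"""Least-squares fit of the tumor component to volume time series.

Tumor volume V(t) stands in for the tumor population x(t); only x is
observed (the host trajectory y(t) is latent), so the objective is

    RSS(theta) = sum_i ( x(t_i; theta) - V_i )^2

over theta = (rx, ry, alpha_xy, alpha_yx, Kx, Ky, x0, y0), minimized
with bounded trust-region least squares from multiple starting points
(one data-driven start plus Latin-hypercube draws).  Because several
parameter combinations produce nearly identical tumor curves (e.g.
alpha_xy close to rx/Kx makes the host term mimic self-limitation),
recovery is assessed at the curve level; a rank-deficiency flag marks
non-identifiable fits.  Fitted curves are compared with the symmetric
Hausdorff distance on (t, V) points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares
from scipy.spatial.distance import directed_hausdorff
from scipy.stats import qmc

from .params import KineticParams

__all__ = [
    "VolumeSeries",
    "FitResult",
    "DEFAULT_BOUNDS",
    "predict_volume",
    "fit_lv",
    "hausdorff_distance",
    "goodness_report",
]


@dataclass(frozen=True)
class VolumeSeries:
    """Tumor volumes (cm^3) against time (days)."""

    times: np.ndarray
    volumes: np.ndarray
    weights: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.volumes, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "volumes", v)
        if t.shape != v.shape:
            raise ValueError("times and volumes must have the same length")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(v <= 0):
            raise ValueError("volumes must be positive")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            object.__setattr__(self, "weights", w)
            if w.shape != t.shape:
                raise ValueError("weights must match times in length")


@dataclass(frozen=True)
class FitResult:
    params: KineticParams
    x0: float
    y0: float
    rss: float
    converged: bool
    n_starts: int
    rank_deficient: bool
    start_rss: tuple[float, ...] = ()

    @property
    def theta(self) -> np.ndarray:
        p = self.params
        return np.array(
            [p.rx, p.ry, p.alpha_xy, p.alpha_yx, p.Kx, p.Ky, self.x0, self.y0]
        )


# (rx, ry, alpha_xy, alpha_yx, Kx, Ky, x0, y0)
DEFAULT_BOUNDS = (
    np.array([1e-3, 1e-3, 0.0, 0.0, 0.1, 0.1, 1e-3, 0.0]),
    np.array([20.0, 20.0, 20.0, 20.0, 20.0, 20.0, 20.0, 20.0]),
)

_THETA_NAMES = ("rx", "ry", "alpha_xy", "alpha_yx", "Kx", "Ky", "x0", "y0")


def predict_volume(
    theta: Sequence[float], times: np.ndarray, rtol: float = 1e-7, atol: float = 1e-9
) -> np.ndarray:
    """Tumor component x(t; theta) at the requested times (t >= 0)."""
    rx, ry, axy, ayx, Kx, Ky, x0, y0 = theta
    times = np.asarray(times, dtype=float)

    def rhs(t, s):
        x, y = s
        return [
            rx * x * (1.0 - x / Kx) - axy * x * y,
            ry * y * (1.0 - y / Ky) - ayx * x * y,
        ]

    t0 = min(0.0, times[0])
    sol = solve_ivp(
        rhs,
        (t0, times[-1]),
        [x0, y0],
        t_eval=times,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success or sol.y.shape[1] != len(times):
        return np.full(len(times), 1e6)
    return sol.y[0]


def _logistic_stage(series: VolumeSeries) -> tuple[float, float, float]:
    """Stage-1 fit of a closed-form logistic to seed the full model.

    The logistic is the host-free limit of the model, so its (K, r,
    x0) land in or near the valley that contains the full-model
    optimum even when host competition shapes the curve.
    """
    t, v = series.times, series.volumes

    def curve(p):
        K, r, x0 = p
        return K / (1.0 + (K / x0 - 1.0) * np.exp(-r * t))

    # The growth-rate axis has its own local minima (fast risers look
    # flat from a slow start), so the cheap stage is itself
    # multi-started over decades of r.
    best = None
    for r0 in (0.1, 0.3, 1.0, 3.0, 10.0):
        sol = least_squares(
            lambda p: curve(p) - v,
            [1.2 * float(np.max(v)), r0, float(v[0])],
            bounds=([1e-2, 1e-3, 1e-3], [50.0, 50.0, 50.0]),
        )
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0]:
            best = (rss, sol.x)
    return tuple(best[1])


def _data_driven_starts(series: VolumeSeries, lo, hi) -> list[np.ndarray]:
    """Logistic-seeded starts: host-inert and host-active variants."""
    K_l, r_l, x0_l = _logistic_stage(series)
    vmax = float(np.max(series.volumes))
    starts = [
        # Host nearly inert: the logistic parameters carry over.
        np.array([r_l, 0.5, 1e-3, 1e-3, K_l, 1.0, x0_l, 0.1]),
        # Host absorbs half the apparent self-limitation.
        np.array([2 * r_l, r_l, r_l / 2, r_l / 2, 2 * K_l, 2.0, x0_l, 1.0]),
        # Strongly coupled host of comparable size.
        np.array([r_l, r_l, 0.1, 0.1, 1.2 * vmax, 1.2 * vmax,
                  float(series.volumes[0]), vmax]),
    ]
    return [np.clip(s, lo, hi) for s in starts]


def fit_lv(
    series: VolumeSeries,
    bounds: Optional[tuple[np.ndarray, np.ndarray]] = None,
    n_starts: int = 8,
    seed: int = 0,
    rss_stop: float = 1e-12,
    rtol: float = 1e-7,
) -> FitResult:
    """Fit the LV tumor component to a volume series.

    Deterministic for fixed seed.  ``n_starts`` counts the two
    logistic-seeded starts plus Latin-hypercube draws; iteration stops
    early once a start reaches ``rss_stop`` (relative to the data
    scale).
    """
    if len(series.times) < 8:
        raise ValueError("need at least 8 data points for the 8 free parameters")
    lo, hi = bounds if bounds is not None else DEFAULT_BOUNDS
    w = series.weights if series.weights is not None else np.ones_like(series.volumes)
    sw = np.sqrt(w)

    def residuals(theta):
        return sw * (predict_volume(theta, series.times, rtol=rtol) - series.volumes)

    starts = _data_driven_starts(series, lo, hi)[:n_starts]
    if n_starts > len(starts):
        sampler = qmc.LatinHypercube(d=8, seed=seed)
        unit = sampler.random(n_starts - len(starts))
        # Sample rates/interactions on a log-ish scale via squaring to
        # favor the lower decades of the wide default boxes.
        starts.extend(lo + (hi - lo) * unit**2)

    def solve(theta0, diff_step=None):
        kwargs = {"diff_step": diff_step} if diff_step is not None else {}
        sol = least_squares(
            residuals,
            theta0,
            bounds=(lo, hi),
            method="trf",
            x_scale="jac",
            ftol=1e-12,
            xtol=1e-12,
            gtol=1e-12,
            max_nfev=400,
            **kwargs,
        )
        return float(np.sum(sol.fun**2)), sol

    scale = float(np.sum(series.volumes**2))
    best = None
    start_rss = []
    for theta0 in starts:
        try:
            rss, sol = solve(theta0)
        except Exception:
            start_rss.append(float("inf"))
            continue
        start_rss.append(rss)
        if best is None or rss < best[0]:
            best = (rss, sol)
        if rss < rss_stop * scale:
            break
    if best is None:
        raise RuntimeError("all optimizer starts failed")
    # Polish the winner with a coarser FD step, which can descend
    # further when ODE-solver noise limits the default-step Jacobian.
    if best[0] > rss_stop * scale:
        try:
            rss_p, sol_p = solve(best[1].x, diff_step=1e-5)
            if rss_p < best[0]:
                best = (rss_p, sol_p)
        except Exception:
            pass
    rss, sol = best
    theta = sol.x
    # Identifiability: singular values of the final Jacobian.
    sv = np.linalg.svd(sol.jac, compute_uv=False)
    # The cutoff sits above the ODE-solver noise in the FD Jacobian;
    # directions this much weaker than the leading one are not
    # informed by the data.
    rank_deficient = bool(sv[0] <= 0 or sv[-1] / sv[0] < 1e-5)
    params = KineticParams(
        rx=theta[0], ry=theta[1], alpha_xy=theta[2], alpha_yx=theta[3],
        Kx=theta[4], Ky=theta[5],
    )
    return FitResult(
        params=params,
        x0=float(theta[6]),
        y0=float(theta[7]),
        rss=rss,
        converged=bool(sol.status > 0),
        n_starts=len(start_rss),
        rank_deficient=rank_deficient,
        start_rss=tuple(start_rss),
    )


def hausdorff_distance(curve_a: np.ndarray, curve_b: np.ndarray) -> float:
    """Symmetric Hausdorff distance between two sampled curves.

    Both inputs are (n, 2) arrays of (t, V) points in natural units.
    """
    a = np.atleast_2d(np.asarray(curve_a, dtype=float))
    b = np.atleast_2d(np.asarray(curve_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("curves must be non-empty")
    return max(directed_hausdorff(a, b)[0], directed_hausdorff(b, a)[0])


def goodness_report(series: VolumeSeries, fit: FitResult, n_dense: int = 200):
    """Residual table and a dense fitted curve for plotting.

    Returns (table, curve): the table has per-point predictions and
    residuals, the curve is an (n_dense, 2) array of (t, V) samples
    spanning the data window.
    """
    pred = predict_volume(fit.theta, series.times)
    table = pd.DataFrame(
        {
            "t": series.times,
            "V": series.volumes,
            "V_fit": pred,
            "residual": pred - series.volumes,
        }
    )
    t_dense = np.linspace(series.times[0], series.times[-1], n_dense)
    curve = np.column_stack([t_dense, predict_volume(fit.theta, t_dense)])
    return table, curve
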