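"""Synthetic inputs: reference parameter sets and generated data.

The experimental inputs the analysis would normally consume (Ehrlich
tumor volumes in BALB/c mice: logistic-like growth from about 0.5 cm^3
toward a 2-3 cm^3 plateau over roughly 30 days) are not redistributed;
this module emulates them.  Volume series are simulated from a chosen
kinetic set and corrupted with multiplicative log-normal noise, whose
standard deviation sigma is the per-point coefficient of variation --
measurement error on tumor volumes scales with size.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .additive import bifurcation_amplitudes
from .dynamics import simulate
from .fitting import VolumeSeries
from .params import DimensionlessParams, KineticParams, from_dimensionless, to_dimensionless
from .stability import Regime, classify_regime

__all__ = ["SyntheticSpec", "fixtures", "generate_volume_series", "generate_scenario_suite"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a noisy synthetic tumor-volume series."""

    params: KineticParams
    x0: float
    y0: float
    times: np.ndarray = field(
        default_factory=lambda: np.linspace(0.0, 30.0, 12)
    )
    sigma: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.x0 <= 0 or self.y0 < 0:
            raise ValueError("x0 must be positive and y0 non-negative")


def fixtures() -> dict:
    """Named reference parameter sets used throughout the analyses.

    ``regime1`` .. ``regime4`` are the benchmark kinetic sets for the
    four natural regimes (regime3's printed kinetics are internally
    inconsistent with its dimensionless triple; the triple in
    ``dimensionless`` is the authoritative one and the flag records
    the discrepancy).  ``regime4_forced`` is the host-forced
    aggressive-tumor scenario, ``lce_local_max`` the five-parameter point
    where the Lyapunov search peaks, and ``fitted_ehrlich`` the LV
    octet fitted to Ehrlich tumor volumes.
    """
    fx = {
        "regime1": {
            "kinetics": KineticParams(rx=0.1, ry=0.075, Kx=1.0, Ky=1.0,
                                      alpha_xy=0.1237, alpha_yx=0.045),
            "regime": "I",
        },
        "regime2": {
            "kinetics": KineticParams(rx=0.1, ry=0.09, Kx=1.0, Ky=1.0,
                                      alpha_xy=0.09, alpha_yx=0.0788),
            "regime": "II",
        },
        "regime3": {
            "kinetics": KineticParams(rx=0.1, ry=0.065, Kx=1.0, Ky=1.0,
                                      alpha_xy=0.0247, alpha_yx=0.069),
            "dimensionless": DimensionlessParams(c=1.65, d=0.65, f=0.69),
            "regime": "III",
            # The stated kinetics give c = 0.38, not the 1.65 of the
            # dimensionless triple; analyses use the triple directly.
            "kinetics_inconsistent": True,
        },
        "regime4": {
            "kinetics": KineticParams(rx=0.1, ry=0.066, Kx=1.0, Ky=1.0,
                                      alpha_xy=0.066, alpha_yx=0.07),
            "regime": "IV",
        },
        "regime4_forced": {
            "kinetics": KineticParams(rx=0.1, ry=0.066, Kx=1.0, Ky=1.0,
                                      alpha_xy=0.066, alpha_yx=0.11),
            "regime": "IV",
            "beta_y": -1.0 / 40.0,
            "D": 1.0,
            "omega": 1.0 / 14.0,
        },
        "lce_local_max": {
            "c": 0.933816, "d": 0.999086, "f": 1.27836,
            "A": 0.100613, "omega": 0.496117,
        },
        "fitted_ehrlich": {
            "kinetics": KineticParams(rx=4.83671566, ry=6.36103209,
                                      Kx=3.21508273, Ky=2.78479322,
                                      alpha_xy=1.52999021, alpha_yx=1.97864993),
            "x0": 0.46733650,
            "y0": 2.38718513,
        },
    }
    for name in ("regime1", "regime2", "regime4", "regime4_forced"):
        fx[name]["dimensionless"] = to_dimensionless(fx[name]["kinetics"])
    return copy.deepcopy(fx)


def generate_volume_series(spec: SyntheticSpec) -> VolumeSeries:
    """Simulate x(t), sample it, and apply multiplicative noise.

    With sigma = 0 the series is the exact model curve at the sample
    times; fixed seeds reproduce the noise exactly.
    """
    traj = simulate(
        (spec.x0, spec.y0),
        spec.params,
        (min(0.0, spec.times[0]), float(spec.times[-1])),
        t_eval=np.asarray(spec.times, dtype=float),
    )
    clean = traj.states[:, 0]
    if spec.sigma == 0:
        volumes = clean
    else:
        rng = np.random.default_rng(spec.seed)
        volumes = clean * np.exp(spec.sigma * rng.standard_normal(len(clean)))
    return VolumeSeries(times=np.asarray(spec.times, dtype=float), volumes=volumes)


_REGIME_TESTS = {
    "I": lambda c, d, f: c * d > 1 and f < d,
    "II": lambda c, d, f: c * d < 1 and f < d and c * f < 1,
    "III": lambda c, d, f: c * d > 1 and f > d and c * f > 1,
    "IV": lambda c, d, f: c * d < 1 and f > d,
}


def generate_scenario_suite(seed: int = 0, n_per_regime: int = 5) -> list[dict]:
    """Random regime-labelled parameter sets with therapy draws.

    Rejection-samples (c, d, f) from a broad box until ``n_per_regime``
    sets satisfy each regime's condition; for Regime IV both c*f
    subcases are covered (alternating draws).  Each scenario bundles
    an original-coordinate kinetic realization (rx = 0.1/day, unit
    capacities), an effective and an ineffective proportional-therapy
    coefficient pair, and a host-directed additive coefficient.
    """
    if n_per_regime < 1:
        raise ValueError("n_per_regime must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for regime, test in _REGIME_TESTS.items():
        count = 0
        want_cf_above = True  # alternate the Regime-IV subcase
        while count < n_per_regime:
            c = rng.uniform(0.2, 2.5)
            d = rng.uniform(0.3, 1.5)
            f = rng.uniform(0.2, 2.0)
            if not test(c, d, f):
                continue
            if regime == "IV" and n_per_regime >= 2:
                if (c * f > 1) != want_cf_above:
                    continue
                want_cf_above = not want_cf_above
            dp = DimensionlessParams(c=c, d=d, f=f)
            params = from_dimensionless(dp, rx=0.1, Kx=1.0, Ky=1.0)
            # Effective proportional therapy: ry*beta_x - rx*beta_y > 0.
            beta_x = rng.uniform(0.02, 0.2)
            beta_y = rng.uniform(0.0, 0.9) * params.ry * beta_x / params.rx
            # Ineffective pair reverses the inequality.
            beta_x_bad = rng.uniform(0.001, 0.02)
            beta_y_bad = params.ry * beta_x_bad / params.rx * rng.uniform(1.1, 3.0)
            out.append(
                {
                    "regime": regime,
                    "dimensionless": dp,
                    "kinetics": params,
                    "beta_x": float(beta_x),
                    "beta_y": float(beta_y),
                    "beta_x_ineffective": float(beta_x_bad),
                    "beta_y_ineffective": float(beta_y_bad),
                    "beta_y_additive": float(-rng.uniform(0.005, 0.1)),
                }
            )
            count += 1
    return out
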