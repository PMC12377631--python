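"""Continuous therapy with proportional effect.

A constant dose D removing D*beta_x*x tumor cells and D*beta_y*y host
cells per day rescales the growth rates to rx - D*beta_x and
ry - D*beta_y while leaving c and f unchanged; only

    d*(D) = (ry - D*beta_y) / (rx - D*beta_x)

moves.  The therapy is effective (d* increasing in D) iff
ry*beta_x - rx*beta_y > 0.  Crossing the doses

    D1 = ry (rx - Ky*alpha_xy) / (ry*beta_x - beta_y*Ky*alpha_xy)
    D2 = rx (Kx*alpha_yx - ry) / (beta_x*Kx*alpha_yx - rx*beta_y)

flips the regime conditions c*d* > 1 and d* > f respectively, which is
how a patient in Regime II/III/IV can be steered toward tumor
elimination (Regime I).  Doses above rx/beta_x (ry/beta_y) drive the
tumor (host) extinct outright.
"""

from __future__ import annotations

from dataclasses import dataclass

from .params import DimensionlessParams, KineticParams, to_dimensionless
from .stability import Regime, classify_regime

__all__ = [
    "EffectivenessError",
    "ExtinctionRegimeError",
    "ProportionalPlan",
    "effective_params",
    "dose_thresholds",
    "plan_outcome",
]


class EffectivenessError(ValueError):
    """Therapy cannot raise d*: ry*beta_x - rx*beta_y <= 0."""


class ExtinctionRegimeError(ValueError):
    """Dose exceeds an extinction threshold; d* is undefined."""


@dataclass(frozen=True)
class ProportionalPlan:
    baseline: Regime
    effective: bool
    D1: float
    D2: float
    # Raw threshold values can be negative when the corresponding
    # condition already holds at D=0; flags record the clamping.
    D1_always_satisfied: bool
    D2_always_satisfied: bool
    extinction_dose_tumor: float
    extinction_dose_host: float
    outcome: str
    relapse_on_withdrawal: bool


def effective_params(
    params: KineticParams, D: float, beta_x: float, beta_y: float
) -> DimensionlessParams:
    """Dimensionless triple (c, d*, f) of the dose-rescaled system."""
    rx_eff = params.rx - D * beta_x
    ry_eff = params.ry - D * beta_y
    if rx_eff <= 0 or ry_eff <= 0:
        raise ExtinctionRegimeError(
            "dose exceeds an extinction threshold "
            f"(rx-D*beta_x={rx_eff}, ry-D*beta_y={ry_eff})"
        )
    base = to_dimensionless(params)
    return DimensionlessParams(c=base.c, d=ry_eff / rx_eff, f=base.f)


def dose_thresholds(
    params: KineticParams, beta_x: float, beta_y: float
) -> tuple[float, float]:
    """Raw regime-flip doses (D1, D2); negative means already satisfied.

    Requires an effective therapy (ry*beta_x - rx*beta_y > 0), which
    makes both denominators positive whenever the corresponding
    baseline condition can be flipped.
    """
    if params.ry * beta_x - params.rx * beta_y <= 0:
        raise EffectivenessError(
            "therapy is ineffective: ry*beta_x - rx*beta_y must be positive"
        )
    D1 = (
        params.ry
        * (params.rx - params.Ky * params.alpha_xy)
        / (params.ry * beta_x - beta_y * params.Ky * params.alpha_xy)
    )
    D2 = (
        params.rx
        * (params.Kx * params.alpha_yx - params.ry)
        / (beta_x * params.Kx * params.alpha_yx - params.rx * beta_y)
    )
    return D1, D2


def plan_outcome(
    params: KineticParams,
    beta_x: float,
    beta_y: float,
    D: float,
    boundary_tol: float = 1e-12,
) -> ProportionalPlan:
    """Predict the regime reached under proportional therapy at dose D.

    Implements the per-regime decision lists; doses landing exactly on
    a threshold (within ``boundary_tol``) report DEGENERATE.  The
    relapse flag records that the system returns to its baseline
    regime when therapy is withdrawn (unless the tumor has been driven
    below any practical detection floor).
    """
    baseline = classify_regime(to_dimensionless(params))
    effective = params.ry * beta_x - params.rx * beta_y > 0
    ext_x = params.rx / beta_x if beta_x > 0 else float("inf")
    ext_y = params.ry / beta_y if beta_y > 0 else float("inf")

    if effective:
        D1, D2 = dose_thresholds(params, beta_x, beta_y)
    else:
        D1 = D2 = float("nan")

    def finish(outcome: str, relapse: bool = True) -> ProportionalPlan:
        return ProportionalPlan(
            baseline=baseline,
            effective=effective,
            D1=D1,
            D2=D2,
            D1_always_satisfied=bool(effective and D1 <= 0),
            D2_always_satisfied=bool(effective and D2 <= 0),
            extinction_dose_tumor=ext_x,
            extinction_dose_host=ext_y,
            outcome=outcome,
            relapse_on_withdrawal=relapse,
        )

    if D == 0 or baseline is Regime.I:
        return finish(baseline.value, relapse=False)
    if D >= max(ext_x, ext_y):
        return finish("extinct_both", relapse=False)
    if D >= ext_x:
        # Tumor growth rate driven non-positive: x strictly decreasing.
        return finish("I", relapse=False)
    if D >= ext_y:
        return finish("host_extinct", relapse=False)
    if not effective:
        return finish(baseline.value)

    near = lambda a, b: abs(a - b) <= boundary_tol * max(1.0, abs(b))  # noqa: E731
    if near(D, D1) or near(D, D2):
        return finish("DEGENERATE")

    cf = to_dimensionless(params).c * to_dimensionless(params).f
    if baseline is Regime.IV:
        if D > max(D1, D2):
            return finish("I")
        if cf < 1 and D1 > D > D2:
            return finish("II")
        if cf > 1 and D2 > D > D1:
            return finish("III")
        if D < min(D1, D2):
            return finish("IV")
        return finish("DEGENERATE")
    if baseline is Regime.III:
        return finish("I" if D > D2 else "III")
    if baseline is Regime.II:
        return finish("I" if D > D1 else "II")
    return finish("DEGENERATE")
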