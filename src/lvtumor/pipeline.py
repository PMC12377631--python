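"""Config-driven pipeline: run stages in order, write a manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np

from . import __version__
from .additive import bifurcation_amplitudes, dose_thresholds_additive, forcing_amplitude, plan_outcome_additive
from .dynamics import simulate
from .fitting import fit_lv
from .io import read_volume_series, to_jsonable, write_json, write_trajectory
from .lyapunov import LyapunovSettings, lyapunov_spectrum
from .params import DimensionlessParams, KineticParams, TherapySpec, to_dimensionless
from .periodic import amplitude_vs_frequency
from .proportional import plan_outcome
from .stability import classify_regime, dulac_certificate, equilibria

logger = logging.getLogger("lvtumor")

STAGES = ("classify", "plan-dose", "simulate", "periodic-scan", "lyapunov", "fit")


def _kinetics_from_config(block: dict) -> KineticParams:
    return KineticParams(**{k: float(v) for k, v in block.items()})


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: dict, outdir) -> dict:
    """Execute the requested stages and return the run manifest.

    ``config`` blocks: ``stages`` (list), ``kinetics`` or
    ``dimensionless``, ``therapy``, ``simulation``, ``lyapunov``,
    ``fit`` (with ``input`` path), ``seed``.  Per-stage JSON artifacts
    are written under ``outdir``; failures are recorded in the
    manifest and re-raised by the CLI as a nonzero exit.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", [])
    seed = int(config.get("seed", 0))

    if "kinetics" in config:
        params = _kinetics_from_config(config["kinetics"])
        dp = to_dimensionless(params)
    else:
        params = None
        dp = (
            DimensionlessParams(**config["dimensionless"])
            if "dimensionless" in config
            else None
        )

    manifest = {
        "version": __version__,
        "seed": seed,
        "stages": list(stages),
        "artifacts": {},
        "failures": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    for stage in stages:
        try:
            artifact = outdir / f"{stage.replace('-', '_')}.json"
            if stage == "classify":
                result = {
                    "regime": classify_regime(dp).value,
                    "equilibria": equilibria(dp),
                    "dulac": dulac_certificate(dp),
                }
                write_json(result, artifact)
            elif stage == "plan-dose":
                th = config.get("therapy", {})
                mode = th.get("mode", "proportional_constant")
                D = float(th.get("D", 0.0))
                if mode == "proportional_constant":
                    plan = plan_outcome(params, float(th["beta_x"]), float(th["beta_y"]), D)
                    result = to_jsonable(plan)
                    result["baseline"] = plan.baseline.value
                else:
                    beta_y = float(th["beta_y"])
                    A = forcing_amplitude(D, beta_y, params)
                    amps = bifurcation_amplitudes(dp)
                    D1, D2 = dose_thresholds_additive(params, beta_y)
                    result = {
                        "A": A,
                        "A1": amps.A1,
                        "A2": amps.A2,
                        "D1": D1,
                        "D2": D2,
                        "outcome": plan_outcome_additive(dp, A),
                    }
                write_json(result, artifact)
            elif stage == "simulate":
                sim = config.get("simulation", {})
                therapy = (
                    TherapySpec(**config["therapy"]) if "therapy" in config else None
                )
                traj = simulate(
                    tuple(sim.get("initial_state", (0.5, 0.5))),
                    params,
                    (0.0, float(sim.get("t_end", 600.0))),
                    therapy=therapy,
                    n_samples=int(sim.get("n_samples", 500)),
                    rtol=float(sim.get("rtol", 1e-8)),
                    atol=float(sim.get("atol", 1e-10)),
                )
                artifact = outdir / "trajectory.csv"
                write_trajectory(traj, artifact)
            elif stage == "periodic-scan":
                th = config["therapy"]
                scan = config.get("periodic_scan", {})
                table = amplitude_vs_frequency(
                    tuple(scan.get("initial_state", (0.5, 0.5))),
                    scan.get("omegas", [0.1, 1.0, 10.0]),
                    params=params,
                    D=float(th.get("D", 1.0)),
                    beta_y=float(th["beta_y"]),
                    **scan.get("options", {}),
                )
                artifact = outdir / "periodic_scan.csv"
                table.to_csv(artifact, index=False)
            elif stage == "lyapunov":
                ly = config.get("lyapunov", {})
                settings = LyapunovSettings(
                    tau_renorm=float(ly.get("tau_renorm", 0.1)),
                    h=float(ly.get("h", 0.02)),
                    n_steps=int(ly.get("n_steps", 10000)),
                )
                res = lyapunov_spectrum(
                    dp, float(ly.get("A", 0.0)), float(ly.get("omega", 1.0)), settings
                )
                result = {
                    "spectrum": list(res.spectrum),
                    "max_exponent": res.max_exponent,
                    "converged": res.converged,
                    "params": res.params,
                }
                write_json(result, artifact)
            elif stage == "fit":
                fit_cfg = config["fit"]
                inp = Path(fit_cfg["input"])
                series = read_volume_series(inp)
                fit = fit_lv(
                    series,
                    n_starts=int(fit_cfg.get("n_starts", 8)),
                    seed=seed,
                )
                result = to_jsonable(fit)
                result["input_digest"] = _digest(inp)
                write_json(result, artifact)
            else:
                raise ValueError(f"unknown stage {stage!r}")
            manifest["artifacts"][stage] = str(artifact)
            logger.info("stage %s -> %s", stage, artifact)
        except Exception as exc:  # recorded, surfaced by the caller
            manifest["failures"][stage] = f"{type(exc).__name__}: {exc}"
            logger.error("stage %s failed: %s", stage, exc)

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    write_json(manifest, outdir / "manifest.json")
    return manifest
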