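"""Readers and writers shared by all stages.

Formats are deliberately plain: delimited text for series and
trajectories (``t,V`` / ``t,x,y`` / ``tau,u,v``), JSON for structured
results, YAML or JSON for run configuration.  Floats are serialized at
full precision (repr round-trip).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .dynamics import Trajectory
from .fitting import VolumeSeries

__all__ = [
    "read_volume_series",
    "write_volume_series",
    "write_trajectory",
    "write_json",
    "read_config",
    "to_jsonable",
]


class ParseError(ValueError):
    """Malformed input row; carries the 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def read_volume_series(path) -> VolumeSeries:
    """Read two-column ``t,V`` delimited text, header auto-detected.

    Accepts comma, tab or whitespace delimiters and dot-decimal
    numbers only.
    """
    path = Path(path)
    times, volumes = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p for chunk in line.split(",") for p in chunk.split()]
            parts = [p for p in parts if p]
            if len(parts) < 2:
                raise ParseError(f"expected two columns, got {line!r}", lineno)
            try:
                t, v = float(parts[0]), float(parts[1])
            except ValueError:
                if not times:  # header row
                    continue
                raise ParseError(f"could not parse {line!r}", lineno) from None
            times.append(t)
            volumes.append(v)
    if not times:
        raise ValueError(f"no data rows in {path}")
    return VolumeSeries(times=np.array(times), volumes=np.array(volumes))


def write_volume_series(series: VolumeSeries, path) -> None:
    pd.DataFrame({"t": series.times, "V": series.volumes}).to_csv(path, index=False)


def write_trajectory(traj: Trajectory, path, sidecar: bool = True) -> None:
    """Write a trajectory as delimited text plus a JSON metadata sidecar."""
    path = Path(path)
    cols = ("t", "x", "y") if traj.coordinates == "original" else ("tau", "u", "v")
    df = pd.DataFrame(
        {cols[0]: traj.times, cols[1]: traj.states[:, 0], cols[2]: traj.states[:, 1]}
    )
    df.to_csv(path, index=False)
    if sidecar:
        write_json(
            {"coordinates": traj.coordinates, **traj.metadata},
            path.with_suffix(path.suffix + ".json"),
        )


def to_jsonable(obj: Any) -> Any:
    """Recursively convert package objects to JSON-serializable form."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(v) for v in obj]
    if isinstance(obj, complex):
        return {"re": obj.real, "im": obj.imag}
    if isinstance(obj, np.ndarray):
        return to_jsonable(obj.tolist())
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if hasattr(obj, "value") and obj.__class__.__module__.endswith("stability"):
        return obj.value  # Regime enum
    return obj


def write_json(obj: Any, path) -> None:
    with open(path, "w") as fh:
        json.dump(to_jsonable(obj), fh, indent=2)
        fh.write("\n")


def read_config(path) -> dict:
    """Read a YAML or JSON run configuration."""
    path = Path(path)
    with open(path) as fh:
        if path.suffix.lower() == ".json":
            return json.load(fh)
        return yaml.safe_load(fh)
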