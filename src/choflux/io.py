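"""CSV/YAML readers and writers plus run manifests."""

from __future__ import annotations

import hashlib
import json
import platform
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .measurements import MeasurementSet

__all__ = [
    "SchemaError",
    "read_measurements",
    "write_measurements",
    "read_viability",
    "write_table",
    "trajectory_frame",
    "write_manifest",
]


class SchemaError(ValueError):
    pass


_MEAS_REQUIRED = ["culture", "output", "time_h", "value", "sd"]


def read_measurements(path, viability_path=None) -> MeasurementSet:
    """Read a measurement CSV (culture, output, time_h, value, sd[, censored])."""
    df = pd.read_csv(path)
    missing = [c for c in _MEAS_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    via = read_viability(viability_path) if viability_path else None
    return MeasurementSet(records=df, viability=via)


def read_viability(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("culture", "time_h", "viability_pct") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    return df


def write_measurements(path, measurements: MeasurementSet, viability_path=None):
    measurements.records.to_csv(path, index=False)
    if viability_path and measurements.viability is not None:
        measurements.viability.to_csv(viability_path, index=False)


def write_table(path, table: pd.DataFrame):
    table.to_csv(path, index=False)


def trajectory_frame(trajectory) -> pd.DataFrame:
    """Tidy (time, variable, value) frame of states and fluxes."""
    rows = []
    for name in trajectory.species:
        series = trajectory.state_series(name)
        rows.append(pd.DataFrame(
            {"time_h": trajectory.times, "variable": name, "value": series}
        ))
    for rid in trajectory.reaction_ids:
        rows.append(pd.DataFrame(
            {"time_h": trajectory.times, "variable": rid,
             "value": trajectory.flux_series(rid)}
        ))
    return pd.concat(rows, ignore_index=True)


def _file_hash(path):
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, seed, inputs=(), extra=None):
    """Record seed, input hashes and versions so reruns are auditable."""
    import choflux

    manifest = {
        "seed": seed,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "python": platform.python_version(),
        "choflux": choflux.__version__,
        "numpy": np.__version__,
        "inputs": {str(p): _file_hash(p) for p in inputs if Path(p).exists()},
    }
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
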