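"""Observed culture outputs with per-point standard deviations."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["MeasurementSet"]

RECORD_COLUMNS = ["culture", "output", "time_h", "value", "sd", "censored"]


@dataclass
class MeasurementSet:
    """Tidy measurement records plus per-culture viability series.

    ``records`` columns: culture, output, time_h, value, sd, censored.
    ``viability`` columns: culture, time_h, viability_pct. Censored
    (below-detection-limit) records are retained but excluded from
    residuals by default.
    """

    records: pd.DataFrame
    viability: pd.DataFrame | None = None

    def __post_init__(self):
        df = self.records.copy()
        if "censored" not in df.columns:
            df["censored"] = False
        missing = [c for c in RECORD_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"measurement table missing columns: {missing}")
        df = df[RECORD_COLUMNS]
        usable = df[~df["censored"]]
        if (usable["sd"] <= 0).any():
            raise ValueError("all uncensored records must have sd > 0")
        if (df["time_h"] < 0).any():
            raise ValueError("negative measurement times")
        self.records = df.reset_index(drop=True)

    def __len__(self):
        return len(self.records)

    @property
    def cultures(self):
        return list(self.records["culture"].unique())

    def usable(self) -> pd.DataFrame:
        """Records that enter residuals (censored points dropped)."""
        return self.records[~self.records["censored"]]

    def for_culture(self, culture) -> pd.DataFrame:
        return self.records[self.records["culture"] == culture]

    def viability_cutoff(self, culture, threshold=95.0) -> float:
        """First time at which viability drops below ``threshold`` (inf if never)."""
        if self.viability is None:
            raise ValueError(f"no viability series available for {culture!r}")
        v = self.viability[self.viability["culture"] == culture].sort_values("time_h")
        if v.empty:
            raise ValueError(f"no viability series available for {culture!r}")
        below = v[v["viability_pct"] < threshold]
        if below.empty:
            return np.inf
        return float(below["time_h"].iloc[0])

    def subset(self, mask) -> "MeasurementSet":
        return MeasurementSet(
            records=self.records[mask].reset_index(drop=True),
            viability=self.viability,
        )

    def concat(self, other: "MeasurementSet") -> "MeasurementSet":
        via = None
        frames = [v for v in (self.viability, other.viability) if v is not None]
        if frames:
            via = pd.concat(frames, ignore_index=True).drop_duplicates()
        return MeasurementSet(
            records=pd.concat([self.records, other.records], ignore_index=True),
            viability=via,
        )


def merge(sets) -> MeasurementSet:
    sets = list(sets)
    out = sets[0]
    for s in sets[1:]:
        out = out.concat(s)
    return out
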