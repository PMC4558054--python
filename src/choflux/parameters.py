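"""Named kinetic parameter sets with magnitudes, bounds and sensitivity flags."""

from __future__ import annotations

from dataclasses import dataclass, field

import math

import numpy as np
import pandas as pd

__all__ = ["ParameterSet"]


@dataclass
class ParameterSet:
    """Ordered mapping of kinetic constant names to values.

    Each parameter carries an order-of-magnitude exponent ``n`` (used to
    rescale values to ~unit magnitude during optimisation), box bounds
    (lower bound 0 by default, as in the calibration contract) and a flag
    marking membership in the sensitive subset selected for calibration.
    """

    names: list[str]
    values: np.ndarray
    magnitude_exponents: np.ndarray = None
    lower_bounds: np.ndarray = None
    upper_bounds: np.ndarray = None
    sensitive: np.ndarray = None
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.names)
        if self.values.shape != (n,):
            raise ValueError("values length does not match names")
        if self.magnitude_exponents is None:
            self.magnitude_exponents = np.array(
                [self._default_exponent(v) for v in self.values]
            )
        self.magnitude_exponents = np.asarray(self.magnitude_exponents, dtype=int)
        if self.lower_bounds is None:
            self.lower_bounds = np.zeros(n)
        if self.upper_bounds is None:
            self.upper_bounds = np.full(n, np.inf)
        self.lower_bounds = np.asarray(self.lower_bounds, dtype=float)
        self.upper_bounds = np.asarray(self.upper_bounds, dtype=float)
        if self.sensitive is None:
            self.sensitive = np.zeros(n, dtype=bool)
        self.sensitive = np.asarray(self.sensitive, dtype=bool)
        self._index = {name: i for i, name in enumerate(self.names)}
        if len(self._index) != n:
            raise ValueError("duplicate parameter names")

    @staticmethod
    def _default_exponent(value: float) -> int:
        if value == 0 or not math.isfinite(value):
            return 0
        return int(math.floor(math.log10(abs(value))))

    # -- mapping interface -------------------------------------------------
    def __len__(self):
        return len(self.names)

    def __contains__(self, name):
        return name in self._index

    def __getitem__(self, name: str) -> float:
        return float(self.values[self._index[name]])

    def __setitem__(self, name: str, value: float):
        self.values[self._index[name]] = value

    def index(self, name: str) -> int:
        return self._index[name]

    def as_dict(self) -> dict:
        return {n: float(v) for n, v in zip(self.names, self.values)}

    def copy(self) -> "ParameterSet":
        return ParameterSet(
            names=list(self.names),
            values=self.values.copy(),
            magnitude_exponents=self.magnitude_exponents.copy(),
            lower_bounds=self.lower_bounds.copy(),
            upper_bounds=self.upper_bounds.copy(),
            sensitive=self.sensitive.copy(),
        )

    def with_values(self, values: np.ndarray) -> "ParameterSet":
        out = self.copy()
        out.values = np.asarray(values, dtype=float).copy()
        return out

    def sensitive_names(self) -> list[str]:
        return [n for n, s in zip(self.names, self.sensitive) if s]

    # -- CSV round trip ----------------------------------------------------
    @classmethod
    def from_csv(cls, path) -> "ParameterSet":
        df = pd.read_csv(path)
        required = {"name", "value"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"parameter table missing columns: {sorted(missing)}")
        kwargs = {}
        if "magnitude_exponent" in df.columns:
            kwargs["magnitude_exponents"] = df["magnitude_exponent"].to_numpy()
        if "lower_bound" in df.columns:
            kwargs["lower_bounds"] = df["lower_bound"].to_numpy()
        if "upper_bound" in df.columns:
            ub = df["upper_bound"].astype(float).to_numpy()
            kwargs["upper_bounds"] = np.where(np.isnan(ub), np.inf, ub)
        if "sensitive_flag" in df.columns:
            kwargs["sensitive"] = df["sensitive_flag"].astype(int).to_numpy() != 0
        return cls(
            names=df["name"].tolist(),
            values=df["value"].to_numpy(),
            **kwargs,
        )

    def to_csv(self, path):
        pd.DataFrame(
            {
                "name": self.names,
                "value": self.values,
                "magnitude_exponent": self.magnitude_exponents,
                "lower_bound": self.lower_bounds,
                "upper_bound": self.upper_bounds,
                "sensitive_flag": self.sensitive.astype(int),
            }
        ).to_csv(path, index=False)
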