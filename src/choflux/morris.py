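"""Morris elementary-effects screening of kinetic parameters.

Global sensitivity is ranked by the Morris one-at-a-time design: each
repetition walks a random trajectory on a 4-level grid over the box
[nominal*(1-b), nominal*(1+b)] (b = 25% by default), stepping one
parameter at a time by Delta = 2/3 on the unit-scaled axis and recording
the elementary effect of each step on a scalar, standard-deviation-
weighted objective. The absolute mean of a parameter's elementary effects
measures its sensitivity; the standard deviation flags nonlinearity or
interactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .measurements import MeasurementSet
from .simulator import IntegrationFailureError, observe, simulate

__all__ = [
    "MorrisDesign",
    "MorrisResult",
    "elementary_effect",
    "build_trajectories",
    "scalar_objective",
    "morris_screen",
    "select_sensitive",
]


@dataclass
class MorrisDesign:
    """Screening design over a named parameter subset."""

    names: list
    nominal: np.ndarray
    bound_fraction: float = 0.25
    levels: int = 4
    delta: float = 2.0 / 3.0
    repetitions: int = 35
    seed: int = 0

    def __post_init__(self):
        self.nominal = np.asarray(self.nominal, dtype=float)
        if self.levels % 2 != 0:
            raise ValueError("levels must be even")
        canonical = self.levels / (2.0 * (self.levels - 1))
        if not np.isclose(self.delta, canonical):
            raise ValueError(
                f"delta={self.delta} is not the canonical levels/(2*(levels-1))"
                f"={canonical} pairing"
            )

    @property
    def k(self):
        return len(self.names)

    def to_natural(self, x_unit):
        """Map unit-grid coordinates in [0,1] to natural parameter values."""
        lo = self.nominal * (1.0 - self.bound_fraction)
        hi = self.nominal * (1.0 + self.bound_fraction)
        return lo + np.asarray(x_unit) * (hi - lo)


@dataclass
class MorrisResult:
    table: pd.DataFrame  # parameter, mean_ee, std_ee, abs_mean_ee, rank
    n_failures: int = 0

    def ranked_names(self):
        return self.table.sort_values("rank")["parameter"].tolist()


def elementary_effect(f, x, i, delta):
    """Elementary effect of coordinate ``i`` at unit-scaled point ``x``.

    ``(f(x + delta*e_i) - f(x)) / delta``; the stepped point must remain
    inside the unit box.
    """
    x = np.asarray(x, dtype=float)
    x2 = x.copy()
    x2[i] += delta
    if np.any(x2 < -1e-12) or np.any(x2 > 1.0 + 1e-12):
        raise ValueError("step leaves the design region")
    return (f(x2) - f(x)) / delta


def build_trajectories(design: MorrisDesign, rng=None):
    """Random Morris trajectories on the unit grid.

    Returns a list of ``(points, order, signs)`` per repetition: ``points``
    is a ``(k+1, k)`` array of unit-grid points in which consecutive rows
    differ in exactly one coordinate by ``+-delta``; ``order[j]`` is the
    coordinate changed between rows ``j`` and ``j+1`` and ``signs[j]`` the
    step sign.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    k, p, delta = design.k, design.levels, design.delta
    base_levels = np.arange(p) / (p - 1)
    base_levels = base_levels[base_levels <= 1.0 - delta + 1e-12]
    out = []
    for _ in range(design.repetitions):
        x_star = rng.choice(base_levels, size=k)
        directions = rng.choice([-1.0, 1.0], size=k)
        # mirror the base point for descending coordinates so the walk stays in [0,1]
        start = np.where(directions > 0, x_star, 1.0 - x_star)
        order = rng.permutation(k)
        points = np.empty((k + 1, k))
        points[0] = start
        x = start.copy()
        signs = np.empty(k)
        for j, coord in enumerate(order):
            x = x.copy()
            x[coord] += directions[coord] * delta
            signs[j] = directions[coord]
            points[j + 1] = x
        out.append((points, order, signs))
    return out


def scalar_objective(outputs, sigmas):
    """Standard-deviation-weighted scalar screening objective.

    ``mean(|y / sigma|)`` over every output at every sampling time; this is
    the single value whose elementary effects are screened.
    """
    outputs = np.asarray(outputs, dtype=float)
    sigmas = np.asarray(sigmas, dtype=float)
    if outputs.size == 0:
        raise ValueError("no outputs to aggregate")
    if np.any(~np.isfinite(sigmas)) or np.any(sigmas <= 0):
        raise ValueError("every output needs a positive standard deviation")
    return float(np.mean(np.abs(outputs / sigmas)))


def _culture_obs_plan(measurements: MeasurementSet, cultures):
    """Per-culture (outputs, times, record index arrays, sds) lookup tables."""
    plans = {}
    for culture in cultures:
        df = measurements.for_culture(culture)
        df = df[~df["censored"]]
        if df.empty:
            continue
        outputs = sorted(df["output"].unique())
        times = np.sort(df["time_h"].unique())
        o_idx = {o: i for i, o in enumerate(outputs)}
        t_idx = {t: i for i, t in enumerate(times)}
        plans[culture] = dict(
            outputs=outputs,
            times=times,
            i_out=df["output"].map(o_idx).to_numpy(),
            i_time=df["time_h"].map(t_idx).to_numpy(),
            sd=df["sd"].to_numpy(),
        )
    return plans


def _screening_function(network, params, experiments, measurements, design,
                        sim_kwargs):
    plans = _culture_obs_plan(measurements, [e.name for e in experiments])
    exps = [e for e in experiments if e.name in plans]
    if not exps:
        raise ValueError("no usable measurements for any experiment in scope")
    base = params.copy()
    idx = np.array([params.index(n) for n in design.names])

    def f(x_unit):
        theta = base.values.copy()
        theta[idx] = design.to_natural(x_unit)
        p = base.with_values(theta)
        vals, sds = [], []
        for exp in exps:
            plan = plans[exp.name]
            traj = simulate(network, p, exp, **sim_kwargs)
            M = observe(traj, plan["outputs"], plan["times"])
            vals.append(M[plan["i_out"], plan["i_time"]])
            sds.append(plan["sd"])
        return scalar_objective(np.concatenate(vals), np.concatenate(sds))

    return f


def morris_screen(network, params, experiments, measurements,
                  design: MorrisDesign, sim_kwargs=None) -> MorrisResult:
    """Screen the design's parameters and rank them by |mean elementary effect|.

    A simulation failure at a design point is recorded and the elementary
    effects touching that point are skipped. Deterministic for a fixed
    design seed.
    """
    sim_kwargs = dict(sim_kwargs or {})
    f = _screening_function(network, params, experiments, measurements,
                            design, sim_kwargs)
    return morris_screen_function(f, design)


def morris_screen_function(f, design: MorrisDesign) -> MorrisResult:
    """Morris screening of an arbitrary scalar function of unit-scaled inputs."""
    trajectories = build_trajectories(design)
    k = design.k
    ees = [[] for _ in range(k)]
    failures = 0
    for points, order, signs in trajectories:
        values = np.full(len(points), np.nan)
        for j, x in enumerate(points):
            try:
                values[j] = f(x)
            except (IntegrationFailureError, FloatingPointError):
                failures += 1
        for j, coord in enumerate(order):
            y0, y1 = values[j], values[j + 1]
            if np.isfinite(y0) and np.isfinite(y1):
                ees[int(coord)].append((y1 - y0) / (signs[j] * design.delta))
    rows = []
    for name, e in zip(design.names, ees):
        e = np.asarray(e, dtype=float)
        mean = float(np.mean(e)) if e.size else np.nan
        std = float(np.std(e, ddof=1)) if e.size > 1 else 0.0
        rows.append((name, mean, std, abs(mean) if e.size else np.nan))
    table = pd.DataFrame(rows, columns=["parameter", "mean_ee", "std_ee", "abs_mean_ee"])
    table["rank"] = (
        table["abs_mean_ee"].rank(ascending=False, method="first").astype(int)
    )
    table = table.sort_values("rank").reset_index(drop=True)
    return MorrisResult(table=table, n_failures=failures)


def select_sensitive(result: MorrisResult, threshold=0.6, max_count=20):
    """Parameters with |mean EE| >= threshold, capped at ``max_count`` by rank.

    Falls back (with a warning entry) to the top ``max_count`` if the
    threshold selects nothing.
    """
    t = result.table.sort_values("rank")
    chosen = t[t["abs_mean_ee"] >= threshold]["parameter"].tolist()
    if not chosen:
        import warnings

        warnings.warn("threshold selected no parameters; returning top ranked")
        chosen = t["parameter"].tolist()
    return chosen[:max_count]
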