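"""Batch / fed-batch culture ODE integration with discrete bolus feed events.

State layout: extracellular concentrations (mM), intracellular per-cell
pools (mmol per 10^6 cells), then the culture scalars Xv (10^6 cells/mL),
mAb (mg/L) and V (L). Between feed events the system is integrated with a
stiff adaptive solver; a feed event is an exact discontinuity
(stop - bolus - restart). Balance equations:

* dXv/dt   = mu * Xv
* dmAb/dt  = q_mAb * Xv * 1000
* ext S:     dS/dt = (sum_j nu_Sj v_j) * Xv * 1000          [mM/h]
* intr C:    dC/dt = sum_j nu_Cj v_j - mu * C               [per-cell, with
             growth dilution; the dilution term is configurable]
* dV/dt    = 0 between events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .network import MetabolicNetwork, CompiledNetwork
from .parameters import ParameterSet

__all__ = [
    "FeedComposition",
    "FeedPolicy",
    "CultureExperiment",
    "SimulationTrajectory",
    "IntegrationFailureError",
    "InvalidPolicyError",
    "rhs",
    "apply_bolus",
    "feed_volume_for_target",
    "simulate",
    "observe",
]


class IntegrationFailureError(RuntimeError):
    def __init__(self, message, t=None, state=None):
        super().__init__(message)
        self.t = t
        self.state = state


class InvalidPolicyError(ValueError):
    pass


@dataclass
class FeedComposition:
    """Concentrate composition, species -> mM."""

    concentrations: dict

    def __post_init__(self):
        if any(c < 0 for c in self.concentrations.values()):
            raise ValueError("feed concentrations must be non-negative")

    def get(self, species):
        return float(self.concentrations.get(species, 0.0))


@dataclass
class FeedPolicy:
    """Daily bolus feeding rule.

    ``mode='daily'`` feeds unconditionally at every trigger up to the
    glucose set-point; ``mode='threshold'`` feeds only when glucose has
    fallen below the floor (default 10 mM). The set-point defaults to the
    culture's initial glucose concentration.
    """

    interval_h: float = 24.0
    first_feed_h: float = 24.0
    glucose_floor_mM: float = 10.0
    set_point_mM: float | None = None
    mode: str = "daily"
    glucose_id: str = "GLC"

    def __post_init__(self):
        if self.mode not in ("daily", "threshold"):
            raise InvalidPolicyError(f"unknown feed mode {self.mode!r}")

    def trigger_times(self, duration_h):
        t = np.arange(self.first_feed_h, duration_h, self.interval_h)
        return t[t > 0]


@dataclass
class CultureExperiment:
    """One culture: initial state, mode, and (fed-batch) feed definition."""

    name: str
    initial_state: dict  # species/scalar -> value; must include Xv, V
    mode: str  # 'batch' | 'fed-batch'
    duration_h: float
    feed: FeedComposition | None = None
    policy: FeedPolicy | None = None

    def __post_init__(self):
        if self.mode not in ("batch", "fed-batch"):
            raise ValueError(f"unknown culture mode {self.mode!r}")
        if self.mode == "batch" and (self.feed is not None or self.policy is not None):
            raise ValueError("batch experiments must not define a feed")
        if self.mode == "fed-batch":
            if self.feed is None:
                raise ValueError("fed-batch experiments require a feed composition")
            if self.policy is None:
                self.policy = FeedPolicy()


@dataclass
class SimulationTrajectory:
    """Dense simulation output: states and fluxes on a common time grid."""

    times: np.ndarray
    species: list  # dynamic species order, then Xv, mAb, V
    states: np.ndarray  # (n_state, T)
    reaction_ids: list
    fluxes: np.ndarray  # (n_rxn, T)
    feed_events: list = field(default_factory=list)  # (t, volume_L, FeedComposition)

    def state_series(self, name):
        return self.states[self.species.index(name)]

    def flux_series(self, rid):
        return self.fluxes[self.reaction_ids.index(rid)]

    def state_at(self, t):
        """Linear interpolation of the full state at time t."""
        return np.array([np.interp(t, self.times, row) for row in self.states])


# ---------------------------------------------------------------------------
# Right-hand side
# ---------------------------------------------------------------------------

def _make_rhs(comp: CompiledNetwork, theta, dilution=True):
    n_dyn = comp.n_ext + comp.n_int
    n_ext = comp.n_ext
    stoich = comp.stoich
    growth_j, mab_j = comp.growth_j, comp.mab_j

    def fun(t, y):
        single = y.ndim == 1
        Y = y[:, None] if single else y
        conc = Y[:n_dyn]
        Xv = np.maximum(Y[n_dyn], 0.0)
        v = comp.fluxes(conc, theta)
        mu = v[growth_j] if growth_j is not None else 0.0
        q = v[mab_j] if mab_j is not None else 0.0
        dC = stoich @ v
        dC[:n_ext] *= Xv * 1000.0
        if dilution:
            dC[n_ext:] -= mu * np.maximum(conc[n_ext:], 0.0)
        out = np.empty_like(Y)
        out[:n_dyn] = dC
        out[n_dyn] = mu * Xv
        out[n_dyn + 1] = q * Xv * 1000.0
        out[n_dyn + 2] = 0.0
        return out[:, 0] if single else out

    return fun


def rhs(state_vec, network: MetabolicNetwork, params: ParameterSet, dilution=True):
    """Time derivative of the full state vector (module-level convenience).

    Raises :class:`IntegrationFailureError` naming the offending species if
    any derivative is non-finite.
    """
    comp = network.compiled(params)
    fun = _make_rhs(comp, params.values, dilution=dilution)
    d = fun(0.0, np.asarray(state_vec, dtype=float))
    if not np.all(np.isfinite(d)):
        names = comp.species + ["Xv", "mAb", "V"]
        bad = [names[i] for i in np.where(~np.isfinite(d))[0]]
        raise IntegrationFailureError(f"non-finite derivative for {bad}")
    return d


# ---------------------------------------------------------------------------
# Feeding
# ---------------------------------------------------------------------------

def apply_bolus(state: dict, volume_L: float, feed: FeedComposition,
                ext_species=None) -> dict:
    """Instantaneous, mass-conserving addition of feed concentrate.

    Extracellular concentrations and mAb mix by volume; viable cell density
    is diluted; intracellular per-cell pools are unchanged.
    """
    if volume_L < 0:
        raise ValueError("bolus volume must be non-negative")
    out = dict(state)
    if volume_L == 0:
        return out
    V = state["V"]
    Vp = V + volume_L
    if ext_species is None:
        ext_species = [
            k for k in state
            if k not in ("Xv", "mAb", "V") and (k in feed.concentrations or True)
        ]
    for sp in ext_species:
        out[sp] = (state[sp] * V + feed.get(sp) * volume_L) / Vp
    out["mAb"] = state["mAb"] * V / Vp
    out["Xv"] = state["Xv"] * V / Vp
    out["V"] = Vp
    return out


def feed_volume_for_target(state: dict, feed: FeedComposition, target_mM: float,
                           glucose_id="GLC") -> float:
    """Bolus volume bringing glucose exactly to ``target_mM`` after mixing."""
    G = state[glucose_id]
    G_feed = feed.get(glucose_id)
    if target_mM >= G_feed:
        raise InvalidPolicyError(
            f"glucose set-point {target_mM} mM is not below the feed "
            f"concentration {G_feed} mM"
        )
    if G >= target_mM:
        return 0.0
    return state["V"] * (target_mM - G) / (G_feed - target_mM)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _state_to_vec(comp, state: dict):
    vec = [state[s] for s in comp.species] + [state["Xv"], state["mAb"], state["V"]]
    return np.array(vec, dtype=float)


def _vec_to_state(comp, y):
    d = {s: float(y[i]) for i, s in enumerate(comp.species)}
    n = len(comp.species)
    d["Xv"], d["mAb"], d["V"] = float(y[n]), float(y[n + 1]), float(y[n + 2])
    return d


def simulate(network: MetabolicNetwork, params: ParameterSet,
             experiment: CultureExperiment, output_times=None,
             rtol=1e-8, atol_scale=1e-10, dilution=True,
             max_grid_step_h=1.0, method="BDF") -> SimulationTrajectory:
    """Integrate a culture experiment and return the dense trajectory.

    Integration runs between feed events with a stiff adaptive solver
    (relative tolerance 1e-8 by default; absolute tolerance per species at
    ``atol_scale`` of its typical magnitude). At each feed trigger the
    bolus volume is computed from the policy and applied as an exact
    discontinuity. Deterministic for fixed inputs and solver settings.
    """
    comp = network.compiled(params)
    theta = params.values
    y = _state_to_vec(comp, experiment.initial_state)
    n_dyn = comp.n_ext + comp.n_int

    scale = np.abs(y).copy()
    ext_default = 1.0
    int_default = max(np.max(np.abs(y[comp.n_ext:n_dyn]), initial=0.0), 1e-9)
    scale[:comp.n_ext] = np.maximum(scale[:comp.n_ext], ext_default)
    scale[comp.n_ext:n_dyn] = np.maximum(scale[comp.n_ext:n_dyn], int_default)
    scale[n_dyn:] = np.maximum(scale[n_dyn:], 1.0)
    atol = atol_scale * scale

    fun = _make_rhs(comp, theta, dilution=dilution)

    duration = experiment.duration_h
    if experiment.mode == "fed-batch":
        policy = experiment.policy
        events = list(policy.trigger_times(duration))
    else:
        policy, events = None, []
    breakpoints = sorted(set([0.0] + [t for t in events if t < duration] + [duration]))

    if output_times is not None:
        output_times = np.asarray(output_times, dtype=float)
        if output_times.size and (
            output_times.min() < 0 or output_times.max() > duration
        ):
            raise ValueError("output_times outside [0, duration]")

    times = [np.array([0.0])]
    states = [y[:, None].copy()]
    feed_log = []
    t_now = 0.0
    for t0, t1 in zip(breakpoints[:-1], breakpoints[1:]):
        if t1 <= t0:
            continue
        grid = np.arange(t0, t1, max_grid_step_h)[1:]
        t_eval = np.concatenate([grid, [t1]])
        with np.errstate(over="ignore"):  # benign overflow in num_jac scaling
            sol = solve_ivp(
                fun, (t0, t1), y, method=method, rtol=rtol, atol=atol,
                t_eval=t_eval, vectorized=True,
            )
        if not sol.success:
            last_t = sol.t[-1] if sol.t.size else t0
            raise IntegrationFailureError(
                f"solver failed at t={last_t:.2f} h: {sol.message}",
                t=last_t,
                state=_vec_to_state(comp, sol.y[:, -1] if sol.t.size else y),
            )
        times.append(sol.t)
        states.append(sol.y)
        y = sol.y[:, -1].copy()
        t_now = t1
        if policy is not None and t1 in events and t1 < duration:
            state = _vec_to_state(comp, y)
            target = policy.set_point_mM
            if target is None:
                target = experiment.initial_state[policy.glucose_id]
            G = state[policy.glucose_id]
            vol = 0.0
            if policy.mode == "daily" or G < policy.glucose_floor_mM:
                vol = feed_volume_for_target(
                    state, experiment.feed, target, policy.glucose_id
                )
            if vol > 0:
                state = apply_bolus(
                    state, vol, experiment.feed,
                    ext_species=comp.species[:comp.n_ext],
                )
                y = _state_to_vec(comp, state)
                feed_log.append((t1, vol, experiment.feed))
                times.append(np.array([t1]))
                states.append(y[:, None].copy())

    t_all = np.concatenate(times)
    y_all = np.concatenate(states, axis=1)
    # keep the post-bolus value at duplicated feed instants
    order = np.argsort(t_all, kind="stable")
    t_all, y_all = t_all[order], y_all[:, order]
    dup = np.concatenate([np.diff(t_all) == 0, [False]])
    t_all, y_all = t_all[~dup], y_all[:, ~dup]
    # solver round-off can leave depleted species infinitesimally negative
    y_all = np.maximum(y_all, 0.0)

    flux = comp.fluxes(y_all[:n_dyn], theta)
    return SimulationTrajectory(
        times=t_all,
        species=list(comp.species) + ["Xv", "mAb", "V"],
        states=y_all,
        reaction_ids=list(comp.rids),
        fluxes=flux,
        feed_events=feed_log,
    )


# ---------------------------------------------------------------------------
# Observation
# ---------------------------------------------------------------------------

def observe(trajectory: SimulationTrajectory, outputs, times,
            resp_reaction="V_resp"):
    """Interpolate observables at the requested times.

    An output may be a state name (species, ``Xv``, ``mAb``, ``V``), a pool
    ratio ``'A/B'``, a reaction flux id (``V_*``), or ``'OUR'`` (oxygen
    uptake rate, ``V_resp * Xv``, mmol L^-1 h^-1 scale per 10^6 cells/mL).
    Returns an array of shape ``(n_outputs, n_times)``.
    """
    times = np.asarray(times, dtype=float)
    if times.size and (
        times.min() < trajectory.times[0] - 1e-9
        or times.max() > trajectory.times[-1] + 1e-9
    ):
        raise ValueError("requested times outside the simulated range")

    out = np.empty((len(outputs), times.size))
    for i, name in enumerate(outputs):
        series = _output_series(trajectory, name, resp_reaction)
        out[i] = np.interp(times, trajectory.times, series)
    return out


def _output_series(trajectory, name, resp_reaction="V_resp"):
    if name == "OUR":
        return trajectory.flux_series(resp_reaction) * trajectory.state_series("Xv")
    if "/" in name:
        num, den = name.split("/")
        d = trajectory.state_series(den)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = trajectory.state_series(num) / d
        return np.where(d > 0, r, np.nan)
    if name in trajectory.species:
        return trajectory.state_series(name)
    if name in trajectory.reaction_ids:
        return trajectory.flux_series(name)
    raise KeyError(f"unknown output {name!r}")
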