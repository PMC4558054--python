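"""Synthetic pseudo-experimental datasets for end-to-end testing.

The generator emulates the statistical structure of the study's four
cultures — two media (Biogro-CHO and PowerCHO-2), each run as a batch and
a daily-fed fed-batch, inoculated at 2x10^5 cells/mL, sampled daily (12 h
option for the short Biogro batch) — with multiplicative measurement
noise whose coefficient of variation scales with the signal, and
limit-of-detection censoring of low intracellular species. Ground-truth
parameters are returned alongside each dataset so parameter-recovery
benchmarks need no external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .measurements import MeasurementSet
from .network import (
    BiomassComposition,
    Metabolite,
    MetabolicNetwork,
    RateLawSpec,
    Reaction,
    RegulationTerm,
    SubstrateTerm,
    load_network,
)
from .parameters import ParameterSet
from .simulator import (
    CultureExperiment,
    FeedComposition,
    FeedPolicy,
    observe,
    simulate,
)

__all__ = [
    "NoiseModel",
    "SamplingSchedule",
    "DEFAULT_OUTPUTS",
    "reference_network",
    "reference_parameters",
    "reference_experiments",
    "generate_dataset",
    "synthetic_viability",
    "recovery_benchmark",
    "toy_model",
]

# The default observable panel used for screening and calibration: cells,
# product, major extracellular substrates/byproducts and amino acids, the
# oxygen uptake rate, and the measured intracellular pools and ratios.
DEFAULT_OUTPUTS = [
    "Xv", "mAb", "GLC", "LAC", "NH4", "OUR",
    "GLN", "GLU", "ALA", "ASP", "ASN", "SER", "GLY", "ARG", "HIS", "ILE",
    "LYS", "MET", "PHE", "THR", "TYR", "VAL",
    "G6P", "PYR", "CIT", "AKG", "MAL", "R5P", "ATP",
    "AMP/ATP", "NAD/NADH", "NADPH/NADP",
]

_INTRACELLULAR_HINT = {
    "G6P", "F6P", "FBP", "PEP", "PYR", "CIT", "AKG", "MAL", "R5P", "EGLU",
    "ATP", "ADP", "AMP", "NAD", "NADH", "NADP", "NADPH",
}


@dataclass
class NoiseModel:
    """Multiplicative truncated-Gaussian noise with per-class CVs.

    ``value = truth * (1 + eps)``, ``eps ~ N(0, CV^2)``, truncated at 0;
    the reported standard deviation is ``CV * truth``. Species whose true
    value falls below the limit of detection are emitted as censored.
    """

    cv_extracellular: float = 0.10
    cv_intracellular: float = 0.15
    cv_scalar: float = 0.10
    lod: dict = field(default_factory=dict)  # output -> detection limit
    sd_floor_frac: float = 0.02  # sd floor, as a fraction of the series maximum

    def cv_for(self, output: str) -> float:
        base = output.split("/")[0]
        if output in ("Xv", "mAb", "V"):
            return self.cv_scalar
        if base in _INTRACELLULAR_HINT:
            return self.cv_intracellular
        return self.cv_extracellular


@dataclass
class SamplingSchedule:
    interval_h: float = 24.0
    start_h: float = 0.0

    def __post_init__(self):
        if self.interval_h <= 0:
            raise ValueError("sampling interval must be positive")

    def times(self, duration_h: float) -> np.ndarray:
        return np.arange(self.start_h, duration_h + 1e-9, self.interval_h)


# ---------------------------------------------------------------------------
# Shipped reference model
# ---------------------------------------------------------------------------

def _data_path(name):
    return resources.files("choflux").joinpath("data", name)


def reference_network() -> MetabolicNetwork:
    """The shipped CHO-mAb kinetic network (glycolysis, PPP, TCA,
    glutaminolysis, amino-acid catabolism, energetics, growth, mAb)."""
    with resources.as_file(_data_path("model.yaml")) as p:
        return load_network(p)


def reference_parameters() -> ParameterSet:
    with resources.as_file(_data_path("parameters.csv")) as p:
        return ParameterSet.from_csv(p)


def load_experiments(path) -> list:
    """Parse a culture/feed definition YAML file into experiments."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    media = doc.get("media", {})
    out = []
    for c in doc["cultures"]:
        state = {}
        medium = c.get("medium")
        if medium and medium in media:
            state.update(media[medium].get("base_state", {}))
        state.update(c.get("initial_state", {}))
        state = {k: float(v) for k, v in state.items()}
        for required in ("Xv", "V"):
            if required not in state:
                raise ValueError(f"culture {c['name']}: missing initial {required}")
        state.setdefault("mAb", 0.0)
        feed = policy = None
        if c["mode"] == "fed-batch":
            feed = FeedComposition({k: float(v) for k, v in c["feed"].items()})
            policy = FeedPolicy(**c.get("policy", {}))
        exp = CultureExperiment(
            name=c["name"],
            initial_state=state,
            mode=c["mode"],
            duration_h=float(c["duration_h"]),
            feed=feed,
            policy=policy,
        )
        exp.medium = medium
        exp.sampling_interval_h = float(c.get("sampling_interval_h", 24.0))
        out.append(exp)
    return out


def reference_experiments() -> list:
    """The four reference cultures (medium x mode) with shipped initial
    conditions and feed definitions."""
    with resources.as_file(_data_path("experiments.yaml")) as p:
        return load_experiments(p)


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

def synthetic_viability(culture: str, duration_h: float, times=None,
                        onset_frac=0.55, decline_per_h=0.25) -> pd.DataFrame:
    """Viability held at 100% until a decline onset, then a linear fall.

    Emulates the exponential/early-plateau window the model is restricted
    to: the 95% crossing lands at ``onset_frac*duration + 20 h`` with the
    default 0.25 %/h decline.
    """
    if times is None:
        times = np.arange(0.0, duration_h + 1e-9, 24.0)
    times = np.asarray(times, dtype=float)
    onset = onset_frac * duration_h
    v = 100.0 - np.maximum(times - onset, 0.0) * decline_per_h
    return pd.DataFrame(
        {"culture": culture, "time_h": times, "viability_pct": np.maximum(v, 0.0)}
    )


def generate_dataset(network, params, experiment, schedule: SamplingSchedule = None,
                     noise: NoiseModel = None, seed=0, outputs=None,
                     sim_kwargs=None):
    """Simulate one culture and emit noisy measurements plus ground truth.

    Returns ``(MeasurementSet, ground_truth_params)``. Fully reproducible
    for a given seed; with all CVs zero the values equal the model outputs.
    """
    schedule = schedule or SamplingSchedule(
        interval_h=getattr(experiment, "sampling_interval_h", 24.0)
    )
    noise = noise or NoiseModel()
    outputs = list(outputs or DEFAULT_OUTPUTS)
    rng = np.random.default_rng(seed)
    traj = simulate(network, params, experiment, **(sim_kwargs or {}))
    times = schedule.times(experiment.duration_h)
    def resolvable(o):
        if o == "OUR":
            return "V_resp" in traj.reaction_ids
        if "/" in o:
            return all(part in traj.species for part in o.split("/"))
        return o in traj.species or o in traj.reaction_ids

    outputs = [o for o in outputs if resolvable(o)]
    truth = observe(traj, outputs, times)

    rows = []
    for i, out in enumerate(outputs):
        cv = noise.cv_for(out)
        series = truth[i]
        finite = np.isfinite(series)
        floor = noise.sd_floor_frac * (np.nanmax(np.abs(series)) if finite.any() else 1.0)
        lod = noise.lod.get(out, 0.0)
        eps = rng.normal(0.0, 1.0, size=series.size)
        for t, y, e in zip(times, series, eps):
            if not np.isfinite(y):
                continue
            sd = max(cv * abs(y), floor, 1e-12)
            value = max(y * (1.0 + cv * e), 0.0) if cv > 0 else y
            censored = bool(y < lod)
            rows.append((experiment.name, out, float(t), value, sd, censored))
    records = pd.DataFrame(
        rows, columns=["culture", "output", "time_h", "value", "sd", "censored"]
    )
    via = synthetic_viability(experiment.name, experiment.duration_h)
    return MeasurementSet(records=records, viability=via), params.copy()


# ---------------------------------------------------------------------------
# Parameter-recovery benchmark
# ---------------------------------------------------------------------------

def recovery_benchmark(network, params, experiments, free_names, cv=0.05,
                       n_replicates=20, seed=0, schedule=None, outputs=None,
                       confidence=0.95, sim_kwargs=None, max_nfev=None,
                       start_jitter=0.1) -> pd.DataFrame:
    """Repeatedly regenerate noisy data and refit; report bias, RMSE, coverage.

    Each replicate draws a fresh dataset at the ground-truth parameters,
    starts the fit from the truth jittered by ``start_jitter`` (relative),
    and records the estimate and CI per free parameter.
    """
    from .calibrate import CalibrationConfig, confidence_intervals, fit

    if isinstance(experiments, CultureExperiment):
        experiments = [experiments]
    rng = np.random.default_rng(seed)
    noise = NoiseModel(cv_extracellular=cv, cv_intracellular=cv, cv_scalar=cv)
    rows = []
    for rep in range(n_replicates):
        sets = []
        for exp in experiments:
            ms, _ = generate_dataset(
                network, params, exp, schedule=schedule, noise=noise,
                seed=int(rng.integers(2**31 - 1)), outputs=outputs,
                sim_kwargs=sim_kwargs,
            )
            sets.append(ms)
        ms = sets[0]
        for s in sets[1:]:
            ms = ms.concat(s)
        start = params.copy()
        for name in free_names:
            start[name] = params[name] * (1.0 + start_jitter * rng.uniform(-1, 1))
        cfg = CalibrationConfig(
            free_names=list(free_names), window=False, max_nfev=max_nfev,
            sim_kwargs=dict(sim_kwargs or {}),
        )
        res = fit(network, experiments, ms, cfg, params=start)
        ci = confidence_intervals(res, confidence).set_index("parameter")
        for name in free_names:
            true = params[name]
            est = ci.loc[name, "estimate"]
            rows.append(
                dict(
                    replicate=rep, parameter=name, truth=true, estimate=est,
                    error=est - true,
                    covered=bool(ci.loc[name, "ci_low"] <= true <= ci.loc[name, "ci_high"]),
                )
            )
    df = pd.DataFrame(rows)
    report = df.groupby("parameter").agg(
        truth=("truth", "first"),
        bias=("error", "mean"),
        rmse=("error", lambda e: float(np.sqrt(np.mean(np.square(e))))),
        coverage=("covered", "mean"),
        n=("replicate", "count"),
    ).reset_index()
    return report


# ---------------------------------------------------------------------------
# Reduced toy model for fast oracle tests
# ---------------------------------------------------------------------------

def toy_model(duration_h=48.0):
    """Three-reaction toy: uptake -> intermediate -> product with one
    product-inhibition term, at fixed cell density.

    S (extracellular substrate) is taken up into the per-cell pool M,
    which is converted to the secreted product P; the conversion is
    inhibited by P. Returns ``(network, params, experiment)``.
    """
    metabolites = [
        Metabolite("S", "extracellular"),
        Metabolite("P", "extracellular"),
        Metabolite("M", "intracellular"),
        Metabolite("Xv", "scalar", "1e6 cells/mL"),
        Metabolite("mAb", "scalar", "mg/L"),
        Metabolite("V", "scalar", "L"),
    ]
    reactions = [
        Reaction(
            id="V_upt",
            stoichiometry={"S": -1.0, "M": 1.0},
            rate_law=RateLawSpec(
                vmax="VmaxU",
                substrates=(SubstrateTerm("S", "KmS_U"),),
            ),
        ),
        Reaction(
            id="V_conv",
            stoichiometry={"M": -1.0, "P": 1.0},
            rate_law=RateLawSpec(
                vmax="VmaxC",
                substrates=(SubstrateTerm("M", "KmM_C"),),
                regulation=(
                    RegulationTerm(
                        "noncompetitive_inhibition", "P", {"ki": "KdP_C"}
                    ),
                ),
            ),
        ),
        Reaction(
            id="V_exp",
            stoichiometry={"M": -1.0, "P": 1.0},
            rate_law=RateLawSpec(
                vmax="VmaxE",
                substrates=(SubstrateTerm("M", "KmM_E"),),
            ),
        ),
    ]
    biomass = BiomassComposition(3.15e-4, 107.5, 2.93e-3, 9.17e-3)
    net = MetabolicNetwork(
        name="toy-uptake-conversion",
        metabolites=metabolites,
        reactions=reactions,
        biomass=biomass,
        growth_reaction="V_none",
        mab_reaction="V_none",
    )
    params = ParameterSet(
        names=["VmaxU", "KmS_U", "VmaxC", "KmM_C", "KdP_C", "VmaxE", "KmM_E"],
        values=np.array([2.0e-4, 2.0, 1.5e-4, 1.0e-4, 5.0, 5.0e-5, 2.0e-4]),
        sensitive=np.array([True, False, True, False, True, False, False]),
    )
    experiment = CultureExperiment(
        name="toy",
        initial_state={"S": 20.0, "P": 0.0, "M": 1.0e-4, "Xv": 1.0,
                       "mAb": 0.0, "V": 1.0},
        mode="batch",
        duration_h=duration_h,
    )
    experiment.medium = "toy"
    return net, params, experiment
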