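"""Weighted least-squares calibration of the sensitive parameter subset.

The objective is the standard-deviation-weighted sum of squared residuals
over every culture, output and sampling time in scope,

    SSR(p) = sum_n sum_t ((y_exp[n,t] - y_model[n,t](p)) / sigma[n,t])^2,

minimised over the free (sensitive) parameters with a bounded
trust-region-reflective solver. Free parameters are rescaled by their
order of magnitude 10^n so the optimiser works on ~unit-scale variables;
lower bounds are 0. Confidence intervals are linearised (Wald):
cov = s^2 (J'J)^-1 with s^2 = SSR/(N-k) and CI = estimate +-
t(0.975, N-k) * se.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .measurements import MeasurementSet
from .morris import _culture_obs_plan
from .parameters import ParameterSet
from .simulator import IntegrationFailureError, observe, simulate

__all__ = [
    "CalibrationConfig",
    "CalibrationResult",
    "window_measurements",
    "objective",
    "normalize_params",
    "denormalize_params",
    "fit",
    "confidence_intervals",
    "natural_covariance",
    "subset_comparison",
]

SCHEMES = ("all", "batch", "fed-batch", "Biogro", "PowerCHO", "phase1", "phase2")

_PENALTY_RESIDUAL = 1e6  # finite placeholder residual when a simulation fails


@dataclass
class CalibrationConfig:
    free_names: list = None  # default: the parameter set's sensitive subset
    scheme: str = "all"
    window: bool = True  # apply the 24 h / 95%-viability data window
    viability_threshold: float = 95.0
    start_h: float = 24.0
    phase_split_h: float = 72.0
    max_nfev: int = None
    sim_kwargs: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}; one of {SCHEMES}")


@dataclass
class CalibrationResult:
    params: ParameterSet  # full parameter set at the optimum
    free_names: list
    estimates: np.ndarray  # natural scale
    exponents: np.ndarray
    ssr: float
    residuals: np.ndarray
    jacobian: np.ndarray  # w.r.t. unit-scaled free parameters
    n_obs: int
    success: bool
    message: str = ""
    n_failures: int = 0

    @property
    def dof(self):
        return self.n_obs - len(self.free_names)


# ---------------------------------------------------------------------------
# Data windowing and scheme selection
# ---------------------------------------------------------------------------

def window_measurements(measurements: MeasurementSet, config=None) -> MeasurementSet:
    """Restrict records to [24 h, first time viability < 95%] per culture.

    Phase schemes additionally restrict to t < 72 h (phase1) or
    t >= 72 h (phase2).
    """
    config = config or CalibrationConfig()
    df = measurements.records
    keep = df["time_h"] >= config.start_h
    for culture in measurements.cultures:
        cutoff = measurements.viability_cutoff(culture, config.viability_threshold)
        keep &= (df["culture"] != culture) | (df["time_h"] <= cutoff)
    if config.scheme == "phase1":
        keep &= df["time_h"] < config.phase_split_h
    elif config.scheme == "phase2":
        keep &= df["time_h"] >= config.phase_split_h
    return measurements.subset(keep)


def select_experiments(experiments, scheme: str):
    """Filter the culture list for a subset scheme (mode or medium based)."""
    if scheme in ("all", "phase1", "phase2"):
        return list(experiments)
    if scheme in ("batch", "fed-batch"):
        return [e for e in experiments if e.mode == scheme]
    return [e for e in experiments if getattr(e, "medium", None) == scheme]


# ---------------------------------------------------------------------------
# Objective
# ---------------------------------------------------------------------------

def _residual_function(network, params, experiments, measurements, free_names,
                       sim_kwargs):
    """Residual vector ((y_model - y_exp)/sigma) as a function of scaled params."""
    plans = _culture_obs_plan(measurements, [e.name for e in experiments])
    exps = [e for e in experiments if e.name in plans]
    if not exps:
        raise ValueError("no measurements left after windowing/scheme selection")
    df = measurements.usable()
    df = df[df["culture"].isin([e.name for e in exps])]
    y_exp, sd = [], []
    for exp in exps:
        d = df[df["culture"] == exp.name]
        y_exp.append(d["value"].to_numpy())
        sd.append(d["sd"].to_numpy())
    y_exp = np.concatenate(y_exp)
    sd = np.concatenate(sd)
    n_obs = y_exp.size
    base = params.copy()
    idx = np.array([params.index(n) for n in free_names], dtype=int)
    failures = [0]

    def model_outputs(theta_free_natural):
        theta = base.values.copy()
        theta[idx] = theta_free_natural
        p = base.with_values(theta)
        vals = []
        for exp in exps:
            plan = plans[exp.name]
            traj = simulate(network, p, exp, **sim_kwargs)
            M = observe(traj, plan["outputs"], plan["times"])
            vals.append(M[plan["i_out"], plan["i_time"]])
        return np.concatenate(vals)

    def residuals(theta_free_natural):
        try:
            y = model_outputs(theta_free_natural)
        except (IntegrationFailureError, FloatingPointError):
            failures[0] += 1
            return np.full(n_obs, _PENALTY_RESIDUAL)
        return (y - y_exp) / sd

    return residuals, n_obs, failures


def objective(params: ParameterSet, network, experiments,
              measurements: MeasurementSet, sim_kwargs=None) -> float:
    """Weighted SSR of the model against a measurement set (lower is better)."""
    res, _, _ = _residual_function(
        network, params, experiments, measurements, [], dict(sim_kwargs or {})
    )
    r = res(np.empty(0))
    return float(np.sum(r**2))


# ---------------------------------------------------------------------------
# Magnitude normalisation
# ---------------------------------------------------------------------------

def normalize_params(values, magnitude_exponents):
    """Scale values to ~unit magnitude: value / 10^n (exact round trip)."""
    return np.asarray(values, dtype=float) / 10.0 ** np.asarray(magnitude_exponents)


def denormalize_params(scaled, magnitude_exponents):
    return np.asarray(scaled, dtype=float) * 10.0 ** np.asarray(magnitude_exponents)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def fit(network, experiments, measurements: MeasurementSet,
        config: CalibrationConfig = None, params: ParameterSet = None,
        seed=None) -> CalibrationResult:
    """Bounded weighted least squares on the configured free subset.

    The fit starts from the values in ``params`` (the supplied initial
    guess), works on magnitude-normalised variables with lower bounds at 0,
    and returns estimates on the natural scale together with the residuals
    and Jacobian at the optimum. Deterministic given the initial guess.
    """
    if params is None:
        raise ValueError("an initial-guess ParameterSet is required")
    config = config or CalibrationConfig()
    free_names = config.free_names or params.sensitive_names()
    if not free_names:
        raise ValueError("no free parameters configured")
    exps = select_experiments(experiments, config.scheme)
    ms = window_measurements(measurements, config) if config.window else measurements
    ms = ms.subset(ms.records["culture"].isin([e.name for e in exps]))

    residuals, n_obs, failures = _residual_function(
        network, params, exps, ms, free_names, dict(config.sim_kwargs)
    )
    idx = [params.index(n) for n in free_names]
    exponents = params.magnitude_exponents[idx]
    x0_nat = params.values[idx]
    lo = normalize_params(params.lower_bounds[idx], exponents)
    hi = normalize_params(
        np.where(np.isfinite(params.upper_bounds[idx]), params.upper_bounds[idx], np.inf),
        exponents,
    )
    hi = np.where(np.isfinite(hi), hi, np.inf)

    def scaled_residuals(x):
        return residuals(denormalize_params(x, exponents))

    sol = least_squares(
        scaled_residuals,
        normalize_params(x0_nat, exponents),
        bounds=(lo, hi),
        method="trf",
        max_nfev=config.max_nfev,
        x_scale="jac",
    )
    estimates = denormalize_params(sol.x, exponents)
    fitted = params.copy()
    for n, v in zip(free_names, estimates):
        fitted[n] = v
    return CalibrationResult(
        params=fitted,
        free_names=list(free_names),
        estimates=estimates,
        exponents=np.asarray(exponents),
        ssr=float(2.0 * sol.cost),
        residuals=sol.fun,
        jacobian=sol.jac,
        n_obs=n_obs,
        success=bool(sol.success),
        message=str(sol.message),
        n_failures=failures[0],
    )


def covariance_matrix(result: CalibrationResult):
    """Linearised covariance of the unit-scaled free parameters.

    ``s^2 (J'J)^-1`` with ``s^2 = SSR/(N-k)``; near-singular directions of
    ``J'J`` are flagged by returning infinite variance for the parameters
    dominating the deficient singular vectors.
    """
    J = result.jacobian
    dof = result.dof
    if dof <= 0:
        raise ValueError("non-positive degrees of freedom")
    s2 = result.ssr / dof
    U, S, Vt = np.linalg.svd(J, full_matrices=False)
    tol = np.finfo(float).eps * max(J.shape) * (S[0] if S.size else 0.0)
    rank_def = S <= tol
    S_safe = np.where(rank_def, np.inf, S)
    cov = (Vt.T / S_safe**2) @ Vt * s2
    if rank_def.any():
        bad = (np.abs(Vt[rank_def]) > 1e-8).any(axis=0)
        cov[bad, :] = np.where(np.eye(len(bad), dtype=bool)[bad], np.inf, cov[bad, :])
        cov[:, bad] = cov[bad, :].T
    return cov


def natural_covariance(result: CalibrationResult):
    """Covariance of the free parameters on the natural (unscaled) scale."""
    D = 10.0 ** np.asarray(result.exponents, dtype=float)
    return covariance_matrix(result) * np.outer(D, D)


def confidence_intervals(result: CalibrationResult, confidence=0.95) -> pd.DataFrame:
    """Per-parameter linearised confidence intervals on the natural scale."""
    cov = covariance_matrix(result)
    se_scaled = np.sqrt(np.diag(cov))
    se = denormalize_params(se_scaled, result.exponents)
    tval = stats.t.ppf(0.5 + confidence / 2.0, result.dof)
    half = tval * se
    est = result.estimates
    return pd.DataFrame(
        {
            "parameter": result.free_names,
            "estimate": est,
            "se": se,
            "ci_low": est - half,
            "ci_high": est + half,
            "identifiable": np.isfinite(se),
        }
    )


# ---------------------------------------------------------------------------
# Subset / phase comparison
# ---------------------------------------------------------------------------

def intervals_overlap(lo1, hi1, lo2, hi2) -> bool:
    return (lo1 <= hi2) and (lo2 <= hi1)


def subset_comparison(network, experiments, measurements, schemes,
                      params: ParameterSet, config: CalibrationConfig = None,
                      confidence=0.95):
    """Fit each scheme and compare estimates by confidence-interval overlap.

    The 'all' scheme is fitted first (or prepended) and its estimates seed
    every other scheme's fit. Returns ``(table, overlaps)``: a long table of
    per-scheme estimates with CIs, and a dict mapping scheme pairs to
    per-parameter overlap verdicts (overlapping CIs -> not significantly
    different).
    """
    config = config or CalibrationConfig()
    schemes = list(schemes)
    if "all" not in schemes:
        schemes = ["all"] + schemes

    results = {}
    tables = []
    seed_params = params
    for scheme in schemes:
        cfg = CalibrationConfig(
            free_names=config.free_names,
            scheme=scheme,
            window=config.window,
            viability_threshold=config.viability_threshold,
            start_h=config.start_h,
            phase_split_h=config.phase_split_h,
            max_nfev=config.max_nfev,
            sim_kwargs=config.sim_kwargs,
        )
        start = params if scheme == "all" else seed_params
        try:
            res = fit(network, experiments, measurements, cfg, params=start)
        except ValueError as exc:
            import warnings

            warnings.warn(f"scheme {scheme!r} skipped: {exc}")
            continue
        if scheme == "all":
            seed_params = res.params
        ci = confidence_intervals(res, confidence)
        ci.insert(0, "scheme", scheme)
        tables.append(ci)
        results[scheme] = ci
    table = pd.concat(tables, ignore_index=True)

    overlaps = {}
    done = list(results)
    for a in done:
        for b in done:
            if a >= b:
                continue
            ca = results[a].set_index("parameter")
            cb = results[b].set_index("parameter")
            verdict = {}
            for name in ca.index:
                verdict[name] = intervals_overlap(
                    ca.loc[name, "ci_low"], ca.loc[name, "ci_high"],
                    cb.loc[name, "ci_low"], cb.loc[name, "ci_high"],
                )
            overlaps[(a, b)] = verdict
    return table, overlaps
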