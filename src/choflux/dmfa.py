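"""Dynamic metabolic flux analysis on simulated culture trajectories.

Intracellular reaction rates are evaluated along the simulated time
course (rather than at a steady-state snapshot), and summarised through
the derived flux sums and ratios used to interpret CHO cell physiology:
total ammonia production, total influx into the TCA cycle, net ATP
production, the amino-acid / pyruvate-dehydrogenase / pyruvate-carboxylase
contributions to TCA influx, and the glycolytic and respiratory shares of
ATP production. Derived quantities are data (linear combinations over
reaction ids), not code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulator import SimulationTrajectory, simulate

__all__ = [
    "DerivedFluxDefinition",
    "DERIVED_FLUXES",
    "evaluate_fluxes",
    "linear_combination",
    "ammonia_production",
    "tca_influx",
    "net_atp_production",
    "flux_ratios",
    "inhibition_term_course",
    "flux_confidence",
]


@dataclass(frozen=True)
class DerivedFluxDefinition:
    name: str
    coefficients: dict  # reaction id -> coefficient
    kind: str = "sum"  # sum | ratio numerator etc.


# The physiological flux aggregates: linear combinations of reaction rates.
DERIVED_FLUXES = {
    "ammonia_production": DerivedFluxDefinition(
        "ammonia_production",
        {"V_GLDH": 1, "V_GlnT": 1, "V_SDHH": 1, "V_ASN": 1, "V_HISARGTA": 1},
    ),
    "tca_influx": DerivedFluxDefinition(
        "tca_influx",
        {"V_GLDH": 1, "V_PDH": 1, "V_AlaTA": 1, "V_PC": 1, "V_AAtoSUC": 5},
    ),
    "net_atp_production": DerivedFluxDefinition(
        "net_atp_production",
        {"V_PGK": 1, "V_PK": 1, "V_AKGDH": 1, "V_PC": 1, "V_GlnT": 1,
         "V_resp": 2 * 2.5},
    ),
    "aa_to_tca": DerivedFluxDefinition(
        "aa_to_tca", {"V_GLDH": 1, "V_AlaTA": 1, "V_AAtoSUC": 5}
    ),
    "glycolysis_atp": DerivedFluxDefinition(
        "glycolysis_atp", {"V_HK": 1, "V_PFK": 1}
    ),
    "respiration_atp": DerivedFluxDefinition(
        "respiration_atp", {"V_resp": 2 * 2.5}
    ),
}


def evaluate_fluxes(trajectory: SimulationTrajectory, network, params):
    """Re-evaluate every rate law along the stored state trajectory.

    Returns ``{reaction id: series}``; consistent with the simulator's
    stored fluxes to floating-point round-off.
    """
    comp = network.compiled(params)
    n_dyn = comp.n_ext + comp.n_int
    v = comp.fluxes(trajectory.states[:n_dyn], params.values)
    return {rid: v[j] for j, rid in enumerate(comp.rids)}


def _as_flux_map(fluxes):
    if isinstance(fluxes, SimulationTrajectory):
        return {rid: fluxes.flux_series(rid) for rid in fluxes.reaction_ids}
    return fluxes


def linear_combination(fluxes, definition: DerivedFluxDefinition):
    fluxes = _as_flux_map(fluxes)
    missing = [r for r in definition.coefficients if r not in fluxes]
    if missing:
        raise KeyError(
            f"derived flux {definition.name!r} references unknown reactions {missing}"
        )
    terms = [c * np.asarray(fluxes[r], dtype=float)
             for r, c in definition.coefficients.items()]
    return sum(terms)


def ammonia_production(fluxes):
    """Total ammonia-producing flux: V_GLDH + V_GlnT + V_SDHH + V_ASN + V_HISARGTA."""
    return linear_combination(fluxes, DERIVED_FLUXES["ammonia_production"])


def tca_influx(fluxes):
    """Total influx into the TCA cycle: V_GLDH + V_PDH + V_AlaTA + V_PC + 5*V_AAtoSUC."""
    return linear_combination(fluxes, DERIVED_FLUXES["tca_influx"])


def net_atp_production(fluxes):
    """Net ATP production: V_PGK + V_PK + V_AKGDH + V_PC + V_GlnT + 2*2.5*V_resp."""
    return linear_combination(fluxes, DERIVED_FLUXES["net_atp_production"])


def _safe_ratio(num, den):
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = num / den
    return np.where(den > 0, r, np.nan)


def flux_ratios(fluxes):
    """Named physiological flux ratios (zero denominators reported as NaN).

    The three TCA-influx contributions (amino acids, PDH, PC) partition
    unity at every time point.
    """
    fx = _as_flux_map(fluxes)
    tca = tca_influx(fx)
    atp = net_atp_production(fx)
    return {
        "aa_contribution_tca": _safe_ratio(
            linear_combination(fx, DERIVED_FLUXES["aa_to_tca"]), tca
        ),
        "pdh_contribution_tca": _safe_ratio(fx["V_PDH"], tca),
        "pc_contribution_tca": _safe_ratio(fx["V_PC"], tca),
        "glycolysis_atp_share": _safe_ratio(
            linear_combination(fx, DERIVED_FLUXES["glycolysis_atp"]), atp
        ),
        "respiration_atp_share": _safe_ratio(
            linear_combination(fx, DERIVED_FLUXES["respiration_atp"]), atp
        ),
        "pdh_to_pk": _safe_ratio(fx["V_PDH"], fx["V_PK"]),
        "ldh_to_pk": _safe_ratio(fx["V_LDH"], fx["V_PK"]),
    }


def inhibition_term_course(trajectory: SimulationTrajectory, effector: str,
                           K: float):
    """Time course of a non-competitive inhibition term ``1/(1 + I(t)/K)``.

    ``effector`` is a state name (e.g. extracellular lactate or ammonia);
    the returned series lies in (0, 1] and decreases as the inhibitor
    accumulates.
    """
    if K <= 0:
        raise ValueError("inhibition constant must be positive")
    if effector not in trajectory.species:
        raise KeyError(f"unknown inhibition effector {effector!r}")
    I = np.maximum(trajectory.state_series(effector), 0.0)
    return 1.0 / (1.0 + I / K)


# ---------------------------------------------------------------------------
# Delta-method flux confidence intervals
# ---------------------------------------------------------------------------

def flux_confidence(network, params, experiment, times, free_names,
                    covariance, dof, quantities=None, confidence=0.95,
                    rel_step=1e-4, sim_kwargs=None) -> pd.DataFrame:
    """Delta-method confidence bands for fluxes and derived quantities.

    For each requested quantity q(t; p), the gradient with respect to the
    free calibrated parameters is computed by central finite differences of
    full re-simulations (relative step 1e-4 per parameter); the CI is
    ``q +- t(0.975, dof) * sqrt(g' Sigma g)`` with Sigma the calibration
    covariance on the natural parameter scale. A singular covariance
    simply propagates to wide (infinite) intervals.
    """
    sim_kwargs = dict(sim_kwargs or {})
    times = np.asarray(times, dtype=float)
    covariance = np.asarray(covariance, dtype=float)

    def quantity_values(p):
        traj = simulate(network, p, experiment, **sim_kwargs)
        fx = {rid: np.interp(times, traj.times, traj.flux_series(rid))
              for rid in traj.reaction_ids}
        out = {}
        names = quantities or (
            list(traj.reaction_ids) + list(DERIVED_FLUXES) )
        for name in names:
            if name in fx:
                out[name] = fx[name]
            elif name in DERIVED_FLUXES:
                out[name] = linear_combination(fx, DERIVED_FLUXES[name])
            else:
                raise KeyError(f"unknown flux quantity {name!r}")
        return out

    base = quantity_values(params)
    names = list(base)
    # gradients: dict name -> (n_free, n_times)
    grads = {n: np.zeros((len(free_names), times.size)) for n in names}
    for i, pname in enumerate(free_names):
        h = abs(params[pname]) * rel_step
        if h == 0:
            h = rel_step
        up, dn = params.copy(), params.copy()
        up[pname] = params[pname] + h
        dn[pname] = max(params[pname] - h, 0.0)
        denom = up[pname] - dn[pname]
        q_up = quantity_values(up)
        q_dn = quantity_values(dn)
        for n in names:
            grads[n][i] = (q_up[n] - q_dn[n]) / denom

    tval = stats.t.ppf(0.5 + confidence / 2.0, dof)
    rows = []
    for n in names:
        g = grads[n]  # (k, T)
        var = np.einsum("it,ij,jt->t", g, covariance, g)
        half = tval * np.sqrt(np.maximum(var, 0.0))
        for t, v, hw in zip(times, base[n], half):
            rows.append((t, n, v, v - hw, v + hw))
    return pd.DataFrame(rows, columns=["time_h", "quantity", "value", "ci_low", "ci_high"])
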