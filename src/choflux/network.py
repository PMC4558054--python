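"""Metabolic network definition and per-cell flux evaluation.

The network (metabolites, reactions with stoichiometry, rate-law wiring)
is data, loaded from a YAML file, so the kinetic structure can be edited
without touching code. Every reaction rate is a product of

``Vmax * [substrate saturation terms] * [inhibition factors] * [activation]``

where substrate terms are Michaelis-Menten fractions in a species or in a
nucleotide ratio, inhibition is the separable non-competitive factor
``1/(1 + I/KI)`` and activation follows the non-essential activation law
attached to one designated substrate term. Reversible enzymes appear as
two irreversible reactions (forward and reverse) with mirrored
stoichiometry, so every individual flux is non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .parameters import ParameterSet
from .ratelaws import activation_core

__all__ = [
    "Metabolite",
    "SubstrateTerm",
    "RegulationTerm",
    "RateLawSpec",
    "Reaction",
    "BiomassComposition",
    "MetabolicNetwork",
    "ModelDefinitionError",
    "load_network",
    "flux_vector",
    "growth_rate",
    "mab_rate",
    "reaction_rate",
    "validate_network",
]

_COMPARTMENT_UNITS = {
    "extracellular": "mM",
    "intracellular": "mmol/(1e6 cells)",
    "scalar": None,
}


class ModelDefinitionError(ValueError):
    """The model file references an undeclared species or parameter."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    compartment: str  # extracellular | intracellular | scalar
    units: str | None = None

    def __post_init__(self):
        if self.compartment not in _COMPARTMENT_UNITS:
            raise ModelDefinitionError(
                f"unknown compartment {self.compartment!r} for {self.id}"
            )
        if self.units is None:
            object.__setattr__(self, "units", _COMPARTMENT_UNITS[self.compartment])


@dataclass(frozen=True)
class SubstrateTerm:
    """One Michaelis-Menten factor: a species id or a 'NUM/DEN' ratio."""

    species: str
    km: str  # parameter name

    @property
    def is_ratio(self) -> bool:
        return "/" in self.species


@dataclass(frozen=True)
class RegulationTerm:
    kind: str  # noncompetitive_inhibition | nonessential_activation
    effector: str  # species id or 'NUM/DEN' ratio
    constants: dict  # parameter names: {ki} or {ka, alpha, beta}
    substrate: str | None = None  # activation: which substrate term it couples to


@dataclass(frozen=True)
class RateLawSpec:
    vmax: str
    substrates: tuple
    regulation: tuple = ()
    reversible_pair: str | None = None


@dataclass(frozen=True)
class Reaction:
    id: str
    stoichiometry: dict
    rate_law: RateLawSpec
    name: str = ""
    reconstructed: bool = False


@dataclass(frozen=True)
class BiomassComposition:
    """Anabolic demand bookkeeping and the unit-conversion factors.

    The precursor demands themselves live in the growth / mAb reaction
    stoichiometries (mmol per 10^6 new cells, mmol per mg mAb); this type
    carries the conversion factors used for the consistency check between
    the cell dry weight, the mean protein molar mass and the stated
    biomass factor.
    """

    dry_weight_g_per_1e6_cells: float
    protein_molar_mass_g_per_mol: float
    biomass_mmol_per_1e6_cells: float
    mab_mmol_per_mg: float

    def factor_consistent(self, rtol: float = 0.01) -> bool:
        implied = self.dry_weight_g_per_1e6_cells / self.protein_molar_mass_g_per_mol
        implied_mmol = implied * 1000.0
        return abs(implied_mmol - self.biomass_mmol_per_1e6_cells) <= rtol * abs(
            self.biomass_mmol_per_1e6_cells
        )


@dataclass
class MetabolicNetwork:
    name: str
    metabolites: list
    reactions: list
    biomass: BiomassComposition
    growth_reaction: str = "V_growth"
    mab_reaction: str = "V_mAb"
    _compiled: "CompiledNetwork" = field(default=None, repr=False, compare=False)

    def species_ids(self, compartment=None):
        return [
            m.id
            for m in self.metabolites
            if compartment is None or m.compartment == compartment
        ]

    @property
    def dynamic_species(self):
        """Extracellular then intracellular species (the ODE concentration part)."""
        return self.species_ids("extracellular") + self.species_ids("intracellular")

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def compiled(self, params: ParameterSet) -> "CompiledNetwork":
        if self._compiled is None or self._compiled.param_names != tuple(params.names):
            self._compiled = CompiledNetwork(self, params)
        return self._compiled


# ---------------------------------------------------------------------------
# YAML loading
# ---------------------------------------------------------------------------

def _parse_rate(spec: dict) -> RateLawSpec:
    subs = tuple(
        SubstrateTerm(species=s.get("species") or s["ratio"], km=s["km"])
        for s in spec.get("substrates", [])
    )
    reg = []
    for term in spec.get("inhibition", []) or []:
        reg.append(
            RegulationTerm(
                kind="noncompetitive_inhibition",
                effector=term["species"],
                constants={"ki": term["ki"]},
            )
        )
    for term in spec.get("activation", []) or []:
        reg.append(
            RegulationTerm(
                kind="nonessential_activation",
                effector=term["effector"],
                constants={
                    "ka": term["ka"],
                    "alpha": term["alpha"],
                    "beta": term["beta"],
                },
                substrate=term.get("substrate"),
            )
        )
    return RateLawSpec(
        vmax=spec["vmax"],
        substrates=subs,
        regulation=tuple(reg),
        reversible_pair=spec.get("reverse_of"),
    )


def load_network(path) -> MetabolicNetwork:
    """Load a model-definition YAML file into a :class:`MetabolicNetwork`."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    metabolites = [
        Metabolite(id=m["id"], compartment=m["compartment"], units=m.get("units"))
        for m in doc["metabolites"]
    ]
    reactions = []
    for r in doc["reactions"]:
        rate = dict(r["rate"])
        rate.setdefault("reverse_of", r.get("reverse_of"))
        reactions.append(
            Reaction(
                id=r["id"],
                name=r.get("name", ""),
                stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                rate_law=_parse_rate(rate),
                reconstructed=bool(r.get("reconstructed", False)),
            )
        )
    cf = doc["conversion_factors"]
    biomass = BiomassComposition(
        dry_weight_g_per_1e6_cells=float(cf["dry_weight_g_per_1e6_cells"]),
        protein_molar_mass_g_per_mol=float(cf["protein_molar_mass_g_per_mol"]),
        biomass_mmol_per_1e6_cells=float(cf["biomass_mmol_per_1e6_cells"]),
        mab_mmol_per_mg=float(cf["mab_mmol_per_mg"]),
    )
    return MetabolicNetwork(
        name=doc.get("name", "model"),
        metabolites=metabolites,
        reactions=reactions,
        biomass=biomass,
        growth_reaction=doc.get("growth_reaction", "V_growth"),
        mab_reaction=doc.get("mab_reaction", "V_mAb"),
    )


# ---------------------------------------------------------------------------
# Compiled evaluation
# ---------------------------------------------------------------------------

class CompiledNetwork:
    """Index-array compilation of a network for fast, vectorised flux evaluation.

    Concentration input is a vector over ``network.dynamic_species`` (or a
    matrix with one column per state, for vectorised stiff-solver calls);
    output is the per-reaction flux vector (matrix).
    """

    def __init__(self, network: MetabolicNetwork, params: ParameterSet):
        self.network = network
        self.param_names = tuple(params.names)
        self.species = list(network.dynamic_species)
        self.sidx = {s: i for i, s in enumerate(self.species)}
        self.rids = [r.id for r in network.reactions]
        self.ridx = {r: i for i, r in enumerate(self.rids)}
        n_sp, n_rx = len(self.species), len(self.rids)

        def pidx(name):
            if name not in params:
                raise ModelDefinitionError(f"parameter {name!r} not in parameter table")
            return params.index(name)

        def check_species(name, rid):
            if name not in self.sidx:
                raise ModelDefinitionError(
                    f"reaction {rid}: species {name!r} is not declared"
                )
            return self.sidx[name]

        self.stoich = np.zeros((n_sp, n_rx))
        self.vmax_idx = np.zeros(n_rx, dtype=int)

        plain = []  # (rxn, sp, km)
        ratio = []  # (rxn, num, den, km)
        inhib = []  # (rxn, sp, ki)
        acts = []   # dicts
        for j, rxn in enumerate(network.reactions):
            for sp, coeff in rxn.stoichiometry.items():
                self.stoich[check_species(sp, rxn.id), j] = coeff
            self.vmax_idx[j] = pidx(rxn.rate_law.vmax)
            plain_slots = {}
            for term in rxn.rate_law.substrates:
                if term.is_ratio:
                    num, den = term.species.split("/")
                    ratio.append(
                        (j, check_species(num, rxn.id), check_species(den, rxn.id), pidx(term.km))
                    )
                else:
                    plain_slots[term.species] = len(plain)
                    plain.append((j, check_species(term.species, rxn.id), pidx(term.km)))
            for reg in rxn.rate_law.regulation:
                if reg.kind == "noncompetitive_inhibition":
                    inhib.append((j, check_species(reg.effector, rxn.id), pidx(reg.constants["ki"])))
                elif reg.kind == "nonessential_activation":
                    sub = reg.substrate
                    if sub is None:
                        if not plain_slots:
                            raise ModelDefinitionError(
                                f"reaction {rxn.id}: activation needs a plain substrate term"
                            )
                        slot = next(iter(plain_slots.values()))
                    else:
                        if sub not in plain_slots:
                            raise ModelDefinitionError(
                                f"reaction {rxn.id}: activation substrate {sub!r} "
                                "is not one of the reaction's substrate terms"
                            )
                        slot = plain_slots[sub]
                    if "/" in reg.effector:
                        num, den = reg.effector.split("/")
                        eff = (check_species(num, rxn.id), check_species(den, rxn.id))
                    else:
                        eff = (check_species(reg.effector, rxn.id), -1)
                    acts.append(
                        dict(
                            slot=slot,
                            eff=eff,
                            ka=pidx(reg.constants["ka"]),
                            alpha=pidx(reg.constants["alpha"]),
                            beta=pidx(reg.constants["beta"]),
                        )
                    )
                else:  # pragma: no cover - guarded at parse time
                    raise ModelDefinitionError(f"unknown regulation kind {reg.kind!r}")

        self._plain = tuple(np.array(x, dtype=int) for x in zip(*plain)) if plain else None
        self._ratio = tuple(np.array(x, dtype=int) for x in zip(*ratio)) if ratio else None
        self._inhib = tuple(np.array(x, dtype=int) for x in zip(*inhib)) if inhib else None
        self._acts = acts

        # state layout helpers for the simulator
        self.n_ext = len(network.species_ids("extracellular"))
        self.n_int = len(network.species_ids("intracellular"))
        self.growth_j = self.ridx.get(network.growth_reaction)
        self.mab_j = self.ridx.get(network.mab_reaction)

    # -- flux evaluation ---------------------------------------------------
    def fluxes(self, conc, theta):
        """Per-reaction flux vector for concentrations ``conc`` (clamped at 0).

        ``conc`` may be 1-D ``(n_species,)`` or 2-D ``(n_species, m)``;
        the result matches (``(n_reactions,)`` or ``(n_reactions, m)``).
        """
        conc = np.asarray(conc, dtype=float)
        single = conc.ndim == 1
        C = np.maximum(conc[:, None] if single else conc, 0.0)
        m = C.shape[1]
        theta = np.asarray(theta, dtype=float)

        v = np.repeat(theta[self.vmax_idx][:, None], m, axis=1)

        if self._plain is not None:
            p_rxn, p_sp, p_km = self._plain
            S = C[p_sp]
            Km = theta[p_km][:, None]
            frac = S / np.maximum(S + Km, 1e-300)
            if self._acts:
                for a in self._acts:
                    slot = a["slot"]
                    Ssub = C[p_sp[slot]]
                    KS = theta[p_km[slot]]
                    num_i, den_i = a["eff"]
                    if den_i >= 0:
                        den = C[den_i]
                        A = np.where(den > 0, C[num_i] / np.maximum(den, 1e-300), 0.0)
                        A = np.where((den <= 0) & (C[num_i] > 0), 1e9, A)
                    else:
                        A = C[num_i]
                    frac[slot] = activation_core(
                        Ssub, KS, A, theta[a["ka"]], theta[a["alpha"]], theta[a["beta"]]
                    )
            np.multiply.at(v, p_rxn, frac)

        if self._ratio is not None:
            r_rxn, r_num, r_den, r_km = self._ratio
            num = C[r_num]
            den = C[r_den]
            K = theta[r_km][:, None]
            frac = np.where(
                den > 0,
                num / np.maximum(num + K * den, 1e-300),
                (num > 0).astype(float),
            )
            np.multiply.at(v, r_rxn, frac)

        if self._inhib is not None:
            i_rxn, i_sp, i_ki = self._inhib
            fac = 1.0 / (1.0 + C[i_sp] / theta[i_ki][:, None])
            np.multiply.at(v, i_rxn, fac)

        if not np.all(np.isfinite(v)):
            bad = [self.rids[j] for j in np.where(~np.isfinite(v).all(axis=1))[0]]
            raise FloatingPointError(f"non-finite flux in reactions {bad}")
        return v[:, 0] if single else v

    def state_vector(self, state: dict) -> np.ndarray:
        return np.array([state[s] for s in self.species], dtype=float)


# ---------------------------------------------------------------------------
# Module-level operations
# ---------------------------------------------------------------------------

def flux_vector(network: MetabolicNetwork, state: dict, params: ParameterSet) -> dict:
    """Evaluate every reaction rate at a state given as ``{species: value}``."""
    comp = network.compiled(params)
    v = comp.fluxes(comp.state_vector(state), params.values)
    return {rid: float(v[j]) for j, rid in enumerate(comp.rids)}


def reaction_rate(network, reaction_id: str, state: dict, params: ParameterSet) -> float:
    """Rate of a single reaction (product of Vmax, saturation and regulation)."""
    return flux_vector(network, state, params)[reaction_id]


def growth_rate(network, state: dict, params: ParameterSet) -> float:
    """Specific growth rate mu (h^-1) at the given state."""
    return reaction_rate(network, network.growth_reaction, state, params)


def mab_rate(network, state: dict, params: ParameterSet) -> float:
    """Cell-specific mAb production rate q_mAb (mg (10^6 cells)^-1 h^-1)."""
    return reaction_rate(network, network.mab_reaction, state, params)


def validate_network(network: MetabolicNetwork, params: ParameterSet | None = None) -> dict:
    """Static consistency report for a network (empty ``issues`` = valid).

    Checks: species referenced by stoichiometry or rate laws are declared;
    orphan metabolites; rate-law parameters resolve in the parameter table;
    reverse reactions have mirrored stoichiometry; the biomass conversion
    factor matches dry weight / protein molar mass within 1%.
    """
    issues = []
    declared = set(m.id for m in network.metabolites)
    dynamic = set(network.dynamic_species)
    used = set()
    rxn_ids = {r.id for r in network.reactions}

    def species_refs(rxn):
        for sp in rxn.stoichiometry:
            yield sp
        for t in rxn.rate_law.substrates:
            yield from t.species.split("/")
        for reg in rxn.rate_law.regulation:
            yield from reg.effector.split("/")

    for rxn in network.reactions:
        for sp in species_refs(rxn):
            used.add(sp)
            if sp not in declared:
                issues.append(f"{rxn.id}: undeclared species {sp!r}")
            elif sp not in dynamic:
                issues.append(f"{rxn.id}: references scalar species {sp!r} in kinetics")
        coeffs = list(rxn.stoichiometry.values())
        if not any(c < 0 for c in coeffs):
            issues.append(f"{rxn.id}: no substrate (negative) stoichiometric coefficient")
        if not all(np.isfinite(c) for c in coeffs):
            issues.append(f"{rxn.id}: non-finite stoichiometric coefficient")
        pair = rxn.rate_law.reversible_pair
        if pair is not None:
            if pair not in rxn_ids:
                issues.append(f"{rxn.id}: reverse_of unknown reaction {pair!r}")
            else:
                fwd = network.reaction(pair)
                mirrored = {k: -v for k, v in fwd.stoichiometry.items()}
                for sp, c in rxn.stoichiometry.items():
                    # reverse may recruit extra cofactors; flag only sign clashes
                    if sp in mirrored and c * mirrored[sp] < 0:
                        issues.append(
                            f"{rxn.id}: stoichiometry of {sp} not mirrored against {pair}"
                        )
        if params is not None:
            names = [rxn.rate_law.vmax]
            names += [t.km for t in rxn.rate_law.substrates]
            for reg in rxn.rate_law.regulation:
                names += list(reg.constants.values())
            for name in names:
                if name not in params:
                    issues.append(f"{rxn.id}: unresolved parameter {name!r}")

    for m in network.metabolites:
        if m.compartment != "scalar" and m.id not in used:
            issues.append(f"orphan metabolite {m.id!r}")

    if not network.biomass.factor_consistent():
        issues.append(
            "biomass factor inconsistent with dry weight / protein molar mass"
        )

    n_params = None
    if params is not None:
        n_params = len(params)
    return {
        "issues": issues,
        "n_metabolites": len(network.metabolites),
        "n_reactions": len(network.reactions),
        "n_parameters": n_params,
        "reconstructed_reactions": [r.id for r in network.reactions if r.reconstructed],
        "valid": not issues,
    }
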