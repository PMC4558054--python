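# Methods

## Model structure

The model describes a stirred CHO cell culture by one ODE system spanning
three groups of state variables:

* **Extracellular concentrations** (mM): glucose, lactate, ammonia, and 18
  amino acids. Isoleucine and leucine are carried as a single pooled species
  (`ILE`) because they co-elute in the HPLC assay the data emulate.
* **Intracellular per-cell pools** (mmol per 10⁶ cells): glycolytic
  intermediates (G6P, F6P, FBP, PEP, PYR), TCA metabolites (CIT, AKG, MAL),
  ribulose-5-phosphate, intracellular glutamate, and the energy/redox
  nucleotides ATP/ADP/AMP, NAD/NADH, NADP/NADPH.
* **Culture scalars**: viable cell density Xv (10⁶ cells/mL), product titer
  (mg/L) and working volume (L).

Balance equations: `dXv/dt = μ·Xv`; extracellular species change at
`(Σ ν·v)·Xv·1000` mM/h (per-cell fluxes are mmol·(10⁶ cells)⁻¹·h⁻¹);
per-cell pools follow `dC/dt = Σ ν·v − μ·C`, the last term being dilution of
per-cell content by division (the dilution term can be switched off to test
the alternative convention, since it is not observable from extracellular
data alone); volume only changes at feed events.

Reaction rates are built from four primitives: Michaelis–Menten saturation
in each substrate, saturation in a nucleotide *ratio* (AMP/ATP, ADP/ATP,
NAD/NADH, NADP/NADPH and their inverses — ratios, not absolute pools, carry
the energetic regulation), a separable non-competitive inhibition factor
`1/(1+I/K_I)`, and Segel's non-essential activation law attached to one
designated substrate term. With α = β = 1 activation is exactly neutral; the
test suite asserts this identity network-wide. Reversible enzymes
(phosphoglucose isomerase, lactate dehydrogenase, glutaminase/glutamine
synthetase, glutamate dehydrogenase, glutamate transport, adenylate kinase)
are represented as forward/reverse irreversible pairs with separate maximal
rates, so every individual flux is non-negative and net direction emerges
from the pair.

Two inhibition conventions exist in the literature for the "non-competitive"
label: the Km-modifying form `V = Vmax·S/(S + Km(1+I/K_I))` and the
separable factor `V = Vmax·S/(S+Km) · 1/(1+I/K_I)`. The package exposes the
Km-modifying form as a standalone primitive, but wires the *separable*
factor into multi-substrate reaction rates: it composes cleanly with any
number of saturation terms, and it makes the reported "inhibition term" time
courses (e.g. lactate on glycolysis, ammonia on growth) exact multiplicative
factors of the corresponding flux rather than approximations.

Regulatory wiring: hexokinase is feedback-inhibited by G6P and activated by
AMP/ATP; PFK is inhibited by citrate and extracellular lactate and activated
by AMP/ATP; pyruvate kinase is inhibited by alanine and activated by F6P;
LDH is activated by AMP/ATP; reverse LDH is inhibited by pyruvate; forward
PGI is inhibited by PEP; the reverse alanine transaminase is inhibited by
glutamine, which produces the switch from alanine production to alanine
consumption once glutamine is depleted.

Growth is a multiplicative Michaelis–Menten product over the biomass
precursors — all modelled amino acids plus G6P (glycogen), citrate (lipids)
and R5P (nucleotides) — times non-competitive inhibition factors for lactate
and ammonia, each with its own constant. mAb synthesis has the same shape
over amino acids with its own (smaller) affinity constants. Precursor
demands use a biomass factor of 2.93×10⁻³ mmol amino acid per 10⁶ cells
(dry weight 3.15×10⁻⁴ g per 10⁶ cells over a mean protein molar mass of
107.5 g/mol — consistency enforced to 1% by `validate_network`) and
9.17×10⁻³ mmol per mg of antibody; ATP demands for growth and product
synthesis are lumped per unit of each flux.

## The shipped reference parameterization

The exact published equation set and parameter table for this cell line are
not distributed with the package; the shipped `model.yaml` /
`parameters.csv` are a *reconstruction* built from the rate-law grammar, the
regulatory wiring above, and the printed quantitative anchors:

* per-cell flux magnitudes at mid-exponential phase: glucose uptake
  ≈ 2×10⁻⁴, pyruvate dehydrogenase ≈ 1.6×10⁻⁵, oxidative PPP ≈ 3.5×10⁻⁶
  mmol·(10⁶ cells)⁻¹·h⁻¹;
* inhibition-term anchors: the lactate term on glycolysis starts at 0.89 in
  fed-batch (fixing K_d,LAC = 16 mM at 2 mM initial lactate) and the ammonia
  term on growth starts at 0.957 (fixing K_d,NH4 = 6.7 mM at 0.3 mM initial
  ammonia); K_m,G6P = 2.9×10⁻⁸ mmol/10⁶ cells and K_a,AMP/ATP = 0.09;
* a 20-member sensitive parameter subset (11 maximal rates, 4 affinity
  constants, 5 regulation constants) flagged in the parameter table.

Maximal rates were then solved so that every intracellular node is exactly
balanced at the Biogro-batch initial state (production = consumption +
growth dilution), which guarantees the simulation starts on, and relaxes
near, a physiological quasi-steady state. Reactions whose exact published
form is unknown — the isocitrate-dehydrogenase lump, malic enzyme, the
amino-acid-to-succinyl-CoA and histidine/arginine lumps, nucleotide
synthesis and NADPH re-oxidation — carry `reconstructed: true` in the model
file. The model has 37 reactions and 144 parameters; the count is reported
by `validate_network` rather than pinned.

Three stability-motivated design choices are worth knowing:

* Every ATP-consuming reaction carries a small-Km (10⁻⁶) ATP "guard" term
  so rates shut down smoothly as ATP approaches depletion — otherwise the
  stoichiometric ATP drain of glycolysis and anabolism can integrate the
  pool below zero.
* Reactions that must absorb surges (reverse PGI, lumped lower glycolysis,
  LDH) are given Km values above their substrate's resting pool, i.e.
  several-fold Vmax headroom; this is what lets lactate inhibition of PFK
  back-pressure through F6P and G6P into hexokinase instead of accumulating
  F6P without bound.
* HK and PFK take their energy sensitivity from the AMP/ATP activation
  rather than an ATP/ADP substrate term; an ATP/ADP term there creates a
  positive feedback (low ATP → less glycolysis → lower ATP) that makes the
  resting state unstable.

## Simulation

Stiff integration (BDF, relative tolerance 10⁻⁸, per-species absolute
tolerance at 10⁻¹⁰ of its typical magnitude) between feed events; a feed is
an exact stop–bolus–restart discontinuity. The default fed-batch policy
feeds daily from 24 h to the glucose set-point (the culture's initial
glucose), computing the bolus volume `v = V(G* − G)/(G_feed − G*)` so the
post-bolus concentration hits the set-point exactly; a conditional mode
feeds only below the 10 mM floor. Bolus mixing conserves every species'
total amount and the total cell count to machine precision (tested at
10⁻¹²). Sampling losses, evaporation, base addition and pH/DO/temperature
dynamics are not modelled (held constant experimentally). The model does not
describe cell death; trajectories past the time where viability would drop
below 95% are extrapolation and the calibration window excludes them.

## Sensitivity screening

Morris elementary effects on a 4-level unit grid with the canonical step
Δ = p/(2(p−1)) = 2/3, bounds at ±25% of each nominal value (35 repetitions
by default). Each repetition walks a random one-at-a-time trajectory
(k+1 model evaluations for k parameters); the elementary effect of a step is
the change in a *scalar* objective — the mean of |output/σ| over the 32
selected observables at all experimental sampling times, the same σ-weights
as the calibration — divided by Δ. Parameters are ranked by the absolute
mean of their elementary effects; the standard deviation flags
nonlinearity/interactions. Selection keeps |mean EE| ≥ 0.6 capped at the 20
top-ranked parameters. (The screening threshold is stated as a *high*-
sensitivity cut; the shipped subset contains exactly the 20 parameters at or
above 0.6.) Screening on the full 144-parameter set at 35 repetitions costs
≈ 5,000 culture simulations; tests and the acceptance script use a
documented reduced design (a named subset, 3–4 repetitions, one culture),
which is the package's own choice of problem size for its checks.

## Calibration

Weighted least squares `Σ((y_exp − y(p))/σ)²` over all cultures, outputs and
sampling times in scope, minimised with a bounded trust-region-reflective
solver on magnitude-normalised free parameters (`p/10ⁿ`, lower bounds 0),
single start from the supplied initial guess. The data window keeps records
from 24 h post-inoculation until viability falls below 95%, per culture;
phase schemes further split at 72 h. Simulation failures inside the
optimiser return a large finite penalty residual so the search continues.
Confidence intervals are linearised (Wald): `cov = s²(JᵀJ)⁻¹` with
`s² = SSR/(N−k)` and `CI = p̂ ± t(0.975, N−k)·se`; rank-deficient Jacobian
directions are flagged non-identifiable (infinite intervals) rather than
silently regularised. Subset comparison fits the all-data scheme first,
seeds every other scheme (batch / fed-batch / medium / phase) from those
estimates, and declares two estimates "not significantly different" when
their 95% intervals overlap.

## Dynamic MFA

Fluxes are re-evaluated along the simulated trajectory (consistency with the
simulator's stored fluxes is tested at 10⁻¹²). Derived aggregates are data
(linear combinations over reaction ids):

* ammonia production = V_GLDH + V_GlnT + V_SDHH + V_ASN + V_HISARGTA,
* TCA influx = V_GLDH + V_PDH + V_AlaTA + V_PC + 5·V_AAtoSUC,
* net ATP production = V_PGK + V_PK + V_AKGDH + V_PC + V_GlnT + 2·2.5·V_resp.

The three TCA-influx contributions (amino acids = V_GLDH + V_AlaTA +
5·V_AAtoSUC, PDH, PC) partition unity at every time point. The "ATP from
glycolysis" numerator (V_HK + V_PFK) and the appearance of V_GlnT and V_PC
in the *net ATP* sum are implemented exactly as conventionally printed even
though HK, PFK and PC are stoichiometric ATP consumers and glutaminase is
ATP-neutral; they are flux aggregates used as activity markers, not an ATP
balance. Ratio time points with a zero denominator are reported missing, not
zero. Flux confidence bands use the delta method — central finite
differences of full re-simulations with relative step 10⁻⁴ per calibrated
parameter, `CI = v ± t·√(gᵀΣg)` with Σ the calibration covariance on the
natural scale — and agree with Monte-Carlo parameter resampling within 15%
on the toy network.

## Synthetic data

The generator emulates the reference study conditions: four cultures (two
media × batch/fed-batch) inoculated at 2×10⁵ cells/mL; daily sampling with a
12-h option for the short Biogro batch; Biogro feed = base medium at 130 mM
glucose and 25 mM glutamine, PowerCHO feed = 2.5× concentrated medium at
100 mM glucose and 16 mM glutamine; the PowerCHO base glucose concentration
(30 mM) and the full amino-acid profiles are reconstructed values chosen to
be typical of rich CHO media, with PowerCHO deliberately richer in
aspartate, asparagine, serine, arginine and isoleucine. Noise is
multiplicative truncated-Gaussian, `value = truth·(1+ε)`, `ε ~ N(0, CV²)`,
truncated at zero, with per-class CV defaults of 10% (extracellular,
cells/titer) and 15% (intracellular) — placeholders for unpublished
per-analyte precisions, stated in outputs. The reported σ column is
CV·truth with a small floor so weights stay finite near zero signal.
Species below a configurable limit of detection are emitted as censored and
excluded from residuals (mirroring undetectable α-ketoglutarate, NADH and
pyruvate in the low-signal cultures). Synthetic viability stays at 100%
until a decline onset (55% of culture duration by default) then falls
linearly at 0.25%/h, so the 95%-viability data window is exercised. A
3-reaction toy network (substrate uptake → intermediate → product with one
product-inhibition term, fixed cell density) ships for fast
parameter-recovery oracles; at 5% CV its 95% intervals achieve ~94%
empirical coverage over 200 replicates.

## Known limitations

* The reference parameterization is a reconstruction: it reproduces the
  anchor fluxes, the inhibition-term anchors, and the Biogro/PowerCHO
  fed-batch performance pattern, but underpredicts the PowerCHO *batch*
  peak cell density and titer, and its late-culture ammonia inhibition is
  milder than the reported end-of-culture values (0.36–0.54 vs 0.28–0.37 at
  120 h). A genuine parameter table would slot in via `parameters.csv`
  without code changes.
* No cell-death/viability kinetics, gas-phase transfer, or glycosylation;
  batch-mode simulation past the viability window is extrapolation.
* Elementary balancing (C/N/charge) of the lumped reactions is not
  enforced; stoichiometries are pathway-level.
* Linearised CIs only; no profile likelihood or Bayesian posteriors.
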