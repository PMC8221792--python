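# Methods

This note documents the models, numerical choices and known limits of
`fluxmaint`. Everything quantitative stated here is computed by the
test suite or by `scripts/acceptance.py`.

## Flux prediction

FBA solves max/min c·v subject to S·v = 0 and bounds; pFBA then fixes
the objective at exactly its optimum (fraction 1.0) and minimizes total
absolute flux, with every reversible reaction represented by its
non-negative forward and reverse solver variables. LP
feasibility/optimality tolerances are requested at 1e−9 so that the
maintenance grid search makes reproducible feasibility calls; optimal
solutions are accepted only if max|S·v| ≤ 1e−6. Alternate optima
within the minimal-total-flux set are resolved by the solver (GLPK);
tests therefore assert on objective values, total flux and mapped
aggregate fluxes, never on individual fluxes of degenerate reactions.

Constraint policies: `point-fix` sets both exchange bounds to the
measured value (used by the computational mATP estimation), `interval`
sets them to value ± SD (used by the chemostat energetics). Oxygen is
never constrained. When tryptophan is unmeasured its uptake is fixed
to the smallest-magnitude measured amino-acid uptake, it being the
least abundant amino acid in biomass.

## Total NTP production

Total energy production of a flux state is the sum over reactions of
the positive net production of every nucleoside triphosphate (ATP,
GTP, CTP, UTP, TTP, ITP and deoxy forms). Two double-counting guards
are applied: each NTP species is pooled across compartments within a
reaction, so transporters (e.g. the adenine nucleotide translocase)
contribute nothing; and reactions whose ids match a configurable
exclusion prefix list (default `NDPK`, the nucleoside-diphosphate
kinases) are skipped, since phosphate transfer between NTP pools moves
energy rather than producing it. Whether the original analysis
excluded kinase interconversions is not documented; the exclusion list
is this package's choice and is configurable.

## Maintenance estimation (grid search)

For each candidate mATP the maintenance reaction is constrained as an
equality (both bounds), growth is maximized by pFBA, predictions are
mapped into the ¹³C namespace, and the median relative error over the
filtered experimental fluxes is recorded. The default grid is 0–40
mmol·gDW⁻¹·h⁻¹ in steps of 0.25; the step resolves between-dataset
differences of ~0.5 without excessive LP calls. Ties in the minimal
median error break toward the smaller mATP (parsimony of the energy
demand). The joint estimate divides the summed per-dataset medians by
the number of feasible datasets at each grid value, since higher mATP
values knock out more datasets. The small-flux filter uses absolute
values in numerator and denominator (|vₑ|/max|vₑ| < 0.01), so the
cutoff is direction-independent. Unmapped ¹³C reactions are reported
and excluded from scoring, never silently dropped.

## Chemostat bookkeeping

D = F/V with F from an OLS slope of cumulative feed mass (medium
density 1 g·mL⁻¹) and V = 270 mL by default; μ = D·Nt/Nv (≥ D, with
equality only at 100% viability); q = (Cout − Cin)·D/X with X from
viable density × cell dry mass (default 264 pg, overridable per
record). Standard deviations follow the usual first-order rules —
σ_C = |C|·√((σ_A/A)² + (σ_B/B)²) for products/quotients and
σ_C = √(σ_A² + σ_B²) for sums/differences. The source text prints the
product/quotient prefactor ambiguously (as "1/C"); the standard
relative-error form |C| is implemented, since only that form is
dimensionally consistent with the reported rate uncertainties.

Steady-state stability: OLS of each monitored parameter against time;
stable iff the 95% CI of the slope contains zero; with < 3 points the
result is flagged insufficient rather than silently stable; an
optional per-parameter instrument-error threshold marks significant
but tiny drifts as within measurement error (thresholds are
configuration with no universal default).

Carbon recovery = (C secreted + μ·C_biomass)/(C taken up), with the
biomass carbon content computed from the biomass reaction's elemental
composition. On noise-free synthetic steady states this is exactly
1.000 because the toy network is elementally balanced and the
generator emits a CO₂ "measurement" closing the balance; in real
cultures CO₂ is usually not measured and recovery reflects only the
liquid-phase species.

## Experimental maintenance determination

Per steady state, exchange and growth bounds are applied as intervals
(± SD), essential amino-acid uptakes that cannot sustain the measured
growth are widened to the model's minimal requirement (computed by
uptake minimization at fixed growth; in the toy model essential amino
acids feed biomass only, so this never alters the ATP accounting), ATP
hydrolysis is maximized by pFBA and total NTP production is recorded.
Infeasible states are repaired by relaxing the lower bounds of
secretions in 5% steps to a 40% cap — a generalization of the ad-hoc
25–40% relaxations such reconciliations need in practice — with every
relaxation logged; upper bounds always stay at the measured values.
The maintenance fit is unweighted OLS of ATP production on μ
(weighting is reserved for the flux-comparison fits): the intercept is
mATP with its standard error, the slope is in mmol ATP·gDW⁻¹, and
Y_ATP^max = 1000/slope in g·mol⁻¹ with a first-order (delta-method)
standard error.

## Statistics

Weighted fits use weightᵢ = 1/(CI widthᵢ); zero widths are capped at
the largest finite weight (to avoid infinite leverage), missing widths
receive the median weight, and if no width is informative the fit
falls back to equal weights. The maintenance-effect test stacks both
prediction sets with a 0/1 group indicator, fits vp ~ ve + g + ve:g,
reports the interaction p-value, and compares the nested models by a
likelihood-ratio χ² with 2 df. Tests are two-sided at α = 0.05 with no
multiple-testing correction.

## The toy model

Compartments e/c/m; ~70 reactions, ~65 metabolites (BiGG-style
formulas and charges). Energy metabolism: a lumped glycolysis
(glc → 2 pyr + 2 ATP + 2 NADH), a hexokinase/G6P branch feeding the
oxidative PPP (2 NADPH + CO₂ per G6P) with a non-oxidative return
(6 Ru5P → 5 G6P + Pi), lactate dehydrogenase and export, a
malate–aspartate-style NADH shuttle, pyruvate dehydrogenase, a lumped
TCA turn (AcCoA → 2 CO₂ + 3 NADH + FADH₂ + GTP), and glutaminolysis
via cytosolic and mitochondrial glutaminase (the compartment duplicate
the mapping rules need) with full glutamate oxidation. Essential amino
acids (his, lys, trp) are medium-only and fully oxidizable; the
nonessential ala/asp/ser have reversible synthesis reactions. A
glucose-6-phosphatase completes a futile cycle with hexokinase, giving
the network a physiological ATP sink under point-fixed exchanges.

Oxidative phosphorylation is proton-explicit: the NADH–ETC lump pumps
10 H⁺ per NADH (plus one consumed chemically), the FADH₂ branch 6 H⁺,
and ATP synthase translocates 4 H⁺ per ATP, so P/O(NADH) = 2.5 and
P/O(FADH₂) = 1.5 are emergent; `set_po_ratio(p)` rescales the pumping
to 4p (FADH₂ branch proportionally at 0.6·4p) and an FBA oracle — all
exchanges closed, a fixed water-splitting NADH-regeneration probe in
the matrix, ATP hydrolysis maximized — returns p to LP precision for
p ∈ [2, 3]. At P/O 2.5 the maximal ATP yield is 32.5 per glucose: the
textbook 32 (25 from 10 NADH, 3 from 2 FADH₂, 2 GTP, 2 glycolytic)
plus 0.5 from the protons the pyruvate and phosphate symporters
deposit in the matrix.

Every reaction except biomass, maintenance and exchanges is closed
elementally and in charge by construction: the builder solves the
water and proton coefficients of each reaction and raises if any other
element fails to balance.

Two biomass variants differ in protein fraction (0.56 vs 0.70, the
low-protein one compensating with more carbohydrate, lipid-precursor
and nucleotide mass); amino-acid coefficients use a 110 g·mol⁻¹ mean
residue mass and mole fractions with tryptophan least abundant. The
growth-associated ATP demand defaults to 150 mmol·gDW⁻¹ — deliberately
lumping polymerization, transport and assembly costs so that the
ATP-vs-growth slope (and hence Y_ATP^max ≈ 6.6 g·mol⁻¹) and the
resulting growth rates (~0.02–0.06 h⁻¹) sit in the range observed for
mammalian cells in culture.

## Synthetic data generation

**¹³C datasets.** A nutrient environment is sampled per dataset
(glucose −0.20 to −0.38, glutamine −0.03 to −0.06 mmol·gDW⁻¹·h⁻¹,
oxygen replete, essential amino acids offered moderately above the
biomass requirement so the surplus is catabolized — the energy-limited
regime of cells in rich media), the maintenance reaction is fixed at
the true mATP, and pFBA maximizes growth; infeasible draws are
resampled deterministically. The realized solution provides both the
"measured" exchange rates (glucose, glutamine, lactate and the
essential amino acids; ammonium and the nonessential amino acids are
deliberately unmeasured, as in typical literature datasets — and
necessarily so, since a fully measured exchange panel pins growth at
every grid value and destroys the identifiability of mATP) and the
¹³C fluxes, projected through a 13-entry mapping table that exercises
compartment merging, parallel summation and signed net lumping. Noise
is multiplicative Gaussian with configurable CV (default 10%),
truncated at ±3σ to avoid sign flips — ¹³C flux uncertainties are
roughly proportional to magnitude; confidence intervals are set to
±1.96·CV·|v|.

**Chemostat runs.** For each dilution rate, μ = D/viability (default
95%), the per-gDW state is solved with maintenance fixed at the truth,
essential amino-acid availability and glutamine uptake scaling with μ
(all growth-dependent energy terms proportional to μ, so the intercept
of the ATP line is exactly the planted maintenance), and glucose
uptake minimized — a substrate-limited culture wastes nothing. Biomass
concentration follows from the glucose balance at a 2 mM residual;
outlet concentrations from Cout = Cin + qX/D (carbon-balanced by
construction, with CO₂ emitted as a closing pseudo-measurement); feed
mass, cell counts and concentrations are then noised at the configured
CV. The true Y_ATP^max is an emergent property of the network; it is
obtained by probing the same steady-state solver at two growth rates
(`implied_atp_line`) and recorded with the truth. The reconstruction
pipeline (rates → interval constraints → ATP maximization → OLS) is
exercised against it end to end.

## Problem sizes

Validation runs at desk scale: the maintenance grid search solves 161
pFBA problems per dataset in under a second; recovery statistics use
20 datasets; confidence-interval coverage uses 100 seeded chemostat
replicates of 11 dilution rates; the pFBA oracle enumerates all basic
solutions of 50 random 8-reaction networks; Monte-Carlo oracles use
10⁶ draws.

## Known limitations

- The toy network lumps entire pathways into single reactions; its
  flux values are internally consistent but not literature CHO fluxes,
  and passing recovery tests demonstrates correctness of the pipeline,
  not predictive accuracy on real CHO data.
- Synthetic noise is independent across observations; real ¹³C flux
  estimates are correlated through the fitting procedure, so real
  recovery errors would be larger than the synthetic ones.
- The chemostat generator emits steady states only (no transients, no
  steady-state multiplicity) and a CO₂ rate that real liquid-phase
  assays do not provide.
- No thermodynamic or loopless constraints; the futile
  hexokinase/phosphatase cycle is suppressed by pFBA parsimony, not by
  free-energy arguments.
- SBML export mirrors subsystems as group annotations; model
  provenance fields (biomass ids, maintenance id, ETC specification)
  are carried only by the native JSON dialect, and SBML loading falls
  back to id conventions (`BIOMASS*`, `ATPM`).
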