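# Methods

## Modelling framework

The package analyses C3 leaf energetics with diel flux-balance analysis
(FBA): a linear-programming prediction of steady-state fluxes from reaction
stoichiometry, bounds and an optimisation objective.  A *diel* model is a
day-phase and a night-phase copy of a core stoichiometric network that share
no metabolites; the phases are coupled exclusively through storage linkers,
one irreversible day→night and one irreversible night→day route per storage
pool (starch in the chloroplast; sucrose, malate, citrate, the amino-acid
pool and nitrate in the vacuole).  Directed linkers make storage
conservation (what one phase stores, the other releases) an identity of the
stoichiometry rather than a property to verify, and give per-direction FVA
ranges.  We considered routing both directions through an explicit
phase-neutral pool metabolite; the direct paired-reaction form is
equivalent at steady state with two fewer columns per pool and was kept.
Day and night are not modelled with explicit lengths; a configurable
day:night scale factor between stored amounts defaults to 1
(stoichiometric equivalence).

The flux unit is µmol m⁻² s⁻¹ throughout.  All bench-unit conversions
happen at the boundary:

* 1 nmol min⁻¹ g⁻¹ FW → µmol m⁻² s⁻¹ divides by (leaf area per g fresh
  weight) × 60 × 1000.  The published conversion chain for Arabidopsis
  rounds its intermediates (1 g DW = 11.4 g FW, 1 g FW = 0.0043 m²), giving
  the factor 0.00387597; `ConversionFactors` carries `area_per_g_fw=0.0043`
  explicitly as the default and recomputes from the raw geometry
  (SLA 50 m² kg⁻¹ DW × dry:fresh 0.088 → 0.0044 m², factor 0.003788) when
  the intermediate is set to `None`.  The two differ by ~2%; we follow the
  published chain so capacity caps land on the published values.
* per mg protein routes through 5.7 mg protein g⁻¹ FW.
* per mg chlorophyll requires a chlorophyll density with **no silent
  default**; the value 136 mg chl m⁻² shipped as `IMPLIED_CHL_PER_AREA` is
  back-computed from the published input/output pair
  (0.9 µmol mg⁻¹ chl h⁻¹ → 0.034 µmol m⁻² s⁻¹) and documented as implied,
  not measured.

## Constraints

**Light.**  Only PSII, PSI and the cyclic route consume photons.  A single
coupling constraint sets summed day-phase photon use equal to (or, in the
parsimonious-light mode, bounded above by) 90% of incident PPFD; the 10%
reflectance/transmission loss is applied to the right-hand side rather than
through a pseudo-reaction (simpler duals, same optimum).

**Output.**  The leaf's metabolic output is ratio-locked: for each
component the day+night drain fluxes sum to proportion × scale, with one
scale variable shared across components.  This makes CO2 matching a
one-dimensional search and leaves the day:night export split to the LP
(phloem export can run at night from stores).  The source-leaf composition
is 0.7 sucrose : 0.3 amino acid by mole — a documented stand-in, since
measured phloem-sap proportions are not part of this package — and the
growing leaf uses a single lumped biomass drain that is deliberately more
ATP-expensive per carbon.

**Capacity caps.**  Vmax values tighten bounds monotonically
(`min(existing, vmax)`, both directions for reversible reactions): PPDK
0.034, phosphorylating NAD-GAPDH 93, nonphosphorylating NADP-GAPDH 0.33,
chloroplast malate valve 0.75 µmol m⁻² s⁻¹.

## Solving

pFBA minimises Σ|v| over *all* reactions (storage linkers included by
default; excludable by flag) on the solver's split forward/reverse
variables.  FVA recomputes the pFBA optimum T, imposes Σ|v| ≤ T (plus 1e-9
numerical slack), and minimises/maximises each reaction.  A flux is flagged
*reliable* when its FVA range is below 10% of the pFBA reference flux; at
reference ≈ 0, where a relative rule is undefined, the flag uses an
absolute 1e-6 window.  Alternative optima are deliberately not broken by
tie rules — FVA ranges are the published interface for ambiguity, and
conclusions should be drawn only from reliable fluxes.

CO2 matching evaluates daytime net CO2 exchange under pFBA at a trial
output scale, brackets the target by geometric expansion (detecting the
light-limited regime, where larger scales go infeasible, and reporting the
maximum achievable assimilation), checks monotonicity at the sampled
points, and bisects to |A_model − A_curve| ≤ 1e-4 (60-iteration budget;
log2(range/tol) ≈ 24 in practice).  LP feasibility tolerance is 1e-9;
package-level checks (steady state, energy closure) use 1e-6.

LP-backend correctness is cross-checked two independent ways in the test
suite: exhaustive vertex enumeration of the flux polytope on ≤12-reaction
networks (with v=0 hyperplanes added for the piecewise-linear pFBA
objective; FVA oracle restricted to irreversible networks where the
total-flux lock is linear), and cobrapy's own pfba/FVA routines.

## Energy accounting

Cofactor ledgers sum Σ max(0, s·v) (production) and Σ max(0, −s·v)
(consumption) over reactions confined to one compartment; reactions
spanning compartments (ANT, NTT) are booked as carrier imports/exports.
Reducing equivalents never cross membranes as species, so NAD(P)H closure
is local by construction; their transfer is reported through the named
shuttles, which are declared by tags at model build (graph inference of
shuttle cycles is ambiguous at genome scale).  Sign convention:
organelle→cytosol positive, ANT export positive, NTT import positive — so
the peroxisomal malate-OAA shuttle reads negative in normal operation
(malate flowing *into* the peroxisome).  The cyclic:linear
electron-transport fraction is measured on an electron basis as the ratio
of cyclic to PSII photon flux (one photon ≙ one electron on each route).

## The synthetic leaf network

The toy network (~97 reactions, 93 metabolites, 7 compartments) emulates
the energetic structure of a compartmented leaf core-metabolism model.
Every non-boundary reaction is elementally and charge balanced against
explicit formulas (checked at build time and again by `validate_balance`).
Massless book-keeping tokens carry energy coupling: proton-motive-force
quanta (`pmf_p`, `pmf_m`, one per translocated H⁺), electron pairs between
the photosystems, and a carboxylation:oxygenation token that pins
Vc/Vo = 3 by steady state (set the ratio to ∞ to close the oxygenase
branch, or `None` to uncouple it).  Chemical protons are exchangeable
across membranes through uniporters — the energetic gradient lives in the
pmf tokens, not in the H⁺ species — which avoids spurious proton deadlocks
in lumped compartments.

Key stoichiometric parameters (all exposed on `ToyLeafParams`):

| parameter | default | meaning |
|---|---|---|
| photons_per_nadph_linear | 4 | 8 photons per 2 NADPH, linear chain |
| hplus_per_atp_chl | 14/3 | CF0F1 H⁺/ATP |
| atp_per_nadph_linear | 9/7 ≈ 1.286 | 12 lumen H⁺ per 2 NADPH at 14/3 |
| atp_per_photon_cyclic | 3/7 ≈ 0.429 | 2 H⁺ per cyclic photon |
| p_o_ratio_mito | 2.5 | ATP per NADH, oxidative phosphorylation |
| vc_vo_ratio | 3.0 | photorespiratory load |
| maintenance ATPase | 4.0 day and night | see below |

These canonical values preserve the ordering that respiring one
NAD(P)H-equivalent in the mitochondrion yields ≈1.94× the ATP per photon of
the linear chloroplast chain — the energetics behind every light-parsimony
result.  The maintenance ATPase (4 µmol ATP m⁻² s⁻¹ per phase, cytosolic)
is sized from typical leaf maintenance respiration of ~0.8 µmol CO2 m⁻²
s⁻¹ at ~5 ATP per CO2; it is the main "other" cytosolic ATP demand and the
quantity against which shuttle capacities compete.

Two phase-specific blocks are part of the toy's study conditions: the NTT
is clamped in the day phase (the transporter energises plastids in
darkness, not illuminated chloroplasts), and the mitochondrial pyruvate
dehydrogenase complex is clamped in the day phase (the complex is
phosphorylated/inactivated in the light, which is what keeps daytime
TCA-cycle flux low in leaves).  The PDH day-block gives the toy the
behaviour established for diel leaf models — nocturnal vacuolar citrate
supplying daytime 2-oxoglutarate for amino-acid synthesis — and prevents a
small network from trivially running a daytime TCA cycle that real leaves
do not.  Dissipation routes (a lumped water-water cycle, futile plastid
ATPase, proton leaks, the alternative oxidase) make the equality-light mode
feasible at any PPFD, standing in for the xanthophyll-cycle-type sinks of
larger models.

The light-response fixture is a non-rectangular hyperbola
A(I) = (φI + A_max − √((φI+A_max)² − 4θφI·A_max))/(2θ) − R_d with
φ = 0.06, A_max = 18 µmol m⁻² s⁻¹, θ = 0.8, R_d = 0 — realistic for an
Arabidopsis rosette leaf but explicitly a fixture, **not** digitized
gas-exchange data.

**What the toy does and does not show.**  The toy reproduces the structure
of the energetic argument: which shuttles exist, their stoichiometric
couplings, the photon economics of respiration vs export, photorespiratory
NADH bookkeeping, and day/night storage coupling.  It does not reproduce
genome-scale numbers: its output demand, transport cost inventory and
biomass recipe are lumped, so quantities like the light-use fraction (75%
at PPFD 200 here) differ from genome-scale values; tests and acceptance
checks on scenario outcomes are therefore property-based (orderings,
signs, zeros, closures) rather than numeric reproductions.  Problem sizes
were chosen to keep every scenario under a second per solve (a 206-column
LP, ~30 LPs per scenario including FVA on the key reactions).

## Scenario matrix

S1 free shuttles, equality light; S2 chloroplast ATP-export capacity caps;
S3 light as upper bound (+ light-minimisation comparison); S4 = S3 with
daytime mitochondrial ATP synthase knocked out; S5 = S3 with the malate
valve capped at 0.75; S6 chloroplast ATP export blocked (feasibility
probe); S7 all chloroplast NAD(P)H export blocked (nocturnal citrate
probe); S8 growing leaf (biomass output).  All are source leaves at PPFD
200 unless stated.  Scenario results are written even when FVA marks key
fluxes unreliable; the reliability column travels with the tables so
downstream claims can apply the 10% rule.

## Known limitations

No kinetic or regulatory detail (shuttle directionality is set by
steady-state economics, not NADH/NAD poise); no explicit day:night length
ratio; no thermodynamic constraints; the vacuole stores pools without
tonoplast transport costs; the amino-acid pool is a single glutamate-like
species; and the FVA oracle covers only tiny networks — genome-scale
correctness rests on the LP backend and the cobrapy cross-checks.
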