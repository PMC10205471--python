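# Methods

This note records the scientific model behind `hgtrade`, the assumptions it
makes, the parameters that matter, what the synthetic worlds do and do not
emulate, and the numerical and design choices taken where the design was
genuinely open.

## Scope and overall structure

The package quantifies how international trade relocates mercury emissions,
environmental Hg levels, dietary methylmercury (MeHg) exposure and the
attendant health burden, by comparing the actual ("with trade") world with a
counterfactual ("no trade") world in which every country produces its own
consumption basket domestically. The chain is: embodied-emission accounting
→ counterfactual gridded inventory → environmental response → exposure →
health endpoints and valuation → Monte Carlo uncertainty. Each stage is a
module with an explicit data contract; `run_pipeline` wires them together
and a single seed fans out to per-stage seeds via
`(seed·1000003 + crc32(stage)) mod 2³¹`.

## Embodied-emission accounting

Standard environmentally extended MRIO attribution. The flow matrix is
computed for *all* region pairs including the diagonal, so that row sums
equal production-based (PBA) totals and column sums consumption-based (CBA)
totals — both conservation laws are tested, and the counterfactual stage
needs the CBA totals. The per-region attribution uses the full multiregional
Leontief inverse with the emission-intensity vector zeroed outside the
source region; the off-diagonal restriction is applied only when reporting
the embodied trade share. Inventory source categories (e.g. fuel combustion,
non-ferrous smelting, waste burning) map onto MRIO sectors through a
user-supplied many-to-one mapping (`aggregate_sources`); no concordance is
hard-coded, and sources with no monetary output of their own (such as
artisanal gold mining) are allocated to whichever sector the user's mapping
names.

Numerics: `(I − A)⁻¹` is obtained by LU factorisation, never explicit
inversion, with a residual check at 1e-10 and a spectral-radius diagnostic
on failure. Flow-matrix entries smaller than 1e-12 of the largest entry are
set to zero: they are LU roundoff, and suppressing them makes the autarky
null (`trade_share = 0` ⇒ strictly diagonal flows ⇒ bit-identical
scenarios) exact rather than approximate.

## The "no trade" counterfactual

Assumption: trade partners could manufacture their imports domestically at
the exporter's emission level, so each country's total becomes its CBA total
while the *spatial pattern* of its production is retained — within each
country's mask, `no_trade = with_trade × (cba/pba)`. Global emissions are
conserved by construction because ΣPBA = ΣCBA. Rescaling is per country
total, not per sector layer (a per-layer variant would need a gridded
inventory per sector, which the data contract does not assume). Fractional
border cells are rescaled in proportion to the mask weight, so a cell shared
between countries cannot be double-counted. A country with zero production
but positive consumption has no pattern to scale; its CBA total is spread
uniformly over its masked cells with a logged warning. No economic
re-equilibration (prices, substitution) is attempted — the counterfactual is
deliberately an accounting construct.

## Transport surrogate

A full coupled atmosphere–ocean–land simulation is out of scope; the
surrogate keeps the two properties every downstream equation actually uses:
**linearity** of the annual-mean response in emissions, and a
**latitude-dependent deposited fraction** reflecting faster atmospheric
oxidation (hence more local Hgᴵᴵ deposition) near the 40° band than at the
equator.

Per source cell the deposited fraction is `α(lat) + global_mixing`, where
`α(lat)` ramps linearly in `|lat|` from `local_fraction_min` (default 0.2)
at the equator to `local_fraction_peak` (default 0.6) at `peak_latitude`
(default 40°), clamped poleward. The linear-in-|lat| shape is a package
choice; the mechanism constrains only the ordering α(equator) < α(peak).
The `α(lat)` share is split between the source cell and `advection_cells`
downwind cells (eastward by default, matching mid-latitude westerlies and
the picture of deposition spilling over a coast's eastern boundary) with
exponentially decaying weights; `global_mixing` (default 0.1) is deposited
uniformly; the remainder stays in the long-lived well-mixed pool and is
reported in an explicit mass ledger, never lost silently. Parameter
validation rejects `α_peak + global_mixing > 1`.

Environmental responses: deposition `D = background_D + op·E`; plankton
MeHg `P = ocean·(background_P + plankton_gain·op·E)` (marine MeHg is
methylated from deposited inorganic Hg, so a linear local gain is the
minimal faithful structure); soil
`S = background_S·(1 + soil_gain·op·E/deposition_norm)` with
`soil_gain ≤ 0.01`, reflecting the soil reservoir's enormous mass and
lifetime — scenario-induced soil changes stay below 1%. `deposition_norm`
exists so the soil response is linear (superposition holds to 1e-10, a
tested invariant) yet bounded: the pipeline freezes it at the peak
with-trade deposition anomaly, and both scenarios share that one scale so
proxy ratios are undistorted. Backgrounds stand for natural and legacy
re-emitted mercury (the majority of the annual flux) and are identical
across scenarios.

Defaults (`background_D = 0.5` Mg/yr/cell, `background_P = 1` pM,
`background_S = 50` ng/g, `plankton_gain = 0.05` pM per Mg/yr·cell) are
chosen so that on the demo grid the anthropogenic anomaly is a minority
share of gross deposition, as it is in reality; they set scales, not
science, and every tested identity is scale-free.

## Exposure

With-trade exposure is `Σ pathway I·C` in µg/day. The no-trade exposure
rescales each pathway by its proxy ratio: seafood by catch-weighted marine
plankton MeHg (each country weights the global plankton field by its own
normalized fish-catch distribution; countries without marine catch are
*missing*, never zero), freshwater fish by population-weighted atmospheric
deposition within national boundaries (no transboundary watershed logic),
rice by mask-weighted mean soil Hg. Food consumption patterns are held
fixed across scenarios. Pathways with zero intake skip their ratio entirely,
so a missing proxy can never produce a 0/0; a zero or missing with-trade
proxy under positive intake is a hard error. The per-pathway delta
decomposition is exact by construction and reported as
`no_trade − with_trade` (positive where trade is protective).

## Health endpoints and valuation

Fetal IQ loss is linear with no threshold: `ΔIQ = γλβ·dose` points per
fetus, scaled by births for country totals. Adult FHA deaths are log-linear:
`ΔCF = Σ_g POP_g·Cf_g·ω·(1 − e^(−φλβ·dose))`, summed over genders exactly,
bounded above by `ω·Σ POP_g·Cf_g`, and within 1% of its linearisation for
exponents ≤ 0.01 (tested). `ω` is the causality probability expressing the
epidemiological uncertainty of the cardiovascular association.

The body-weight convention is explicit: `bw_mode="multiply"` (default)
takes `dose = E·BW` following the multiplicative form of the endpoint
equations as written; because the standard one-compartment intake→blood
chain is usually stated per kg body weight, `bw_mode="divide"` is provided —
**the right choice depends on the provenance of β, and the two differ by
BW², so this is the single most consequential configuration flag.**

The dose–response chain (β, λ, γ, φ, ω) has no defensible universal default
and is therefore required configuration; the example YAML ships
literature-magnitude placeholders that are labelled illustrative.
Monetisation uses `EL` = $18,832 per IQ point (2008 USD) and `VSL` =
$6.3 million (2005 USD) as defaults, brought to 2020 USD by user-supplied
deflators (none are bundled; missing deflators are a configuration error).
Optionally the VSL scales with national GDP per capita with elasticity 1
relative to a reference GDP; elasticity 0 recovers the flat-VSL case.
Countries with missing demographics propagate as explicit missing flags,
excluded from global sums with a logged count — never silent zeros.
Impacts are evaluated on each scenario's absolute exposure and then
differenced (matching a per-scenario summary table); a `difference` mode
that feeds ΔE through the dose–response once is provided, and the two agree
exactly for the linear IQ endpoint.

## Monte Carlo uncertainty and NRMSD

Four components — food intake, food MeHg concentration, dose–response,
economic valuation — are modelled as *systematic* multiplicative factors:
one draw per component per iteration, shared across countries, because the
published component bounds describe global biases, not independent
per-country noise. Each factor is log-normal with its 2.5/97.5 percentiles
fitted to the component's stated relative bounds (defaults [−47, 42]%,
[−37, 63]%, [−59, 147]%, [−70, 26]%); the fitted (µ, σ) are exposed for the
record. The default run repeats the health computation 1,000 times and
reports 2.5/97.5 percentiles next to the unperturbed point value (which the
percentile band need not contain, since the fitted factors' median is not
1 for asymmetric bounds). Draws that raise are recorded as failed; more
than 1% failures aborts with diagnostics, preventing silent survivorship
bias. NRMSD is RMSD normalised by the observed range by default
(switchable to mean normalisation), with a zero-range guard.

## Synthetic worlds: what they emulate and what they don't

The generator reproduces the *structure* the analysis assumes: a balanced
economy (x = Z·1 + Y·1 exactly; technical-coefficient columns drawn with
sums in (0.2, 0.55) so the Leontief series converges by construction, with a
rescale-by-1.1ρ guard for degenerate corners); a configurable import share
`trade_share` (default 0.4, placing the embodied trade share near one half,
the regime of interest) applied to both intermediate and final sourcing so
autarky is an exact limit; log-normal sectoral intensities times a
developed/developing multiplier (`intensity_gap`, default 5, recoverable
from the generated data); a global emission total anchored at 1,833.3 Mg/yr;
countries as contiguous longitude strips with fractional border rows,
developed ones centred near 40° and developing ones near the equator;
coastal countries with normalized fish-catch weights on nearby ocean cells
and seafood-heavy diets, inland countries rice-heavy with zero marine
catch.

Not emulated: real sector magnitudes or price structure, seasonality and
meteorology, atmospheric chemistry and speciation, ocean circulation,
food-trade reallocation (fish eaten where caught vs consumed beyond the
catch weighting), within-country heterogeneity, and multi-year dynamics.
Passing tests therefore demonstrate the *identities and mechanisms* of the
chain (conservation, linearity, sign structure, decompositions, interval
calibration) — not predictive skill on real-world magnitudes.

## Problem sizes

The demo configuration runs 10 regions × 4 sectors on a 36 × 72 grid with
200 Monte Carlo draws and completes in a few seconds on one CPU; the test
suite uses smaller worlds (up to 12 regions × 6 sectors, grids up to
18 × 36) and 1,000-draw Monte Carlo where calibration is being tested.
These sizes are the package's chosen demonstration scale: every identity
tested is size-free, and all generators accept larger dimensions.

## Known limitations

* The transport surrogate's α(lat) profile is an assumption-preserving
  stand-in, not a fitted oxidation-rate profile; only scenario *differences*
  should be interpreted, and only qualitatively.
* The counterfactual ignores autarky's economic feedbacks; it answers an
  attribution question, not a forecasting one.
* The per-country VSL transfer (elasticity-1 GDP scaling) is one of several
  conventions in benefit transfer; results in currency terms inherit it.
* The four uncertainty components are treated as independent; correlations
  between, e.g., intake and concentration errors are not modelled, and no
  variance decomposition is attempted.
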