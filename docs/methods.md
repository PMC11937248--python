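# Methods

This note documents the models behind cropgate, the defaults they ship with,
the choices made where the design was genuinely open, and what the synthetic
scenario generator does and does not emulate.

## System boundary and accounting frame

The accounting is attributional, cradle to farm gate: upstream production of
inputs, field emissions (soil CH₄ and N₂O), and the soil organic carbon
balance, all expressed as 100-year CO₂-equivalents. Post-harvest stages
(milling, transport) and residue-burning trace gases are out of scope; burning
only removes residue C and N from the soil-input ledger, which is a known
limitation. The calendar is a 365-day year at monthly resolution; seasons are
integer day-of-year spans and no leap years are modelled.

Units are normalized once, at scenario load: biomass and C in Mg ha⁻¹, N and
gas masses in kg ha⁻¹, water in mm, energy in kWh. Prices are an opaque
currency per Mg — only ratios enter the economic allocation.

## NPP components

Yields are always inputs. Dry matter is fresh yield × (1 − moisture); the
commercial moistures (12% paddy, 14% wheat/maize) are scenario fields, and
footprints are reported per kg of fresh product at those moistures. Residue
dry matter is a measured input where supplied; otherwise it falls back to a
per-crop residue:product coefficient (prioritization: measurements beat
coefficients). Roots are allometric, `root = (product + residue) × R:S`.
C and N contents are per-crop, per-tissue coefficients on a dry-matter basis.

Weed biomass is the only modelled growth. Potential yearly above-ground weed
biomass follows a saturating curve of yearly water input W (precipitation plus
irrigation), `NPP_pot = a(1 − e^(−bW))`, with a = 30 Mg DM ha⁻¹ yr⁻¹ and
b = 6.64 × 10⁻⁴ mm⁻¹ — the classic precipitation-limited potential-NPP
parameterization — shipped in the factor table as a replaceable default
because only the model family, not its constants, is fixed by the method.
The potential is scaled by weed management ({none: 1.0, partial: 0.5,
complete_control: 0.0}, configurable) and prorated linearly to the fallow
duration. Weed roots use a dedicated root:shoot default (0.3). In-season weed
growth is off by default (`weed.in_crop_scale: 0`).

## Soil CH₄ (Tier 1)

Seasonal soil CH₄ for flooded or waterlogged seasons is

    CH₄ = EF_baseline × SF_w × SF_p × SF_o × duration_days

with the shipped factor file carrying the wet-season defaults of the current
Tier 1 guidance: global baseline 1.19 kg CH₄ ha⁻¹ d⁻¹ and a South Asia
regional baseline of 0.85; SF_w per cultivation regime (continuously flooded
1.0 by invariant, single/multiple-aeration 0.71/0.55, rainfed 0.54); SF_p per
pre-season class (<30 d non-flooded 1.0, 30–180 d 0.89, >180 d 0.59, flooded
2.41); SF_o = (1 + Σ ROA·CFOA)^0.59 with CFOA 1.0 for fresh straw, 0.19 for
straw incorporated long before cultivation, and manure/compost values.
Dryland seasons emit exactly zero. The floodplain rice fields' "non-flooded
pre-season under ~50 days" straddles the class bound; fixtures default to the
30–180-day class (0.89), configurable per season.

Waterlogged non-rice seasons (the high-water-table wheat case) are an explicit
scenario opt-in: Tier 1 defines no wheat factor, so such a season reuses the
rice machinery only when the scenario sets a flooded/waterlogged regime.

Scope selection mirrors the measured-data prioritization: when a seasonal
measurement exists for a reference treatment, the scope (global vs regional)
with the smaller absolute relative deviation is applied pattern-wide, ties
breaking to global; without measurements the configured default scope is used.

## Soil N₂O (Tier 1)

The N-input ledger per season holds synthetic fertilizer N, above-ground
residue N scaled by the incorporated fate share only, root N and weed N in
full, and SOM-mineralized N passed in from the SOC balance (entering direct
N₂O as an "other inputs" source). Direct N₂O-N is Σ N × EF1 with the
wet-climate disaggregation: synthetic 0.016, other inputs 0.006, and 0.004
for all inputs on flooded/waterlogged seasons — so the rice factor sits below
the synthetic wet-climate factor by construction. The method is exactly
linear in every ledger entry.

Indirect N₂O: volatilization = (synthetic N × Frac_GASF + recycled organic N ×
Frac_GASM) × EF4, leaching = total N × Frac_LEACH × EF5, suppressed when a
season marks leaching as not occurring (default on — monsoon precipitation or
irrigation is present in all study-like scenarios). Two shipped defaults
deviate deliberately from the plain guideline table and are called out here:

- **Frac_LEACH = 0.10** (guideline wet-climate value 0.24). With 0.24 and
  EF5 = 0.011 the leaching pathway would dominate volatilization
  (0.0026 vs 0.0021 kg N₂O-N per kg synthetic N), inverting the ordering
  consistently observed for these systems (volatilization-driven N₂O larger
  for every crop). Puddled paddy layers and shallow-rooted floodplain soils
  leach less than the generic wet-climate default assumes; 0.10 encodes that
  and is overridable in the `n2o:` factor section.
- **Frac_GASM = 0.21 applied to recycled organic N** (residues, weeds,
  mineralized SOM), not only to organic fertilizers. This treats N cycling
  through decomposing residue as volatilization-prone, consistent with the
  same observed ordering; set `frac_gasm: 0` to restrict volatilization to
  synthetic N.

N₂O-N converts to N₂O mass by 44/28 exactly.

## SOC balance (two-pool dynamic model)

Two pools, "active" (fast) and "humified" (slow). Each month a pool loses
`stock × k_pool × f_T × f_W × f_C [× f_flood]` and fresh C input splits by the
humification coefficient h (per input stream: crop streams from the crop
coefficient table, weeds 0.15): h to the humified pool, 1 − h to the active
pool. Mass balance holds exactly each month.

Modifiers follow RothC conventions: f_T = 47.91 / (1 + e^(106.06/(T+18.27)))
(≈1 at 9 °C, ≈4 at 26 °C); f_W saturates on monthly water input,
clip(W_month / 80 mm, 0.2, 1); f_C = 0.6 when the soil is vegetated, 1 when
bare; f_flood = 0.35 while flooded (slower anaerobic mineralization; direction
fixed by the method, value a configurable default). Base rates k_active =
0.02 month⁻¹ and k_humified = 0.0012 month⁻¹ were set once so that the
reference rotation's equilibrium stock lands in the reported range for these
floodplain soils (~72–76 Mg C ha⁻¹ in the top layer); they are not fitted to
any emission outcome and live in the `soc:` factor section.

C inputs per season (incorporated residue C + root C + weed C) are spread
uniformly over the season's months; fallow weed C over the fallow's months.
Because the system is linear, the annual cycle has a closed-form fixed point
per pool (the equilibrium stock), cross-checked by spin-up iteration
(tolerance 10⁻⁸ Mg C between annual cycles, cap 10⁴ years).

The balance used in footprints initializes every pattern at the **reference
rotation's (R-F-R) equilibrium**, runs 100 years (1200 monthly steps), and
divides the total change by 100. Sign convention, stated prominently:
**positive change rate = net SOC loss = emission**; sequestration is negative
and enters the GWP stack with its sign. CO₂ conversion uses the molecular
weight ratio 3.67. The reference rotation itself therefore reports exactly
zero. Per-season attribution books each calendar month's net change (loss −
input) to the season occupying it, fallow months to the season they precede;
the attribution telescopes, so season entries sum exactly to the pattern rate.
Net SOM-mineralized N for the N ledger is max(0, season loss) × 1000 / C:N,
zero for sequestering seasons.

## Upstream inventory

Each source is quantity × a configured factor: fertilizer nutrients (kg N, P,
K, S), pesticide active ingredient, machinery field passes, seed (default
factor 0 — quantities are rarely reported; set `upstream.seed` to enable),
and electricity. Unmetered irrigation electricity is derived as mm × 1.1 kWh
mm⁻¹ ha⁻¹ (groundwater electric pumping) × the country grid factor from a
local table (no network retrieval). The factors are literature LCI constants;
the package never computes an LCI.

## Aggregation and allocation

AR6 GWP100: CH₄ (non-fossil) 27.0 — the value consistent with converting a
366 kg CH₄ season to ≈9.9 Mg CO₂e — and N₂O 273, both overridable. The
allocation share to the main product is product value / (product value +
harvested-residue value); only the harvested residue share carries value.
Footprints are allocated CO₂e per kg fresh product. Intercrop-period inputs
and emissions are attributed to the following crop season. The weighted rice
footprint is rice-season allocated CO₂e summed / rice product mass summed.

## Chamber fluxes

Flux is the ordinary-least-squares slope of headspace concentration (ppm)
against time over ≥3 points (a linear fit is the defensible choice at three
time points; nonlinear HMR-type fits are not identifiable), converted by
M/V_m at chamber temperature and pressure and the chamber height, to kg ha⁻¹
d⁻¹ (negative = uptake). Seasonal totals integrate daily fluxes with the
trapezoid rule per fertilizer split and sum the splits. Beyond the last
sampling day the default extrapolation holds the last flux constant until a
stated end day (`zero` mode ramps to zero instead).

## Fixtures, placeholders, and the synthetic generator

The five rotation fixtures encode the published season calendars, water
regimes and residue-incorporation shares (10–20% for rice straw, 30% in the
maize- and potato-rice systems, 100% for potato haulm and mungbean residue).
Fertilizer rates, prices, irrigation depths and machinery counts are **not**
published for these trials; the fixtures carry placeholder values typical of
national fertilizer-recommendation practice, kept in one clearly marked block.
Fixture totals are therefore illustrative of the method, not reproductions of
the reported footprints. One calendar note: the potato-rice pattern's fallow
spans potato harvest (mid-February) to aman transplanting (late July), so its
weed inputs attribute forward to aman.

The generator (`synth_scenario`) draws valid patterns inside a subtropical
monsoon envelope: mean temperature ≈26 °C, annual rain 1800–2200 mm with a
May–October peak, 1–4 seasons of 60–150 days with a configurable flooded
fraction, incorporation shares 10–100%, fertilizer N 0–250 kg ha⁻¹. It is
deterministic per seed and always validates. It does **not** emulate
measurement error, spatial heterogeneity, inter-annual climate variability,
pest/yield covariance, or management responding to weather — so passing
property tests demonstrate the accounting identities and model behavior, not
predictive skill on real farms.

## Numerical choices and limitations

- Monthly pool rates are capped at 1 (full turnover); pools cannot go
  negative.
- The analytic equilibrium and the spin-up agree to <10⁻⁶ relative on all
  fixtures and random draws (this equivalence is part of the test suite).
- Ties in CH₄ scope selection break deterministically to global.
- Zero-value allocation raises rather than guessing; a season with no priced
  residue allocates 100% to the product.
- No Tier 2/3 gas modelling, no sub-season drainage events, no uncertainty
  propagation; residue burning emits no accounted trace gases. The per-crop
  SOC attribution is a within-pattern bookkeeping convention; standalone
  per-crop equilibria would differ.
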