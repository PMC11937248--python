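# Default emission-factor / coefficient table.
# Tier 1 rice CH4 and cropland N2O factors follow the 2019 Refinement to the
# 2006 IPCC Guidelines (wet climate disaggregation); GWP100 values follow AR6.
# Upstream factors are Ecoinvent-derived literature constants (editable).
# Every entry is a default, overridable by a user factor file.
version_tag: "cropgate-defaults-2019R-AR6-v1"

ch4:
  default_scope: global
  baseline_daily:            # kg CH4 ha-1 d-1
    global: 1.19
    "regional:south_asia": 0.85
  sf_water:                  # SFw, water regime during cultivation
    continuously_flooded: 1.0
    intermittent_single: 0.71
    intermittent_multiple: 0.55
    rainfed: 0.54
    none: 0.0
  sf_preseason:              # SFp, pre-season water regime
    nonflooded_lt30: 1.0
    nonflooded_30_180: 0.89
    nonflooded_gt180: 0.59
    flooded: 2.41
  cfoa:                      # conversion factor of organic amendment (vs fresh straw)
    straw_short: 1.0         # straw incorporated < 30 d before cultivation
    straw_long: 0.19         # straw incorporated > 30 d before cultivation
    compost: 0.17
    farmyard_manure: 0.21
    green_manure: 0.45

n2o:
  ef1:                       # kg N2O-N per kg N input (direct)
    synthetic_wet: 0.016     # synthetic fertilizer, wet climate, non-rice
    other_wet: 0.006         # other N inputs (residues, organic), wet climate
    flooded_rice: 0.004      # all N inputs on flooded rice
  frac_gasf: 0.15            # fraction of synthetic N volatilized (urea)
  frac_gasm: 0.21            # fraction of organic-origin N volatilized
  ef4: 0.014                 # kg N2O-N per kg N volatilized, wet climate
  frac_leach: 0.10           # fraction of N leached where leaching occurs (see docs/methods.md)
  ef5: 0.011                 # kg N2O-N per kg N leached

gwp100:                      # AR6 100-year GWP, kg CO2e per kg gas
  ch4: 27.0                  # non-fossil CH4
  n2o: 273.0
  co2: 1.0

weed:                        # water-driven potential-biomass model (saturating curve)
  npp_max: 30.0              # Mg DM ha-1 yr-1 asymptote
  npp_k: 6.64e-4             # mm-1 curvature
  management_scale:
    none: 1.0
    partial: 0.5
    complete_control: 0.0
  root_to_shoot: 0.3
  c_content: 0.42
  n_content: 0.015
  humification: 0.15
  in_crop_scale: 0.0         # in-season weed biomass share of potential (default off)

soc:                         # two-pool dynamic SOC model parameters
  k_active: 0.02             # month-1 base mineralization, active pool
  k_humified: 0.0012         # month-1 base mineralization, humified pool
  flooded_modifier: 0.35     # multiplier on mineralization while flooded
  water_ref_mm: 80.0         # monthly water input saturating the moisture modifier
  water_min_modifier: 0.2
  cover_factor: 0.6          # rate multiplier when soil is vegetated

upstream:                    # kg CO2e per unit, Ecoinvent-derived literature values
  fertilizer_n: 3.6          # per kg N (urea production, incl. upstream)
  fertilizer_p: 1.3          # per kg P
  fertilizer_k: 0.55         # per kg K
  fertilizer_s: 0.30         # per kg S
  pesticide: 11.0            # per kg active ingredient
  machinery_pass: 15.0       # per field pass (machine + diesel)
  seed: 0.0                  # per kg seed (default off; see docs/methods.md)
  pumping_kwh_per_mm: 1.1    # kWh per mm irrigation per ha (groundwater electric pump)
  electricity_grid:          # kg CO2e per kWh by country code
    BGD: 0.67
    VNM: 0.49
    PAK: 0.42
    ARG: 0.30
    CRI: 0.07
    ETH: 0.02

crops:                       # allometric / stoichiometric coefficients (DM basis)
  default:
    root_to_shoot: 0.20
    residue_to_product: 1.0
    c_product: 0.42
    c_residue: 0.42
    c_root: 0.40
    n_product: 0.012
    n_residue: 0.007
    n_root: 0.007
    humification: 0.18
  rice:
    root_to_shoot: 0.22
    residue_to_product: 1.1
    c_product: 0.41
    c_residue: 0.41
    c_root: 0.39
    n_product: 0.011
    n_residue: 0.007
    n_root: 0.007
    humification: 0.20
  maize:
    root_to_shoot: 0.18
    residue_to_product: 1.2
    c_product: 0.43
    c_residue: 0.44
    c_root: 0.42
    n_product: 0.014
    n_residue: 0.007
    n_root: 0.007
    humification: 0.18
  wheat:
    root_to_shoot: 0.20
    residue_to_product: 1.15
    c_product: 0.42
    c_residue: 0.43
    c_root: 0.40
    n_product: 0.020
    n_residue: 0.006
    n_root: 0.009
    humification: 0.18
  mungbean:
    root_to_shoot: 0.25
    residue_to_product: 1.5
    c_product: 0.44
    c_residue: 0.42
    c_root: 0.40
    n_product: 0.035
    n_residue: 0.020
    n_root: 0.015
    humification: 0.15
  potato:
    root_to_shoot: 0.10
    residue_to_product: 0.25
    c_product: 0.42
    c_residue: 0.40
    c_root: 0.38
    n_product: 0.015
    n_residue: 0.020
    n_root: 0.012
    humification: 0.15
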