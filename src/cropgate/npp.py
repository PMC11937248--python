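"""Net-primary-production component accounting.

Everything the system grows in a year -- product, above-ground residue, roots,
and weeds -- is expressed in dry matter, carbon and nitrogen per hectare.
Yields are always inputs (measured or scenario-supplied); the only modelled
biomass is weed growth, estimated from yearly water input with a saturating
potential-biomass curve and scaled by qualitative weed-management intensity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import DomainError
from .scenario import (
    ClimateYear,
    CropCoefficients,
    CroppingPattern,
    CropSeason,
    EmissionFactorTable,
    IntercropPeriod,
    WeedManagement,
)

PARTS = ("product", "residue_ag", "root_bg", "weed_ag", "weed_bg")


@dataclass
class NppComponents:
    """Biomass components in Mg DM ha-1 with parallel C (Mg ha-1) and N (kg ha-1)."""

    product_dm: float = 0.0
    residue_ag_dm: float = 0.0
    root_bg_dm: float = 0.0
    weed_ag_dm: float = 0.0
    weed_bg_dm: float = 0.0
    c: dict[str, float] = field(default_factory=lambda: {p: 0.0 for p in PARTS})
    n: dict[str, float] = field(default_factory=lambda: {p: 0.0 for p in PARTS})

    @property
    def total_dm(self) -> float:
        return self.product_dm + self.residue_ag_dm + self.root_bg_dm + self.weed_ag_dm + self.weed_bg_dm

    @property
    def total_c(self) -> float:
        return sum(self.c.values())

    @property
    def total_n(self) -> float:
        return sum(self.n.values())

    def __add__(self, other: "NppComponents") -> "NppComponents":
        return NppComponents(
            product_dm=self.product_dm + other.product_dm,
            residue_ag_dm=self.residue_ag_dm + other.residue_ag_dm,
            root_bg_dm=self.root_bg_dm + other.root_bg_dm,
            weed_ag_dm=self.weed_ag_dm + other.weed_ag_dm,
            weed_bg_dm=self.weed_bg_dm + other.weed_bg_dm,
            c={p: self.c[p] + other.c[p] for p in PARTS},
            n={p: self.n[p] + other.n[p] for p in PARTS},
        )


def dry_matter_from_fresh(fresh_yield: float, moisture: float) -> float:
    """Convert a fresh yield at commercial moisture to dry matter (Mg DM ha-1)."""
    if not 0 <= moisture < 1:
        raise DomainError(f"moisture must be in [0, 1), got {moisture}")
    if fresh_yield < 0:
        raise DomainError(f"fresh yield must be >= 0, got {fresh_yield}")
    return fresh_yield * (1.0 - moisture)


def potential_weed_biomass(
    annual_water: float,
    management: WeedManagement | str,
    factors: EmissionFactorTable,
) -> float:
    """Potential yearly weed above-ground biomass (Mg DM ha-1 yr-1).

    A saturating curve of yearly water input W (precipitation + irrigation),
    ``NPP = a * (1 - exp(-b * W))``, scaled by a weed-management factor in
    [0, 1].  Monotone non-decreasing in W and exactly 0 at W = 0 or under
    complete control.  The curve parameters ship in the factor table and are
    replaceable defaults.
    """
    if annual_water < 0:
        raise DomainError(f"annual water input must be >= 0, got {annual_water}")
    management = WeedManagement(management)
    a = float(factors.weed["npp_max"])
    b = float(factors.weed["npp_k"])
    scale = float(factors.weed["management_scale"][management.value])
    return a * (1.0 - math.exp(-b * annual_water)) * scale


def _stoich(components: NppComponents, c_by_part: dict[str, float], n_by_part: dict[str, float]) -> NppComponents:
    dm = {
        "product": components.product_dm,
        "residue_ag": components.residue_ag_dm,
        "root_bg": components.root_bg_dm,
        "weed_ag": components.weed_ag_dm,
        "weed_bg": components.weed_bg_dm,
    }
    components.c = {p: dm[p] * c_by_part[p] for p in PARTS}
    components.n = {p: dm[p] * n_by_part[p] * 1000.0 for p in PARTS}  # kg N ha-1
    return components


def season_npp(
    season: CropSeason,
    coeffs: CropCoefficients,
    factors: EmissionFactorTable,
    weed_dm: float = 0.0,
) -> NppComponents:
    """NPP components for one crop cycle.

    Measured residue (``season.residue_yield_dm``) overrides the coefficient
    estimate (prioritization rule).  Roots are allometric:
    ``root_bg = (product + residue) * root_to_shoot``.  ``weed_dm`` is
    in-season above-ground weed growth, defaulting to zero.
    """
    p = coeffs.get(season.crop)
    product_dm = dry_matter_from_fresh(season.product_yield_fresh, season.product_moisture)
    if season.residue_yield_dm is not None:
        residue_dm = season.residue_yield_dm
    else:
        residue_dm = product_dm * p.residue_to_product
    rs = season.root_to_shoot if season.root_to_shoot is not None else p.root_to_shoot
    root_dm = (product_dm + residue_dm) * rs
    weed_rs = float(factors.weed["root_to_shoot"])
    comp = NppComponents(
        product_dm=product_dm,
        residue_ag_dm=residue_dm,
        root_bg_dm=root_dm,
        weed_ag_dm=weed_dm,
        weed_bg_dm=weed_dm * weed_rs,
    )
    wc = float(factors.weed["c_content"])
    wn = float(factors.weed["n_content"])
    return _stoich(
        comp,
        {"product": p.c_product, "residue_ag": p.c_residue, "root_bg": p.c_root, "weed_ag": wc, "weed_bg": wc},
        {"product": p.n_product, "residue_ag": p.n_residue, "root_bg": p.n_root, "weed_ag": wn, "weed_bg": wn},
    )


def intercrop_weed_npp(
    period: IntercropPeriod,
    climate: ClimateYear,
    factors: EmissionFactorTable,
) -> NppComponents:
    """Weed NPP grown during a fallow / intercrop period.

    The yearly potential weed biomass for the site's water input is prorated
    linearly to the period duration; zero duration gives zero components.
    """
    annual = potential_weed_biomass(climate.annual_water_input, period.weed_management, factors)
    weed_ag = annual * period.duration_days / 365.0
    weed_rs = float(factors.weed["root_to_shoot"])
    comp = NppComponents(weed_ag_dm=weed_ag, weed_bg_dm=weed_ag * weed_rs)
    wc = float(factors.weed["c_content"])
    wn = float(factors.weed["n_content"])
    zero = {p: 0.0 for p in ("product", "residue_ag", "root_bg")}
    return _stoich(
        comp,
        {**zero, "weed_ag": wc, "weed_bg": wc},
        {**{k: 0.0 for k in zero}, "weed_ag": wn, "weed_bg": wn},
    )


def pattern_npp(
    pattern: CroppingPattern,
    coeffs: CropCoefficients,
    factors: EmissionFactorTable,
) -> dict:
    """Per-season and per-intercrop NPP, plus the additive pattern total."""
    in_crop_scale = float(factors.weed.get("in_crop_scale", 0.0))
    seasons = {}
    for s in pattern.seasons:
        weed_dm = 0.0
        if in_crop_scale > 0:
            weed_dm = (
                potential_weed_biomass(pattern.climate.annual_water_input, WeedManagement.PARTIAL, factors)
                * in_crop_scale * s.duration_days / 365.0
            )
        seasons[s.name] = season_npp(s, coeffs, factors, weed_dm=weed_dm)
    intercrops = {}
    for i, ic in enumerate(pattern.intercrops):
        intercrops[ic.follows_season or f"intercrop_{i}"] = intercrop_weed_npp(ic, pattern.climate, factors)
    total = NppComponents()
    for c in list(seasons.values()) + list(intercrops.values()):
        total = total + c
    return {"seasons": seasons, "intercrops": intercrops, "total": total}
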