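"""Two-pool dynamic soil-organic-carbon balance.

A RothC-style simplification with two active pools: a fast "active" pool and a
slow "humified" pool.  Each month every pool mineralizes at its base rate
multiplied by temperature, soil-water and soil-cover modifiers, and by a
< 1 flooded modifier while the field is flooded (slower anaerobic
mineralization).  Fresh C input is split by the humification coefficient h:
h enters the humified pool, (1 - h) the active pool.

Because the system is linear, the annual cycle has a closed-form fixed point
(the equilibrium stock), which is also cross-checked here by spin-up.  The
annualized change rate runs the model for 100 years from a reference initial
state and divides the total stock change by 100; positive = net SOC loss.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import ConfigurationError, DomainError
from .npp import pattern_npp
from .scenario import (
    CropClass,
    CropCoefficients,
    CroppingPattern,
    EmissionFactorTable,
    WaterRegime,
    intercrop_months,
    monthly_water_input,
    season_months,
)

C_TO_CO2 = 3.67  # molecular weight ratio CO2 : C


def rothc_temperature_modifier(temp_c: float) -> float:
    """RothC rate-modifying factor for temperature (about 1 near 9 degC, ~4 at 26)."""
    if temp_c <= -18.0:
        return 0.0
    return 47.91 / (1.0 + math.exp(106.06 / (temp_c + 18.27)))


@dataclass
class SocState:
    active: float  # Mg C ha-1
    humified: float  # Mg C ha-1
    month_index: int = 0

    @property
    def total(self) -> float:
        return self.active + self.humified

    def validate(self) -> "SocState":
        if self.active < 0 or self.humified < 0:
            raise DomainError("SOC pools must be >= 0")
        return self


@dataclass
class SocParameters:
    k_active: float = 0.02  # month-1 base mineralization, active pool
    k_humified: float = 0.0012  # month-1, humified pool
    flooded_modifier: float = 0.35  # (0, 1]: slower mineralization while flooded
    water_ref_mm: float = 80.0  # monthly water input saturating the moisture modifier
    water_min_modifier: float = 0.2
    cover_factor: float = 0.6  # rate multiplier when soil is vegetated

    def validate(self) -> "SocParameters":
        if self.k_active <= 0 or self.k_humified <= 0:
            raise DomainError("base mineralization rates must be > 0")
        if not 0 < self.flooded_modifier <= 1:
            raise DomainError("flooded_modifier must be in (0, 1]")
        return self

    @classmethod
    def from_factors(cls, factors: EmissionFactorTable) -> "SocParameters":
        soc = factors.soc
        return cls(
            k_active=float(soc.get("k_active", 0.02)),
            k_humified=float(soc.get("k_humified", 0.0012)),
            flooded_modifier=float(soc.get("flooded_modifier", 0.35)),
            water_ref_mm=float(soc.get("water_ref_mm", 80.0)),
            water_min_modifier=float(soc.get("water_min_modifier", 0.2)),
            cover_factor=float(soc.get("cover_factor", 0.6)),
        ).validate()

    def water_modifier(self, water_mm: float) -> float:
        return min(1.0, max(self.water_min_modifier, water_mm / self.water_ref_mm))

    def rate_multiplier(self, temp_c: float, water_mm: float, flooded: bool, covered: bool) -> float:
        m = rothc_temperature_modifier(temp_c) * self.water_modifier(water_mm)
        m *= self.cover_factor if covered else 1.0
        if flooded:
            m *= self.flooded_modifier
        return m


@dataclass
class MonthForcing:
    """One calendar month of drivers and C inputs for the SOC model."""

    temperature: float
    water_mm: float
    flooded: bool
    covered: bool
    input_active: float = 0.0  # Mg C ha-1 entering the active pool this month
    input_humified: float = 0.0
    season: str | None = None  # attribution label for per-season rollups

    @property
    def input_total(self) -> float:
        return self.input_active + self.input_humified


@dataclass
class SocBalance:
    equilibrium_stock: float  # Mg C ha-1 (reference equilibrium used as initial)
    change_rate: float  # Mg C ha-1 yr-1, positive = net loss
    per_season_change: dict[str, float] = field(default_factory=dict)

    @property
    def co2e_rate(self) -> float:
        """Mg CO2e ha-1 yr-1 with the same sign convention (positive = emission)."""
        return self.change_rate * C_TO_CO2


def monthly_step(
    state: SocState,
    c_input: float,
    params: SocParameters,
    temperature: float,
    water_mm: float,
    flooded: bool,
    covered: bool,
    h: float = 0.18,
) -> SocState:
    """Advance the two pools one month.

    Each pool decays by base rate x the month's modifier product; the fresh
    input splits h into the humified pool and (1 - h) into the active pool.
    """
    if c_input < 0:
        raise DomainError(f"C input must be >= 0, got {c_input}")
    mult = params.rate_multiplier(temperature, water_mm, flooded, covered)
    rate_a = min(1.0, params.k_active * mult)
    rate_h = min(1.0, params.k_humified * mult)
    return SocState(
        active=state.active * (1.0 - rate_a) + (1.0 - h) * c_input,
        humified=state.humified * (1.0 - rate_h) + h * c_input,
        month_index=state.month_index + 1,
    )


def monthly_forcing(
    pattern: CroppingPattern,
    coeffs: CropCoefficients,
    factors: EmissionFactorTable,
) -> list[MonthForcing]:
    """Build the 12-month driver/input schedule for a pattern.

    C returned to soil per season = incorporated residue C + root C + in-season
    weed C, spread uniformly over the season's months; intercrop weed C is
    spread over the fallow's months.  Flooded months are those of flooded-rice
    or waterlogged seasons (and flooded fallows); covered months are any with
    a crop or an unmanaged fallow (weeds).
    """
    water = monthly_water_input(pattern)
    forcing = [
        MonthForcing(temperature=pattern.climate.monthly_temperature[m], water_mm=water[m],
                     flooded=False, covered=False)
        for m in range(12)
    ]
    npp = pattern_npp(pattern, coeffs, factors)
    month_label: dict[int, str] = {}
    weed_h = float(factors.weed.get("humification", 0.15))

    for s in pattern.seasons:
        months = season_months(s)
        for m in months:
            forcing[m].covered = True
            month_label.setdefault(m, s.name)
            if s.crop_class in (CropClass.FLOODED_RICE, CropClass.WATERLOGGED_NONRICE) and (
                s.water_regime_cultivation is not WaterRegime.NONE
            ):
                forcing[m].flooded = True
        comp = npp["seasons"][s.name]
        incorporated = s.residue_fate_shares.get("incorporated", 0.0)
        crop_c = comp.c["residue_ag"] * incorporated + comp.c["root_bg"]
        weed_c = comp.c["weed_ag"] + comp.c["weed_bg"]
        h = coeffs.get(s.crop).humification
        for m in months:
            forcing[m].input_active += ((1.0 - h) * crop_c + (1.0 - weed_h) * weed_c) / len(months)
            forcing[m].input_humified += (h * crop_c + weed_h * weed_c) / len(months)

    for ic in pattern.intercrops:
        months = intercrop_months(ic)
        label = ic.follows_season or (pattern.seasons[0].name if pattern.seasons else None)
        for m in months:
            forcing[m].covered = True
            month_label.setdefault(m, label)
            if ic.flooded:
                forcing[m].flooded = True
        if months:
            comp = npp["intercrops"].get(label)
            if comp is not None:
                weed_c = comp.c["weed_ag"] + comp.c["weed_bg"]
                for m in months:
                    forcing[m].input_active += (1.0 - weed_h) * weed_c / len(months)
                    forcing[m].input_humified += weed_h * weed_c / len(months)

    # attribute bare months forward to the next cropped month's season
    for m in range(12):
        if m not in month_label:
            for step in range(1, 13):
                nxt = (m + step) % 12
                if nxt in month_label:
                    month_label[m] = month_label[nxt]
                    break
            else:
                month_label[m] = pattern.seasons[0].name
    for m in range(12):
        forcing[m].season = month_label[m]
    return forcing


def _pool_rates(forcing: list[MonthForcing], params: SocParameters) -> tuple[list[float], list[float]]:
    mults = [params.rate_multiplier(f.temperature, f.water_mm, f.flooded, f.covered) for f in forcing]
    return (
        [min(1.0, params.k_active * m) for m in mults],
        [min(1.0, params.k_humified * m) for m in mults],
    )


def _annual_fixed_point(rates: list[float], inputs: list[float]) -> float:
    """Fixed point of x -> x * prod(1-r) + forced term, for one linear pool."""
    decay = 1.0
    forced = 0.0
    for r, u in zip(rates, inputs):
        forced = forced * (1.0 - r) + u
        decay *= 1.0 - r
    if decay >= 1.0:
        if forced > 0:
            raise ConfigurationError("pool has zero mineralization but positive input: no equilibrium")
        return 0.0
    return forced / (1.0 - decay)


def equilibrium_state(
    pattern: CroppingPattern,
    params: SocParameters,
    coeffs: CropCoefficients,
    factors: EmissionFactorTable,
) -> SocState:
    """Analytic equilibrium pools: one full annual cycle leaves them unchanged."""
    forcing = monthly_forcing(pattern, coeffs, factors)
    rates_a, rates_h = _pool_rates(forcing, params)
    a_star = _annual_fixed_point(rates_a, [f.input_active for f in forcing])
    h_star = _annual_fixed_point(rates_h, [f.input_humified for f in forcing])
    return SocState(active=a_star, humified=h_star)


def equilibrium_stock(
    pattern: CroppingPattern,
    params: SocParameters,
    coeffs: CropCoefficients,
    factors: EmissionFactorTable,
) -> float:
    """Total equilibrium SOC stock (Mg C ha-1) of the pattern's annual cycle."""
    return equilibrium_state(pattern, params, coeffs, factors).total


def spin_up(
    pattern: CroppingPattern,
    params: SocParameters,
    coeffs: CropCoefficients,
    factors: EmissionFactorTable,
    start: SocState | None = None,
    tol: float = 1e-8,
    max_years: int = 10_000,
) -> SocState:
    """Iterate annual cycles until successive years differ by < tol (Mg C).

    Independent cross-check of the analytic fixed point; raises on
    non-convergence with diagnostics.
    """
    forcing = monthly_forcing(pattern, coeffs, factors)
    rates_a, rates_h = _pool_rates(forcing, params)
    state = start or SocState(0.0, 0.0)
    a, h = state.active, state.humified
    for year in range(max_years):
        a0, h0 = a, h
        for m in range(12):
            a = a * (1.0 - rates_a[m]) + forcing[m].input_active
            h = h * (1.0 - rates_h[m]) + forcing[m].input_humified
        if abs(a - a0) + abs(h - h0) < tol:
            return SocState(active=a, humified=h, month_index=12 * (year + 1))
    raise ConfigurationError(
        f"SOC spin-up did not converge within {max_years} years "
        f"(last annual change {abs(a - a0) + abs(h - h0):.3e} Mg C)"
    )


def annualized_change_rate(
    pattern: CroppingPattern,
    params: SocParameters,
    coeffs: CropCoefficients,
    factors: EmissionFactorTable,
    initial: SocState | float,
    years: int = 100,
) -> SocBalance:
    """Run the model ``years`` years from ``initial`` and annualize the change.

    ``change_rate = (initial - final) / years`` (positive = net loss), with a
    per-season attribution: each calendar month's net loss (mineralization
    minus input) is booked to the season occupying it, fallow months to the
    season they precede.
    """
    forcing = monthly_forcing(pattern, coeffs, factors)
    rates_a, rates_h = _pool_rates(forcing, params)
    if isinstance(initial, SocState):
        state_a, state_h = initial.active, initial.humified
    else:
        # split a bare total by this pattern's own equilibrium pool proportions
        eq = equilibrium_state(pattern, params, coeffs, factors)
        frac_a = eq.active / eq.total if eq.total > 0 else 0.0
        state_a, state_h = initial * frac_a, initial * (1.0 - frac_a)
    initial_total = state_a + state_h

    per_season: dict[str, float] = {s.name: 0.0 for s in pattern.seasons}
    for _ in range(years):
        for m in range(12):
            loss = state_a * rates_a[m] + state_h * rates_h[m]
            gain = forcing[m].input_total
            per_season[forcing[m].season] = per_season.get(forcing[m].season, 0.0) + (loss - gain)
            state_a = state_a * (1.0 - rates_a[m]) + forcing[m].input_active
            state_h = state_h * (1.0 - rates_h[m]) + forcing[m].input_humified
    rate = (initial_total - (state_a + state_h)) / years
    return SocBalance(
        equilibrium_stock=initial_total,
        change_rate=rate,
        per_season_change={k: v / years for k, v in per_season.items()},
    )


def som_mineralized_n(soc_loss: float, soil_cn: float) -> float:
    """Net SOM-mineralized N (kg N ha-1 yr-1) from a SOC loss rate (Mg C ha-1 yr-1).

    Zero when the system sequesters (soc_loss <= 0).
    """
    if soil_cn <= 0:
        raise DomainError(f"soil C:N must be > 0, got {soil_cn}")
    return max(0.0, soc_loss) * 1000.0 / soil_cn


def simulate_trajectory(
    pattern: CroppingPattern,
    params: SocParameters,
    coeffs: CropCoefficients,
    factors: EmissionFactorTable,
    initial: SocState,
    years: int = 100,
) -> pd.DataFrame:
    """Tidy monthly trajectory (month, pool stocks, input, loss) for export."""
    forcing = monthly_forcing(pattern, coeffs, factors)
    rates_a, rates_h = _pool_rates(forcing, params)
    a, h = initial.active, initial.humified
    rows = []
    for year in range(years):
        for m in range(12):
            loss = a * rates_a[m] + h * rates_h[m]
            a = a * (1.0 - rates_a[m]) + forcing[m].input_active
            h = h * (1.0 - rates_h[m]) + forcing[m].input_humified
            rows.append({
                "month": year * 12 + m + 1,
                "active_pool": a,
                "humified_pool": h,
                "c_input": forcing[m].input_total,
                "c_loss": loss,
            })
    return pd.DataFrame(rows)
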