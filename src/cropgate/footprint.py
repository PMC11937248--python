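"""CO2e aggregation, economic allocation, and the footprint report.

Converts every flow (soil CH4, direct and indirect N2O, the SOC balance, and
upstream input production) to Mg CO2e ha-1 with GWP100 factors, assembles
per-season and per-pattern ledgers, allocates emissions economically between
the main product and harvested residues, and reports per-kg-product carbon
footprints, including the production-weighted rice footprint of a pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import ch4 as ch4mod
from . import n2o as n2omod
from . import soc as socmod
from . import upstream as upmod
from .errors import ConfigurationError, DomainError, UnknownLabelError
from .npp import pattern_npp
from .scenario import CroppingPattern, EmissionFactorTable

SOURCE_KEYS = (
    "soil_ch4",
    "n2o_direct",
    "n2o_indirect",
    "soc",
    "fertilizer_production",
    "pesticide_production",
    "machinery",
    "electricity",
    "seed",
)


@dataclass
class GwpTable:
    gwp100: dict[str, float]
    c_to_co2: float = socmod.C_TO_CO2  # 3.67
    n2on_to_n2o: float = n2omod.N2ON_TO_N2O  # 44/28

    @classmethod
    def from_factors(cls, factors: EmissionFactorTable) -> "GwpTable":
        return cls(gwp100=dict(factors.gwp100))


def to_co2e(mass: float, gas: str, table: GwpTable) -> float:
    """Convert a gas mass (kg ha-1) to Mg CO2e ha-1.

    ``gas`` may be a GWP100 key (``ch4``, ``n2o``, ``co2``), ``n2o_n``
    (N2O-N, converted by 44/28 first), or ``soc_c`` (Mg C, converted by 3.67
    with sign preserved -- positive C loss is an emission).
    """
    if gas == "soc_c":
        return mass * table.c_to_co2  # input already Mg C ha-1
    if gas == "n2o_n":
        mass = mass * table.n2on_to_n2o
        gas = "n2o"
    try:
        gwp = table.gwp100[gas]
    except KeyError:
        raise UnknownLabelError(f"no GWP100 factor for gas '{gas}'") from None
    return mass * gwp / 1000.0


def economic_allocation(
    product_mass: float,
    product_price: float,
    residue_harvested_mass: float,
    residue_price: float,
) -> float:
    """Share of emissions allocated to the main product by economic value."""
    if product_mass <= 0:
        raise DomainError("product mass must be > 0 for allocation")
    if product_price < 0 or residue_price < 0:
        raise DomainError("prices must be >= 0")
    product_value = product_mass * product_price
    residue_value = residue_harvested_mass * residue_price
    total = product_value + residue_value
    if total == 0:
        raise DomainError("total economic value is zero: allocation undefined")
    return product_value / total


@dataclass
class SeasonFootprint:
    name: str
    crop: str
    is_rice: bool
    sources: dict[str, float]  # Mg CO2e ha-1 by SOURCE_KEYS
    yield_fresh: float  # Mg product ha-1
    allocation_share: float
    ch4_kg: float  # raw seasonal soil CH4, kg ha-1 (selected scope)
    ch4_kg_by_scope: dict[str, float]
    n2o: n2omod.N2oEstimate
    n_ledger: n2omod.NInputLedger

    @property
    def total(self) -> float:
        return sum(self.sources.values())

    @property
    def allocated_total(self) -> float:
        return self.total * self.allocation_share

    @property
    def footprint(self) -> float:
        """kg CO2e per kg fresh product."""
        return self.allocated_total / self.yield_fresh if self.yield_fresh > 0 else float("nan")


@dataclass
class FootprintReport:
    label: str
    scope: str
    seasons: list[SeasonFootprint]
    soc_balance: socmod.SocBalance
    scope_decision: ch4mod.ScopeDecision | None = None

    @property
    def pattern_sources(self) -> dict[str, float]:
        out = {k: 0.0 for k in SOURCE_KEYS}
        for s in self.seasons:
            for k, v in s.sources.items():
                out[k] += v
        return out

    @property
    def total(self) -> float:
        """Pattern GWP, Mg CO2e ha-1 yr-1 (sum over seasons and sources)."""
        return sum(s.total for s in self.seasons)

    @property
    def total_yield(self) -> float:
        return sum(s.yield_fresh for s in self.seasons)

    @property
    def rice_weighted_footprint(self) -> float:
        """Rice CO2e summed over rice seasons / rice product mass summed."""
        rice = [s for s in self.seasons if s.is_rice]
        mass = sum(s.yield_fresh for s in rice)
        if mass == 0:
            return float("nan")
        return sum(s.allocated_total for s in rice) / mass

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per season x source (Mg CO2e ha-1)."""
        rows = []
        for s in self.seasons:
            for k, v in s.sources.items():
                rows.append({"pattern": self.label, "season": s.name, "source": k, "co2e_mg_ha": v})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            f"Cropping pattern {self.label}  (CH4 scope: {self.scope})",
            f"  annual GWP: {self.total:.2f} Mg CO2e ha-1 yr-1; yield {self.total_yield:.2f} Mg ha-1 yr-1",
        ]
        for s in self.seasons:
            lines.append(
                f"  {s.name:<9} total {s.total:6.2f} Mg CO2e ha-1  "
                f"(CH4 {s.sources['soil_ch4']:5.2f}, N2O {s.sources['n2o_direct'] + s.sources['n2o_indirect']:5.2f}, "
                f"SOC {s.sources['soc']:+5.2f}, upstream "
                f"{sum(s.sources[k] for k in ('fertilizer_production', 'pesticide_production', 'machinery', 'electricity', 'seed')):5.2f})"
                f"  footprint {s.footprint:.2f} kg CO2e/kg"
            )
        rice = self.rice_weighted_footprint
        if rice == rice:  # not NaN
            lines.append(f"  weighted rice footprint: {rice:.2f} kg CO2e per kg paddy")
        return "\n".join(lines)


def assemble_report(
    pattern: CroppingPattern,
    factors: EmissionFactorTable,
    scope: str = "global",
    initial_soc: socmod.SocState | float | None = None,
    measured_ch4: tuple[str, float] | None = None,
) -> FootprintReport:
    """Run every component model on a pattern and assemble the footprint report.

    ``scope`` is "global", "regional", or "auto" (requires ``measured_ch4 =
    (season_name, kg CH4 ha-1)`` to pick the baseline closest to the
    measurement).  ``initial_soc`` is the reference initial SOC state for the
    100-year balance; None uses the pattern's own equilibrium, so the
    reference rotation itself reports a zero SOC change rate.
    """
    pattern.validate()
    factors.check_covers(pattern)
    coeffs = factors.crop_coefficients
    gwp = GwpTable.from_factors(factors)
    npp = pattern_npp(pattern, coeffs, factors)
    params = socmod.SocParameters.from_factors(factors)

    if initial_soc is None:
        initial_soc = socmod.equilibrium_state(pattern, params, coeffs, factors)
    balance = socmod.annualized_change_rate(pattern, params, coeffs, factors, initial_soc)

    # CH4 per season under both scopes, then resolve the working scope
    ch4_by_scope: dict[str, dict[str, float]] = {}
    for s in pattern.seasons:
        ests = {}
        for sc in ("global", "regional"):
            try:
                ests[sc] = ch4mod.seasonal_ch4(s, factors, sc).season_total
            except ConfigurationError:
                if sc == "global":
                    raise
        ch4_by_scope[s.name] = ests
    decision = None
    if scope == "auto":
        if measured_ch4 is None:
            scope = factors.default_ch4_scope
        else:
            ref_season, measured = measured_ch4
            ests = ch4_by_scope[ref_season]
            decision = ch4mod.choose_ch4_method(
                measured, ests.get("global"), ests.get("regional"), factors.default_ch4_scope
            )
            scope = decision.scope

    cn = pattern.soil.cn_ratio if pattern.soil is not None else 10.0
    seasons_out = []
    for s in pattern.seasons:
        comp = npp["seasons"][s.name]
        som_n = socmod.som_mineralized_n(balance.per_season_change.get(s.name, 0.0), cn)
        ic_comp = npp["intercrops"].get(s.name)
        ic_weed_n = (ic_comp.n["weed_ag"] + ic_comp.n["weed_bg"]) if ic_comp is not None else 0.0
        ledger = n2omod.build_n_ledger(comp, s, som_min_n=som_n, intercrop_weed_n=ic_weed_n)
        n2o_est = n2omod.season_n2o(ledger, s, factors)
        up = upmod.upstream_emissions(s, factors, country=pattern.country)
        ch4_kg = ch4_by_scope[s.name].get(scope, 0.0)
        if scope not in ch4_by_scope[s.name]:
            raise ConfigurationError(f"no CH4 estimate under scope '{scope}' for season {s.name}")
        sources = {
            "soil_ch4": to_co2e(ch4_kg, "ch4", gwp),
            "n2o_direct": to_co2e(n2o_est.direct_n, "n2o_n", gwp),
            "n2o_indirect": to_co2e(n2o_est.volatilization_n + n2o_est.leaching_n, "n2o_n", gwp),
            "soc": to_co2e(balance.per_season_change.get(s.name, 0.0), "soc_c", gwp),
            "fertilizer_production": up.entries["fertilizer_production"] / 1000.0,
            "pesticide_production": up.entries["pesticide_production"] / 1000.0,
            "machinery": up.entries["machinery"] / 1000.0,
            "electricity": up.entries["electricity"] / 1000.0,
            "seed": up.entries["seed"] / 1000.0,
        }
        residue_harvested = comp.residue_ag_dm * s.residue_fate_shares.get("harvested", 0.0)
        if s.product_yield_fresh > 0 and (s.price_product > 0 or (residue_harvested > 0 and s.price_residue > 0)):
            share = economic_allocation(
                s.product_yield_fresh, s.price_product, residue_harvested, s.price_residue
            )
        else:
            share = 1.0
        seasons_out.append(SeasonFootprint(
            name=s.name,
            crop=s.crop,
            is_rice=s.crop == "rice",
            sources=sources,
            yield_fresh=s.product_yield_fresh,
            allocation_share=share,
            ch4_kg=ch4_kg,
            ch4_kg_by_scope=ch4_by_scope[s.name],
            n2o=n2o_est,
            n_ledger=ledger,
        ))
    return FootprintReport(
        label=pattern.label,
        scope=scope,
        seasons=seasons_out,
        soc_balance=balance,
        scope_decision=decision,
    )


def compare_with_measured(
    report: FootprintReport,
    measured: dict[str, dict[str, float]],
) -> pd.DataFrame:
    """Side-by-side measured vs Tier 1 values with symmetric ratios.

    ``measured`` maps season name -> {gas: value} with gases ``ch4``
    (kg CH4 ha-1) and ``n2o_n`` (kg N2O-N ha-1, compared against the direct
    Tier 1 estimate).
    """
    rows = []
    by_name = {s.name: s for s in report.seasons}
    for season_name, gases in measured.items():
        if season_name not in by_name:
            raise UnknownLabelError(f"measured data keyed to unknown season '{season_name}'")
        s = by_name[season_name]
        for gas, value in gases.items():
            if gas == "ch4":
                estimate = s.ch4_kg
                extra = dict(s.ch4_kg_by_scope)
            elif gas == "n2o_n":
                estimate = s.n2o.direct_n
                extra = {}
            else:
                raise UnknownLabelError(f"unknown measured gas '{gas}'")
            ratio, direction = n2omod.measured_vs_estimate_ratio(value, estimate)
            rows.append({
                "season": season_name,
                "gas": gas,
                "measured": value,
                "tier1_estimate": estimate,
                "ratio": ratio,
                "direction": direction,
                **{f"est_{k}": v for k, v in extra.items()},
            })
    return pd.DataFrame(rows)
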