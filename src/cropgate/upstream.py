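"""Upstream ("cradle") emissions from producing and using farm inputs.

Each source is quantity x a configured life-cycle-inventory factor: fertilizer
nutrients, pesticide active ingredient, machinery field passes, seed, and
irrigation electricity through a country grid factor.  The factors are
precomputed constants in the factor table; nothing here computes an LCI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigurationError, UnknownLabelError
from .scenario import CropSeason, EmissionFactorTable

SOURCES = ("fertilizer_production", "pesticide_production", "machinery", "electricity", "seed")


@dataclass
class UpstreamLedger:
    """Per-source upstream emissions, kg CO2e ha-1."""

    entries: dict[str, float] = field(default_factory=lambda: {s: 0.0 for s in SOURCES})

    @property
    def total(self) -> float:
        return sum(self.entries.values())


def grid_factor(country: str, grid_table: dict[str, float]) -> float:
    """Electricity-mix emission factor (kg CO2e kWh-1) for a country code."""
    try:
        return grid_table[country]
    except KeyError:
        raise UnknownLabelError(
            f"no electricity grid factor for country '{country}'; configured: {sorted(grid_table)}"
        ) from None


def _factor(factors: EmissionFactorTable, key: str) -> float:
    try:
        return float(factors.upstream[key])
    except KeyError:
        raise ConfigurationError(f"no upstream emission factor for '{key}'") from None


def upstream_emissions(
    season: CropSeason,
    factors: EmissionFactorTable,
    country: str = "BGD",
) -> UpstreamLedger:
    """Upstream CO2e ledger for one crop season.

    Electricity is the metered kWh when given, otherwise derived from
    irrigation depth via a configured pumping energy (kWh per mm per ha).
    """
    fert = 0.0
    for f in season.fertilizer_inputs:
        fert += (
            f.n * _factor(factors, "fertilizer_n")
            + f.p * _factor(factors, "fertilizer_p")
            + f.k * _factor(factors, "fertilizer_k")
            + f.s * _factor(factors, "fertilizer_s")
        )
    pest = season.pesticide_applications * _factor(factors, "pesticide")
    machinery = sum(season.machinery_passes.values()) * _factor(factors, "machinery_pass")
    kwh = (
        season.electricity_kwh
        if season.electricity_kwh is not None
        else season.irrigation_mm * _factor(factors, "pumping_kwh_per_mm")
    )
    electricity = kwh * grid_factor(country, factors.grid_factors)
    seed = season.seed_rate * _factor(factors, "seed")
    return UpstreamLedger(entries={
        "fertilizer_production": fert,
        "pesticide_production": pest,
        "machinery": machinery,
        "electricity": electricity,
        "seed": seed,
    })
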