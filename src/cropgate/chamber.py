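"""Closed-chamber flux computation and seasonal cumulative emissions.

A sealed chamber over the soil accumulates gas; the flux is the linear-fit
slope of headspace concentration against time, converted to mass per area via
the ideal-gas molar volume at chamber temperature and pressure and the
chamber's effective height (volume / footprint area).  Daily fluxes are
integrated over the observation period with the trapezoid rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, UnknownLabelError

MOLAR_MASS = {"ch4": 16.043, "n2o": 44.013, "co2": 44.009}  # g mol-1
_R_VM_STP = 22.414  # L mol-1 at 0 degC, 101.325 kPa


@dataclass
class ChamberSeries:
    """One chamber deployment: >= 3 strictly increasing sample times."""

    sample_times_min: list[float]
    concentrations_ppm: list[float]
    chamber_height_m: float
    air_temperature_c: float = 25.0
    pressure_kpa: float = 101.325
    day_index: int = 0

    def validate(self) -> "ChamberSeries":
        t = np.asarray(self.sample_times_min, dtype=float)
        if t.size < 3:
            raise DomainError(f"chamber series needs >= 3 time points, got {t.size}")
        if np.any(np.diff(t) <= 0):
            raise DomainError("sample times must be strictly increasing")
        if len(self.concentrations_ppm) != t.size:
            raise DomainError("times and concentrations must have equal length")
        if self.chamber_height_m <= 0:
            raise DomainError("chamber height must be > 0")
        return self


def molar_volume(temperature_c: float, pressure_kpa: float = 101.325) -> float:
    """Ideal-gas molar volume (L mol-1) at chamber temperature and pressure."""
    return _R_VM_STP * (temperature_c + 273.15) / 273.15 * 101.325 / pressure_kpa


def chamber_flux(series: ChamberSeries, gas: str) -> float:
    """Flux in kg gas ha-1 d-1 from one chamber concentration series.

    flux = slope(ppm min-1) x (M / Vm) x height, scaled to per-day per-hectare.
    Negative values indicate uptake.
    """
    series.validate()
    gas = gas.lower()
    if gas not in MOLAR_MASS:
        raise UnknownLabelError(f"unknown gas '{gas}'; known: {sorted(MOLAR_MASS)}")
    t = np.asarray(series.sample_times_min, dtype=float)
    c = np.asarray(series.concentrations_ppm, dtype=float)
    slope_ppm_min = float(np.polyfit(t, c, 1)[0])
    vm = molar_volume(series.air_temperature_c, series.pressure_kpa)
    # ppm = uL gas / L air; mass concentration rate = slope * M / Vm  [ug L-1 min-1 = mg m-3 min-1]
    mg_m2_day = slope_ppm_min * MOLAR_MASS[gas] / vm * series.chamber_height_m * 1440.0
    return mg_m2_day * 0.01  # mg m-2 d-1 -> kg ha-1 d-1


def cumulative_emission(daily_fluxes: list[tuple[float, float]]) -> float:
    """Integrate (day, flux kg ha-1 d-1) points to kg ha-1 by the trapezoid rule.

    A single observation spans no interval and integrates to zero.  Raises on
    unsorted days.
    """
    if not daily_fluxes:
        return 0.0
    days = np.asarray([d for d, _ in daily_fluxes], dtype=float)
    flux = np.asarray([f for _, f in daily_fluxes], dtype=float)
    if np.any(np.diff(days) <= 0):
        raise DomainError("sampling days must be strictly increasing")
    if days.size == 1:
        return 0.0
    return float(np.trapezoid(flux, days))


def cumulative_over_splits(splits: list[list[tuple[float, float]]]) -> float:
    """Sum trapezoid totals over per-split daily flux series (one per urea split)."""
    return float(sum(cumulative_emission(s) for s in splits))


def extrapolate_tail(
    daily_fluxes: list[tuple[float, float]],
    until_day: float,
    mode: str = "hold",
) -> list[tuple[float, float]]:
    """Extend a series past the last sampling day to ``until_day``.

    ``hold`` keeps the last measured flux constant (default); ``zero`` appends
    a zero flux at ``until_day`` (linear ramp-down under the trapezoid rule).
    """
    if not daily_fluxes or until_day <= daily_fluxes[-1][0]:
        return list(daily_fluxes)
    last_day, last_flux = daily_fluxes[-1]
    if mode == "hold":
        return list(daily_fluxes) + [(until_day, last_flux)]
    if mode == "zero":
        return list(daily_fluxes) + [(until_day, 0.0)]
    raise UnknownLabelError(f"unknown extrapolation mode '{mode}' (use 'hold' or 'zero')")
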