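"""IPCC Tier 1 seasonal soil methane for flooded and waterlogged crops.

Seasonal CH4 = baseline daily EF x SFw x SFp x SFo x cultivation days, where
the scaling factors adjust for the water regime during cultivation (SFw), the
pre-season water regime (SFp), and organic amendments (SFo).  Dryland crops
emit zero soil CH4 by construction.  Baselines are table-driven and keyed by
scope: the global default or a regional (e.g. South Asia) baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigurationError, DomainError
from .scenario import CropClass, CropSeason, EmissionFactorTable, OrganicAmendment, WaterRegime

SFO_EXPONENT = 0.59


@dataclass
class Ch4Estimate:
    adjusted_daily_ef: float  # kg CH4 ha-1 d-1
    season_total: float  # kg CH4 ha-1
    scope: str
    sf_w: float
    sf_p: float
    sf_o: float


@dataclass
class ScopeDecision:
    """Outcome of the measured-vs-estimate prioritization for the CH4 baseline."""

    scope: str
    measured: float | None
    deviations: dict[str, float]  # absolute relative deviation per scope
    rationale: str


def organic_scaling_sfo(
    amendments: list[OrganicAmendment],
    factors: EmissionFactorTable | None = None,
) -> float:
    """SFo = (1 + sum(ROA_i * CFOA_i)) ** 0.59; exactly 1 for no amendments."""
    total = 0.0
    for a in amendments:
        if a.rate < 0:
            raise DomainError(f"amendment rate must be >= 0, got {a.rate} for '{a.type}'")
        if a.cfoa is not None:
            cfoa = a.cfoa
        elif factors is not None:
            cfoa = factors.amendment_cfoa(a)
        else:
            raise ConfigurationError(f"no CFOA available for amendment '{a.type}'")
        total += a.rate * cfoa
    return (1.0 + total) ** SFO_EXPONENT


def _baseline(factors: EmissionFactorTable, scope: str) -> float:
    if scope in factors.ch4_baseline_daily:
        return factors.ch4_baseline_daily[scope]
    if scope == "regional":
        # accept bare "regional" when exactly one regional baseline is configured
        regional = [k for k in factors.ch4_baseline_daily if k.startswith("regional")]
        if len(regional) == 1:
            return factors.ch4_baseline_daily[regional[0]]
    raise ConfigurationError(
        f"no CH4 baseline for scope '{scope}'; configured: {sorted(factors.ch4_baseline_daily)}"
    )


def seasonal_ch4(season: CropSeason, factors: EmissionFactorTable, scope: str = "global") -> Ch4Estimate:
    """Tier 1 seasonal soil CH4 for one crop cycle.

    Dryland crops return a zero estimate.  Waterlogged non-rice crops (the
    high-water-table wheat case) are computed with the rice machinery only when
    the scenario explicitly sets a flooded/waterlogged cultivation regime.
    """
    if season.crop_class is CropClass.DRYLAND or season.water_regime_cultivation is WaterRegime.NONE:
        return Ch4Estimate(0.0, 0.0, scope, 0.0, 0.0, 1.0)
    try:
        sf_w = factors.sf_water[season.water_regime_cultivation.value]
    except KeyError:
        raise ConfigurationError(
            f"no SFw for water regime '{season.water_regime_cultivation.value}'"
        ) from None
    try:
        sf_p = factors.sf_preseason[season.preseason_regime.value]
    except KeyError:
        raise ConfigurationError(
            f"no SFp for pre-season regime '{season.preseason_regime.value}'"
        ) from None
    sf_o = organic_scaling_sfo(season.organic_amendments, factors)
    daily = _baseline(factors, scope) * sf_w * sf_p * sf_o
    return Ch4Estimate(
        adjusted_daily_ef=daily,
        season_total=daily * season.duration_days,
        scope=scope,
        sf_w=sf_w,
        sf_p=sf_p,
        sf_o=sf_o,
    )


def choose_ch4_method(
    measured: float | None,
    global_est: float | None,
    regional_est: float | None,
    default_scope: str = "global",
) -> ScopeDecision:
    """Select the CH4 baseline scope by comparison with a measured reference.

    When a measured seasonal total exists for a reference treatment, the scope
    whose estimate deviates least (absolute relative deviation) is selected
    and applied pattern-wide; ties break deterministically to global.  Without
    a measurement the configured default scope is used.
    """
    estimates = {}
    if global_est is not None:
        estimates["global"] = global_est
    if regional_est is not None:
        estimates["regional"] = regional_est
    if not estimates:
        raise ConfigurationError("choose_ch4_method requires at least one Tier 1 estimate")
    if measured is None:
        scope = default_scope if default_scope in estimates else next(iter(estimates))
        return ScopeDecision(scope, None, {}, "no measurement available; configured default scope used")
    if measured <= 0:
        raise DomainError(f"measured CH4 must be > 0 for the comparison, got {measured}")
    deviations = {k: abs(v - measured) / measured for k, v in estimates.items()}
    best = min(deviations.values())
    # deterministic tie-break: global wins at equal deviation
    scope = "global" if deviations.get("global") == best else min(deviations, key=deviations.get)
    return ScopeDecision(
        scope,
        measured,
        deviations,
        f"scope '{scope}' closest to measured {measured:g} kg CH4 ha-1 "
        + ", ".join(f"({k} est {v:g})" for k, v in estimates.items()),
    )
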