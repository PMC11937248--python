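"""Scenario domain model: crop seasons, cropping patterns, climate, soil, factors.

All downstream modules (NPP, CH4, N2O, SOC, upstream, footprint) consume the
types defined here.  Units are normalized at load time to the package-internal
convention: masses in Mg ha-1 (dry matter, C) or kg ha-1 (N, gases), water in
mm, durations in days, calendar positions as integer day-of-year on a 365-day
year.  Prices are an opaque currency per Mg; only ratios are ever used.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping

import yaml

from .errors import ConfigurationError, ScenarioValidationError

DAYS_PER_YEAR = 365


class CropClass(str, enum.Enum):
    FLOODED_RICE = "flooded_rice"
    WATERLOGGED_NONRICE = "waterlogged_nonrice"
    DRYLAND = "dryland"


class WaterRegime(str, enum.Enum):
    """Water regime during cultivation (drives the CH4 SFw scaling factor)."""

    CONTINUOUSLY_FLOODED = "continuously_flooded"
    INTERMITTENT_SINGLE = "intermittent_single"
    INTERMITTENT_MULTIPLE = "intermittent_multiple"
    RAINFED = "rainfed"
    NONE = "none"


class PreseasonRegime(str, enum.Enum):
    """Pre-season water regime class (drives SFp), keyed by non-flooded days."""

    NONFLOODED_LT30 = "nonflooded_lt30"
    NONFLOODED_30_180 = "nonflooded_30_180"
    NONFLOODED_GT180 = "nonflooded_gt180"
    FLOODED = "flooded"


class WeedManagement(str, enum.Enum):
    NONE = "none"
    PARTIAL = "partial"
    COMPLETE_CONTROL = "complete_control"


RESIDUE_FATES = ("harvested", "incorporated", "burned", "grazed")


def _check(cond: bool, field_name: str, rule: str) -> None:
    if not cond:
        raise ScenarioValidationError(field_name, rule)


@dataclass
class ClimateYear:
    """Monthly climate plus per-season irrigation totals.

    monthly_temperature : deg C, 12 values (Jan..Dec)
    monthly_precipitation : mm, 12 values
    irrigation_by_season : mm per crop season, keyed by season name
    """

    monthly_temperature: list[float]
    monthly_precipitation: list[float]
    irrigation_by_season: dict[str, float] = field(default_factory=dict)

    @property
    def annual_precipitation(self) -> float:
        return float(sum(self.monthly_precipitation))

    @property
    def total_irrigation(self) -> float:
        return float(sum(self.irrigation_by_season.values()))

    @property
    def annual_water_input(self) -> float:
        """Yearly water input (mm): precipitation plus all irrigation."""
        return self.annual_precipitation + self.total_irrigation

    def validate(self) -> "ClimateYear":
        _check(len(self.monthly_temperature) == 12, "monthly_temperature", "12 monthly entries required")
        _check(len(self.monthly_precipitation) == 12, "monthly_precipitation", "12 monthly entries required")
        _check(all(p >= 0 for p in self.monthly_precipitation), "monthly_precipitation", "precipitation must be >= 0")
        _check(all(i >= 0 for i in self.irrigation_by_season.values()), "irrigation_by_season", "irrigation must be >= 0")
        return self


@dataclass
class SoilProfile:
    soc_stock_initial: float  # Mg C ha-1
    clay_fraction: float  # 0-1
    ph: float = 6.5
    depth_cm: float = 15.0
    cn_ratio: float = 10.0  # topsoil C:N, used for SOM-mineralization N

    def validate(self) -> "SoilProfile":
        _check(self.soc_stock_initial >= 0, "soc_stock_initial", "must be >= 0")
        _check(0 <= self.clay_fraction <= 1, "clay_fraction", "must be within [0, 1]")
        _check(self.cn_ratio > 0, "cn_ratio", "must be > 0")
        return self


@dataclass
class FertilizerInput:
    """One synthetic fertilizer product application, nutrient basis kg ha-1."""

    product: str  # e.g. urea, tsp, mop, gypsum
    n: float = 0.0
    p: float = 0.0
    k: float = 0.0
    s: float = 0.0

    def validate(self) -> "FertilizerInput":
        for nut in ("n", "p", "k", "s"):
            _check(getattr(self, nut) >= 0, f"fertilizer_inputs.{self.product}.{nut}", "must be >= 0")
        return self


@dataclass
class OrganicAmendment:
    """Organic input relevant to the CH4 SFo scaling (straw, manure, compost).

    rate : Mg ha-1 (dry matter); cfoa : unitless conversion factor relative to
    fresh straw (looked up from the factor table by `type` when None).
    """

    type: str
    rate: float
    cfoa: float | None = None

    def validate(self) -> "OrganicAmendment":
        _check(self.rate >= 0, f"organic_amendments.{self.type}.rate", "must be >= 0")
        return self


@dataclass
class CropSeason:
    """One crop cycle: management, production, and water regime."""

    name: str  # e.g. "boro", "aman", "maize"
    crop: str  # coefficient-table key, e.g. "rice", "maize", "potato"
    crop_class: CropClass
    start_doy: int  # day-of-year the cycle starts (365-day calendar)
    duration_days: int
    product_yield_fresh: float  # Mg ha-1 at commercial moisture
    product_moisture: float  # fraction in [0, 1)
    residue_yield_dm: float | None = None  # Mg DM ha-1, measured; None -> estimate
    residue_fate_shares: dict[str, float] = field(
        default_factory=lambda: {"harvested": 0.0, "incorporated": 0.0, "burned": 0.0, "grazed": 0.0}
    )
    root_to_shoot: float | None = None  # None -> coefficient default
    fertilizer_inputs: list[FertilizerInput] = field(default_factory=list)
    organic_amendments: list[OrganicAmendment] = field(default_factory=list)
    water_regime_cultivation: WaterRegime = WaterRegime.NONE
    preseason_regime: PreseasonRegime = PreseasonRegime.NONFLOODED_30_180
    irrigation_mm: float = 0.0
    machinery_passes: dict[str, int] = field(default_factory=dict)
    pesticide_applications: float = 0.0  # kg a.i. ha-1 per season
    electricity_kwh: float | None = None  # None -> derived from irrigation_mm
    seed_rate: float = 0.0  # kg ha-1, upstream seed emissions (config factor)
    price_product: float = 0.0  # currency Mg-1, only ratios used
    price_residue: float = 0.0
    leaching_occurs: bool = True  # monsoon / irrigated default

    @property
    def end_doy(self) -> int:
        return self.start_doy + self.duration_days

    @property
    def total_fertilizer_n(self) -> float:
        return float(sum(f.n for f in self.fertilizer_inputs))

    def validate(self) -> "CropSeason":
        _check(self.duration_days > 0, "duration_days", "must be > 0")
        _check(0 <= self.product_moisture < 1, "product_moisture", "must be within [0, 1)")
        _check(self.product_yield_fresh >= 0, "product_yield_fresh", "must be >= 0")
        if self.residue_yield_dm is not None:
            _check(self.residue_yield_dm >= 0, "residue_yield_dm", "must be >= 0")
        shares = self.residue_fate_shares
        unknown = set(shares) - set(RESIDUE_FATES)
        _check(not unknown, "residue_fate_shares", f"unknown fate keys {sorted(unknown)}")
        _check(
            all(0 <= v <= 1 for v in shares.values()),
            "residue_fate_shares",
            "each share must be within [0, 1]",
        )
        _check(sum(shares.values()) <= 1 + 1e-9, "residue_fate_shares", "shares must sum to <= 1")
        _check(self.irrigation_mm >= 0, "irrigation_mm", "must be >= 0")
        _check(self.pesticide_applications >= 0, "pesticide_applications", "must be >= 0")
        if self.crop_class is CropClass.FLOODED_RICE:
            _check(
                self.water_regime_cultivation is not WaterRegime.NONE,
                "water_regime_cultivation",
                "flooded_rice requires a cultivation water regime",
            )
        for f in self.fertilizer_inputs:
            f.validate()
        for a in self.organic_amendments:
            a.validate()
        return self


@dataclass
class IntercropPeriod:
    """Fallow / intercrop gap between two crop cycles."""

    duration_weeks: float
    weed_management: WeedManagement = WeedManagement.NONE
    flooded: bool = False
    start_doy: int = 0
    follows_season: str | None = None  # season name the period precedes; emissions attributed forward

    @property
    def duration_days(self) -> float:
        return self.duration_weeks * 7.0

    def validate(self) -> "IntercropPeriod":
        _check(self.duration_weeks >= 0, "duration_weeks", "must be >= 0")
        return self


@dataclass
class CroppingPattern:
    """An annual rotation: ordered crop seasons plus intercrop periods."""

    label: str
    seasons: list[CropSeason]
    intercrops: list[IntercropPeriod] = field(default_factory=list)
    climate: ClimateYear = None  # type: ignore[assignment]
    soil: SoilProfile = None  # type: ignore[assignment]
    country: str = "BGD"

    def validate(self) -> "CroppingPattern":
        _check(bool(self.seasons), "seasons", "at least one crop season required")
        for s in self.seasons:
            s.validate()
        for ic in self.intercrops:
            ic.validate()
        covered = sum(s.duration_days for s in self.seasons) + sum(ic.duration_days for ic in self.intercrops)
        _check(covered <= 366, "seasons", "calendar coverage of seasons + intercrops must be <= 366 days")
        if self.climate is not None:
            self.climate.validate()
            unknown = set(self.climate.irrigation_by_season) - {s.name for s in self.seasons}
            _check(not unknown, "climate.irrigation_by_season", f"unknown season names {sorted(unknown)}")
        if self.soil is not None:
            self.soil.validate()
        return self

    def season(self, name: str) -> CropSeason:
        for s in self.seasons:
            if s.name == name:
                return s
        raise ConfigurationError(f"no season named '{name}' in pattern {self.label}")

    def intercrop_before(self, season_name: str) -> IntercropPeriod | None:
        for ic in self.intercrops:
            if ic.follows_season == season_name:
                return ic
        return None


# ---------------------------------------------------------------------------
# Coefficients and emission factors
# ---------------------------------------------------------------------------

@dataclass
class CropParams:
    """Per-crop allometric / stoichiometric defaults (dry-matter basis)."""

    root_to_shoot: float = 0.2
    residue_to_product: float = 1.0  # fallback when residue not measured
    c_product: float = 0.42
    c_residue: float = 0.42
    c_root: float = 0.40
    n_product: float = 0.012
    n_residue: float = 0.007
    n_root: float = 0.007
    humification: float = 0.18  # h: share of C input entering the humified pool

    def validate(self) -> "CropParams":
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            _check(v >= 0, f"crop_params.{f.name}", "must be >= 0")
        for f in ("c_product", "c_residue", "c_root", "n_product", "n_residue", "n_root", "humification"):
            _check(getattr(self, f) <= 1, f"crop_params.{f}", "fraction must be <= 1")
        return self


@dataclass
class CropCoefficients:
    """Crop coefficient table with a 'default' fallback row."""

    table: dict[str, CropParams] = field(default_factory=dict)

    def get(self, crop: str) -> CropParams:
        if crop in self.table:
            return self.table[crop]
        if "default" in self.table:
            return self.table["default"]
        raise ConfigurationError(f"no crop coefficients for '{crop}' and no default row")

    def validate(self) -> "CropCoefficients":
        for p in self.table.values():
            p.validate()
        return self


@dataclass
class EmissionFactorTable:
    """Versioned table of every Tier 1, GWP, SOC, weed-model and upstream factor.

    Shipped defaults live in ``cropgate/data/default_factors.yaml``; any entry
    can be overridden by pointing the loader at a user file.
    """

    version_tag: str
    ch4_baseline_daily: dict[str, float]  # scope key: "global" or "regional:<region>"
    sf_water: dict[str, float]
    sf_preseason: dict[str, float]
    cfoa: dict[str, float]
    ef1: dict[str, float]  # keys: synthetic_wet, other_wet, flooded_rice
    frac_gasf: float
    frac_gasm: float
    ef4: float
    frac_leach: float
    ef5: float
    gwp100: dict[str, float]
    upstream: dict[str, Any]
    grid_factors: dict[str, float]
    weed: dict[str, Any]
    soc: dict[str, float]
    crop_coefficients: CropCoefficients = field(default_factory=CropCoefficients)
    default_ch4_scope: str = "global"

    def validate(self) -> "EmissionFactorTable":
        for name in ("ch4_baseline_daily", "sf_water", "sf_preseason", "cfoa", "ef1", "gwp100"):
            _check(
                all(v >= 0 for v in getattr(self, name).values()),
                f"factors.{name}",
                "all factors must be >= 0",
            )
        _check(
            abs(self.sf_water.get(WaterRegime.CONTINUOUSLY_FLOODED.value, 1.0) - 1.0) < 1e-12,
            "factors.sf_water",
            "SFw for continuously_flooded must equal 1",
        )
        for scalar in ("frac_gasf", "frac_gasm", "ef4", "frac_leach", "ef5"):
            _check(getattr(self, scalar) >= 0, f"factors.{scalar}", "must be >= 0")
        self.crop_coefficients.validate()
        return self

    def check_covers(self, pattern: CroppingPattern) -> None:
        """Raise ConfigurationError if any enum value used by the pattern lacks an entry."""
        for s in pattern.seasons:
            if s.crop_class is not CropClass.DRYLAND:
                if s.water_regime_cultivation.value not in self.sf_water:
                    raise ConfigurationError(
                        f"no SFw entry for water regime '{s.water_regime_cultivation.value}' (season {s.name})"
                    )
                if s.preseason_regime.value not in self.sf_preseason:
                    raise ConfigurationError(
                        f"no SFp entry for pre-season regime '{s.preseason_regime.value}' (season {s.name})"
                    )
            for a in s.organic_amendments:
                if a.cfoa is None and a.type not in self.cfoa:
                    raise ConfigurationError(f"no CFOA entry for amendment type '{a.type}' (season {s.name})")

    def amendment_cfoa(self, amendment: OrganicAmendment) -> float:
        if amendment.cfoa is not None:
            return amendment.cfoa
        try:
            return self.cfoa[amendment.type]
        except KeyError:
            raise ConfigurationError(f"no CFOA entry for amendment type '{amendment.type}'") from None


# ---------------------------------------------------------------------------
# Serialization (YAML canonical form)
# ---------------------------------------------------------------------------

_ENUM_FIELDS = {
    "crop_class": CropClass,
    "water_regime_cultivation": WaterRegime,
    "preseason_regime": PreseasonRegime,
    "weed_management": WeedManagement,
}


def _to_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, enum.Enum):
        return obj.value
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def pattern_to_dict(pattern: CroppingPattern) -> dict:
    return _to_plain(pattern)


def _season_from_dict(d: Mapping[str, Any]) -> CropSeason:
    d = dict(d)
    for key, enum_cls in _ENUM_FIELDS.items():
        if key in d and d[key] is not None and not isinstance(d[key], enum_cls):
            try:
                d[key] = enum_cls(d[key])
            except ValueError:
                raise ScenarioValidationError(key, f"'{d[key]}' is not a valid {enum_cls.__name__}") from None
    d["fertilizer_inputs"] = [FertilizerInput(**f) for f in d.get("fertilizer_inputs", [])]
    d["organic_amendments"] = [OrganicAmendment(**a) for a in d.get("organic_amendments", [])]
    known = {f.name for f in dataclasses.fields(CropSeason)}
    unknown = set(d) - known
    if unknown:
        raise ScenarioValidationError(sorted(unknown)[0], "unknown field in crop season")
    return CropSeason(**d)


def pattern_from_dict(d: Mapping[str, Any]) -> CroppingPattern:
    d = dict(d)
    units = d.pop("units", {}) or {}
    seasons = [_season_from_dict(s) for s in d.get("seasons", [])]
    if units.get("yield", "Mg_per_ha") == "kg_per_ha":
        for s in seasons:
            s.product_yield_fresh /= 1000.0
            if s.residue_yield_dm is not None:
                s.residue_yield_dm /= 1000.0
    intercrops = []
    for ic in d.get("intercrops", []):
        ic = dict(ic)
        if "weed_management" in ic and not isinstance(ic["weed_management"], WeedManagement):
            ic["weed_management"] = WeedManagement(ic["weed_management"])
        intercrops.append(IntercropPeriod(**ic))
    climate = None
    if d.get("climate") is not None:
        climate = ClimateYear(**d["climate"])
    soil = None
    if d.get("soil") is not None:
        soil = SoilProfile(**d["soil"])
    return CroppingPattern(
        label=d.get("label", "unnamed"),
        seasons=seasons,
        intercrops=intercrops,
        climate=climate,
        soil=soil,
        country=d.get("country", "BGD"),
    ).validate()


def save_scenario(pattern: CroppingPattern, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(pattern_to_dict(pattern), sort_keys=False))


def factors_from_dict(d: Mapping[str, Any]) -> EmissionFactorTable:
    ch4 = d.get("ch4", {})
    n2o = d.get("n2o", {})
    upstream = dict(d.get("upstream", {}))
    grid = upstream.pop("electricity_grid", d.get("electricity_grid", {}))
    crops = CropCoefficients({name: CropParams(**row) for name, row in d.get("crops", {}).items()})
    table = EmissionFactorTable(
        version_tag=d.get("version_tag", "unversioned"),
        ch4_baseline_daily=dict(ch4.get("baseline_daily", {})),
        sf_water=dict(ch4.get("sf_water", {})),
        sf_preseason=dict(ch4.get("sf_preseason", {})),
        cfoa=dict(ch4.get("cfoa", {})),
        ef1=dict(n2o.get("ef1", {})),
        frac_gasf=float(n2o.get("frac_gasf", 0.0)),
        frac_gasm=float(n2o.get("frac_gasm", 0.0)),
        ef4=float(n2o.get("ef4", 0.0)),
        frac_leach=float(n2o.get("frac_leach", 0.0)),
        ef5=float(n2o.get("ef5", 0.0)),
        gwp100=dict(d.get("gwp100", {})),
        upstream=upstream,
        grid_factors=dict(grid),
        weed=dict(d.get("weed", {})),
        soc=dict(d.get("soc", {})),
        crop_coefficients=crops,
        default_ch4_scope=ch4.get("default_scope", "global"),
    )
    return table.validate()


def load_factors(path: str | Path | None = None) -> EmissionFactorTable:
    """Load an emission-factor table; ``None`` loads the shipped defaults."""
    if path is None:
        path = Path(__file__).parent / "data" / "default_factors.yaml"
    with open(path) as fh:
        return factors_from_dict(yaml.safe_load(fh))


def load_scenario(
    path: str | Path, factor_path: str | Path | None = None
) -> tuple[CroppingPattern, EmissionFactorTable]:
    """Load and validate a scenario file plus its factor table.

    Raises :class:`ScenarioValidationError` on any invariant violation and
    :class:`ConfigurationError` when the factor table lacks an entry the
    scenario uses.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise ScenarioValidationError("<root>", "scenario file must contain a mapping")
    pattern = pattern_from_dict(data)
    factors = load_factors(factor_path)
    factors.check_covers(pattern)
    return pattern, factors


def monthly_water_input(pattern: CroppingPattern) -> list[float]:
    """Monthly water input (mm): precipitation plus irrigation spread uniformly
    over each irrigated season's months."""
    water = list(pattern.climate.monthly_precipitation)
    for s in pattern.seasons:
        irr = pattern.climate.irrigation_by_season.get(s.name, s.irrigation_mm)
        months = season_months(s)
        if irr > 0 and months:
            for m in months:
                water[m] += irr / len(months)
    return water


def season_months(season: CropSeason) -> list[int]:
    """0-based month indices a season occupies (month = 30.42-day bins, wrapping)."""
    start_m = int((season.start_doy % DAYS_PER_YEAR) / (DAYS_PER_YEAR / 12))
    n_months = max(1, round(season.duration_days / (DAYS_PER_YEAR / 12)))
    return [(start_m + i) % 12 for i in range(n_months)]


def intercrop_months(period: IntercropPeriod) -> list[int]:
    start_m = int((period.start_doy % DAYS_PER_YEAR) / (DAYS_PER_YEAR / 12))
    n_months = max(0, round(period.duration_days / (DAYS_PER_YEAR / 12)))
    return [(start_m + i) % 12 for i in range(n_months)]
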