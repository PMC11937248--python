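"""Built-in cropping-pattern fixtures and a synthetic scenario generator.

The five fixtures encode the major rice-based rotations of the Bangladesh
floodplain study sites (R-R-R, R-F-R, M-F-R, W-Mu-R, P-R-F): season calendars,
water regimes, and residue-incorporation shares as described for those
systems.  Management values that the study does not publish (fertilizer rates,
prices, machinery passes, irrigation depths) are PLACEHOLDER defaults typical
of national fertilizer-recommendation practice; they make fixture footprints
illustrative, not reproductions of reported totals.  The placeholder block is
kept together and clearly marked below.
"""

from __future__ import annotations

import numpy as np

from .errors import UnknownLabelError
from .scenario import (
    ClimateYear,
    CropClass,
    CroppingPattern,
    CropSeason,
    FertilizerInput,
    IntercropPeriod,
    OrganicAmendment,
    PreseasonRegime,
    SoilProfile,
    WaterRegime,
    WeedManagement,
)

FIXTURE_LABELS = ("R-R-R", "R-F-R", "M-F-R", "W-Mu-R", "P-R-F")

# Subtropical monsoon climate envelope of the study region (mean ~26 degC,
# ~2000 mm annual rain, May-Oct monsoon).
_MONTHLY_T = [18.0, 21.0, 25.0, 28.0, 29.0, 29.0, 29.0, 29.0, 28.0, 27.0, 23.0, 19.0]
_MONTHLY_P = [8.0, 20.0, 45.0, 120.0, 260.0, 350.0, 400.0, 350.0, 250.0, 150.0, 30.0, 10.0]

_SOIL = dict(soc_stock_initial=40.0, clay_fraction=0.16, ph=6.8, depth_cm=15.0, cn_ratio=10.5)

# ---------------------------------------------------------------------------
# PLACEHOLDER MANAGEMENT BLOCK -- values not published by the study.
# Fertilizer rates follow typical national Fertilizer Recommendation Guide
# levels; prices, machinery passes and irrigation depths are regional
# plausibility values.  Edit freely; fixture outputs are illustrative.
# ---------------------------------------------------------------------------
_PLACEHOLDER = {
    #            N     P    K    S   irrig  pest  price_p price_r
    "boro":     (150.0, 25.0, 70.0, 12.0, 800.0, 1.0, 250.0, 20.0),
    "aus":      (80.0, 15.0, 40.0, 8.0, 0.0, 1.0, 250.0, 20.0),
    "aman":     (110.0, 18.0, 50.0, 10.0, 150.0, 1.0, 250.0, 20.0),
    "maize":    (210.0, 40.0, 90.0, 15.0, 200.0, 0.5, 220.0, 10.0),
    "wheat":    (110.0, 28.0, 45.0, 10.0, 100.0, 0.5, 280.0, 15.0),
    "mungbean": (20.0, 18.0, 30.0, 8.0, 50.0, 0.5, 900.0, 10.0),
    "potato":   (130.0, 30.0, 110.0, 12.0, 150.0, 1.0, 150.0, 0.0),
}
_MACHINERY = {"land_preparation": 3, "spraying": 1}
# ---------------------------------------------------------------------------


def _season(
    name: str,
    crop: str,
    crop_class: CropClass,
    start_doy: int,
    duration: int,
    fresh_yield: float,
    moisture: float,
    residue_dm: float,
    incorporated: float,
    water_regime: WaterRegime,
    amendments: list[OrganicAmendment] | None = None,
) -> CropSeason:
    n, p, k, s, irrig, pest, price_p, price_r = _PLACEHOLDER[name]
    fates = {
        "incorporated": incorporated,
        "harvested": max(0.0, 1.0 - incorporated - 0.10),
        "burned": min(0.10, 1.0 - incorporated),
        "grazed": 0.0,
    }
    return CropSeason(
        name=name,
        crop=crop,
        crop_class=crop_class,
        start_doy=start_doy,
        duration_days=duration,
        product_yield_fresh=fresh_yield,
        product_moisture=moisture,
        residue_yield_dm=residue_dm,
        residue_fate_shares=fates,
        fertilizer_inputs=[
            FertilizerInput("urea", n=n),
            FertilizerInput("tsp", p=p),
            FertilizerInput("mop", k=k),
            FertilizerInput("gypsum", s=s),
        ],
        organic_amendments=amendments or [],
        water_regime_cultivation=water_regime,
        preseason_regime=(
            PreseasonRegime.NONFLOODED_30_180
            if crop_class is not CropClass.DRYLAND
            else PreseasonRegime.NONFLOODED_GT180
        ),
        irrigation_mm=irrig,
        machinery_passes=dict(_MACHINERY),
        pesticide_applications=pest,
        price_product=price_p,
        price_residue=price_r,
    )


def _straw(rate: float, long_lag: bool = False) -> OrganicAmendment:
    """Incorporated straw from the preceding season as a CH4-relevant amendment."""
    return OrganicAmendment(type="straw_long" if long_lag else "straw_short", rate=rate)


def _pattern(label: str, seasons, intercrops) -> CroppingPattern:
    climate = ClimateYear(
        monthly_temperature=list(_MONTHLY_T),
        monthly_precipitation=list(_MONTHLY_P),
        irrigation_by_season={s.name: s.irrigation_mm for s in seasons},
    )
    return CroppingPattern(
        label=label,
        seasons=list(seasons),
        intercrops=list(intercrops),
        climate=climate,
        soil=SoilProfile(**_SOIL),
        country="BGD",
    ).validate()


def _build_rrr() -> CroppingPattern:
    # boro mid-Dec..mid-May, aus mid-May..mid-Aug (no irrigation), aman Aug..Dec
    boro = _season("boro", "rice", CropClass.FLOODED_RICE, 349, 145, 6.875, 0.12,
                   6.5, 0.15, WaterRegime.CONTINUOUSLY_FLOODED,
                   amendments=[_straw(5.0 * 0.15)])           # aman straw, short lag
    aus = _season("aus", "rice", CropClass.FLOODED_RICE, 135, 92, 4.0, 0.12,
                  3.8, 0.15, WaterRegime.RAINFED,
                  amendments=[_straw(6.5 * 0.15)])            # boro straw
    aman = _season("aman", "rice", CropClass.FLOODED_RICE, 228, 120, 5.26, 0.12,
                   5.0, 0.15, WaterRegime.INTERMITTENT_SINGLE,
                   amendments=[_straw(3.8 * 0.15)])           # aus straw
    return _pattern("R-R-R", [boro, aus, aman], [])


def _build_rfr() -> CroppingPattern:
    boro = _season("boro", "rice", CropClass.FLOODED_RICE, 349, 145, 6.875, 0.12,
                   6.5, 0.15, WaterRegime.CONTINUOUSLY_FLOODED,
                   amendments=[_straw(5.0 * 0.15)])
    aman = _season("aman", "rice", CropClass.FLOODED_RICE, 213, 135, 5.26, 0.12,
                   5.0, 0.15, WaterRegime.INTERMITTENT_SINGLE,
                   amendments=[_straw(6.5 * 0.15, long_lag=True)])  # boro straw across fallow
    fallow = IntercropPeriod(duration_weeks=12, weed_management=WeedManagement.NONE,
                             flooded=False, start_doy=129, follows_season="aman")
    return _pattern("R-F-R", [boro, aman], [fallow])


def _build_mfr() -> CroppingPattern:
    maize = _season("maize", "maize", CropClass.DRYLAND, 349, 150, 10.47, 0.14,
                    11.0, 0.30, WaterRegime.NONE)
    aman = _season("aman", "rice", CropClass.FLOODED_RICE, 202, 131, 5.7, 0.12,
                   5.5, 0.30, WaterRegime.INTERMITTENT_SINGLE,
                   amendments=[_straw(11.0 * 0.30, long_lag=True)])
    fallow = IntercropPeriod(duration_weeks=12, weed_management=WeedManagement.NONE,
                             flooded=False, start_doy=134, follows_season="aman")
    return _pattern("M-F-R", [maize, aman], [fallow])


def _build_wmur() -> CroppingPattern:
    # Wheat here grew on a high-water-table field that stayed wet all season;
    # represented as waterlogged_nonrice with an explicit regime (opt-in CH4).
    wheat = _season("wheat", "wheat", CropClass.WATERLOGGED_NONRICE, 319, 150, 4.07, 0.14,
                    4.0, 0.15, WaterRegime.INTERMITTENT_SINGLE)
    mungbean = _season("mungbean", "mungbean", CropClass.DRYLAND, 105, 91, 0.89, 0.10,
                       1.8, 1.0, WaterRegime.NONE)
    aman = _season("aman", "rice", CropClass.FLOODED_RICE, 213, 106, 5.26, 0.12,
                   5.0, 0.15, WaterRegime.INTERMITTENT_SINGLE,
                   amendments=[_straw(1.8 * 1.0)])            # mungbean residue
    return _pattern("W-Mu-R", [wheat, mungbean, aman], [])


def _build_prf() -> CroppingPattern:
    potato = _season("potato", "potato", CropClass.DRYLAND, 319, 92, 17.0, 0.78,
                     1.2, 1.0, WaterRegime.NONE)
    aman = _season("aman", "rice", CropClass.FLOODED_RICE, 202, 133, 5.7, 0.12,
                   5.5, 0.30, WaterRegime.INTERMITTENT_SINGLE,
                   amendments=[_straw(1.2 * 1.0, long_lag=True)])
    # Table-1 calendar: the fallow spans potato harvest (mid Feb) to aman
    # transplanting (late Jul), so its weed inputs attribute forward to aman.
    fallow = IntercropPeriod(duration_weeks=16, weed_management=WeedManagement.NONE,
                             flooded=False, start_doy=47, follows_season="aman")
    return _pattern("P-R-F", [potato, aman], [fallow])


_BUILDERS = {
    "R-R-R": _build_rrr,
    "R-F-R": _build_rfr,
    "M-F-R": _build_mfr,
    "W-Mu-R": _build_wmur,
    "P-R-F": _build_prf,
}


def builtin_fixture(label: str) -> CroppingPattern:
    """Return the encoded cropping pattern for one of the five study rotations.

    Raises :class:`UnknownLabelError` for any other label.
    """
    try:
        builder = _BUILDERS[label]
    except KeyError:
        raise UnknownLabelError(
            f"unknown fixture label '{label}'; available: {', '.join(FIXTURE_LABELS)}"
        ) from None
    return builder()


def synth_scenario(seed: int, n_seasons: int = 2, flooded_fraction: float = 0.5) -> CroppingPattern:
    """Generate a random but valid cropping pattern.

    Deterministic for a fixed seed.  The climate is drawn inside a subtropical
    monsoon envelope (mean temperature about 26 degC, annual rainfall
    1800-2200 mm with a May-October monsoon peak); season calendars, yields,
    residue fates and fertilizer rates are drawn from realistic smallholder
    ranges, and the result always passes :meth:`CroppingPattern.validate`.
    """
    if n_seasons < 1:
        raise ValueError("n_seasons must be >= 1")
    rng = np.random.default_rng(seed)

    target_rain = rng.uniform(1800.0, 2200.0)
    shape = np.array(_MONTHLY_P)
    precip = (shape / shape.sum() * target_rain).tolist()
    temps = (np.array(_MONTHLY_T) + rng.normal(0.0, 0.8, 12)).round(1).tolist()

    # Partition the year: leave room for short gaps between seasons.
    max_days = 350
    durations = rng.integers(80, 150, size=n_seasons)
    while durations.sum() > max_days - 10 * n_seasons:
        durations = np.maximum(60, durations - 10)
    gaps = rng.integers(0, max(1, (max_days - int(durations.sum())) // n_seasons), size=n_seasons)

    seasons: list[CropSeason] = []
    intercrops: list[IntercropPeriod] = []
    doy = int(rng.integers(1, 60))
    for i in range(n_seasons):
        flooded = rng.random() < flooded_fraction
        name = f"season_{i + 1}"
        dur = int(durations[i])
        if flooded:
            regimes = [
                WaterRegime.CONTINUOUSLY_FLOODED,
                WaterRegime.INTERMITTENT_SINGLE,
                WaterRegime.INTERMITTENT_MULTIPLE,
                WaterRegime.RAINFED,
            ]
            regime = regimes[int(rng.integers(len(regimes)))]
            crop_class = CropClass.FLOODED_RICE
            crop = "rice"
            moisture = 0.12
        else:
            regime = WaterRegime.NONE
            crop_class = CropClass.DRYLAND
            crop = str(rng.choice(["maize", "wheat", "potato", "mungbean"]))
            moisture = 0.14 if crop in ("maize", "wheat") else 0.5
        inc = float(rng.uniform(0.10, 1.0))
        fresh = float(rng.uniform(1.0, 12.0))
        residue = float(rng.uniform(0.5, 8.0))
        season = CropSeason(
            name=name,
            crop=crop,
            crop_class=crop_class,
            start_doy=doy,
            duration_days=dur,
            product_yield_fresh=fresh,
            product_moisture=moisture,
            residue_yield_dm=residue,
            residue_fate_shares={
                "incorporated": inc,
                "harvested": min(1.0 - inc, round(float(rng.uniform(0.0, 1.0 - inc)), 3)),
                "burned": 0.0,
                "grazed": 0.0,
            },
            fertilizer_inputs=[FertilizerInput("urea", n=float(rng.uniform(0.0, 250.0))),
                               FertilizerInput("tsp", p=float(rng.uniform(0.0, 40.0)))],
            organic_amendments=(
                [OrganicAmendment("straw_short", rate=float(rng.uniform(0.0, 3.0)))]
                if rng.random() < 0.5 else []
            ),
            water_regime_cultivation=regime,
            preseason_regime=(list(PreseasonRegime)[int(rng.integers(4))] if flooded else PreseasonRegime.NONFLOODED_GT180),
            irrigation_mm=float(rng.uniform(0.0, 900.0)) if flooded else float(rng.uniform(0.0, 300.0)),
            machinery_passes={"land_preparation": int(rng.integers(1, 5)), "spraying": 1},
            pesticide_applications=float(rng.uniform(0.0, 2.0)),
            price_product=float(rng.uniform(100.0, 900.0)),
            price_residue=float(rng.uniform(0.0, 50.0)),
        )
        seasons.append(season)
        gap = int(gaps[i])
        if gap >= 21:  # represent gaps of >= 3 weeks as explicit fallows
            intercrops.append(IntercropPeriod(
                duration_weeks=gap / 7.0,
                weed_management=list(WeedManagement)[int(rng.integers(3))],
                flooded=False,
                start_doy=(doy + dur) % 365,
                follows_season=f"season_{i + 2}" if i + 1 < n_seasons else name,
            ))
        doy = (doy + dur + gap) % 365

    climate = ClimateYear(
        monthly_temperature=temps,
        monthly_precipitation=precip,
        irrigation_by_season={s.name: s.irrigation_mm for s in seasons},
    )
    soil = SoilProfile(
        soc_stock_initial=float(rng.uniform(20.0, 60.0)),
        clay_fraction=float(rng.uniform(0.10, 0.35)),
        ph=float(rng.uniform(5.5, 7.5)),
        cn_ratio=float(rng.uniform(8.0, 14.0)),
    )
    return CroppingPattern(
        label=f"synthetic-{seed}",
        seasons=seasons,
        intercrops=intercrops,
        climate=climate,
        soil=soil,
    ).validate()
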