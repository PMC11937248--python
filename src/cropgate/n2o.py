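"""IPCC Tier 1 nitrous oxide: direct and indirect pathways from the N-input ledger.

Direct N2O-N is a fixed emission factor per kg N input, disaggregated by input
type (synthetic vs other) and by crop water status (flooded rice uses its own
lower factor for all inputs).  Indirect N2O follows volatilized N (FracGAS x
EF4) and leached N (FracLEACH x EF5).  Everything is strictly linear in the
ledger entries -- the Tier 1 premise.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigurationError, DomainError
from .npp import NppComponents
from .scenario import CropClass, CropSeason, EmissionFactorTable

N2ON_TO_N2O = 44.0 / 28.0  # molecular weight ratio N2O / N2


@dataclass
class NInputLedger:
    """Per-season nitrogen inputs, kg N ha-1."""

    synthetic_n: float = 0.0
    residue_ag_n: float = 0.0  # above-ground residue N actually returned (incorporated share)
    residue_bg_n: float = 0.0  # root N, fully returned
    weed_n: float = 0.0  # weed AG + BG N, fully returned
    som_mineralized_n: float = 0.0  # net N released by SOC loss

    @property
    def total(self) -> float:
        return (
            self.synthetic_n
            + self.residue_ag_n
            + self.residue_bg_n
            + self.weed_n
            + self.som_mineralized_n
        )

    @property
    def organic_n(self) -> float:
        """Non-synthetic (recycled) N: residues, weeds and mineralized SOM."""
        return self.total - self.synthetic_n

    def validate(self) -> "NInputLedger":
        for name in ("synthetic_n", "residue_ag_n", "residue_bg_n", "weed_n", "som_mineralized_n"):
            if getattr(self, name) < 0:
                raise DomainError(f"N ledger entry {name} must be >= 0")
        return self


@dataclass
class N2oEstimate:
    """Season N2O in kg N2O-N ha-1, by pathway and by source."""

    direct_n: float
    volatilization_n: float
    leaching_n: float
    by_source: dict[str, float]

    @property
    def total_n(self) -> float:
        return self.direct_n + self.volatilization_n + self.leaching_n

    @property
    def total_n2o(self) -> float:
        """Total as N2O mass (kg N2O ha-1), 44/28 conversion."""
        return self.total_n * N2ON_TO_N2O


def build_n_ledger(
    npp: NppComponents,
    season: CropSeason,
    som_min_n: float = 0.0,
    intercrop_weed_n: float = 0.0,
) -> NInputLedger:
    """Assemble the N-input ledger for one season from its NPP components.

    Above-ground residue N is scaled by the incorporated fate share only;
    below-ground (root) and weed N are returned in full.  ``intercrop_weed_n``
    adds the preceding fallow's weed N (attributed forward to this season).
    """
    incorporated = season.residue_fate_shares.get("incorporated", 0.0)
    return NInputLedger(
        synthetic_n=season.total_fertilizer_n,
        residue_ag_n=npp.n["residue_ag"] * incorporated,
        residue_bg_n=npp.n["root_bg"],
        weed_n=npp.n["weed_ag"] + npp.n["weed_bg"] + intercrop_weed_n,
        som_mineralized_n=som_min_n,
    ).validate()


def _ef1(factors: EmissionFactorTable, source: str, crop_class: CropClass) -> float:
    """EF1 lookup: flooded/waterlogged crops use the rice factor for all inputs."""
    if crop_class in (CropClass.FLOODED_RICE, CropClass.WATERLOGGED_NONRICE):
        key = "flooded_rice"
    else:
        key = "synthetic_wet" if source == "synthetic" else "other_wet"
    try:
        return factors.ef1[key]
    except KeyError:
        raise ConfigurationError(f"no EF1 entry '{key}' (source {source}, class {crop_class.value})") from None


def direct_n2o(ledger: NInputLedger, crop_class: CropClass, factors: EmissionFactorTable) -> N2oEstimate:
    """Direct N2O-N: sum over sources of N x EF1(source, crop class)."""
    sources = {
        "synthetic": ledger.synthetic_n,
        "residue_ag": ledger.residue_ag_n,
        "residue_bg": ledger.residue_bg_n,
        "weed": ledger.weed_n,
        "som": ledger.som_mineralized_n,
    }
    by_source = {
        src: n * _ef1(factors, "synthetic" if src == "synthetic" else "other", crop_class)
        for src, n in sources.items()
    }
    return N2oEstimate(
        direct_n=sum(by_source.values()),
        volatilization_n=0.0,
        leaching_n=0.0,
        by_source=by_source,
    )


def indirect_n2o(
    ledger: NInputLedger,
    crop_class: CropClass,
    factors: EmissionFactorTable,
    leaching_occurs: bool = True,
) -> tuple[float, float]:
    """Indirect N2O-N via volatilization and leaching (kg N2O-N ha-1).

    Volatilization: synthetic N x FracGASF x EF4 plus organic-origin N x
    FracGASM x EF4.  Leaching: total N x FracLEACH x EF5, suppressed when the
    scenario marks leaching as not occurring.
    """
    vol = (
        ledger.synthetic_n * factors.frac_gasf + ledger.organic_n * factors.frac_gasm
    ) * factors.ef4
    leach = ledger.total * factors.frac_leach * factors.ef5 if leaching_occurs else 0.0
    return vol, leach


def season_n2o(
    ledger: NInputLedger,
    season: CropSeason,
    factors: EmissionFactorTable,
) -> N2oEstimate:
    """Full Tier 1 N2O estimate (direct + both indirect pathways) for a season."""
    est = direct_n2o(ledger, season.crop_class, factors)
    vol, leach = indirect_n2o(ledger, season.crop_class, factors, season.leaching_occurs)
    return N2oEstimate(
        direct_n=est.direct_n,
        volatilization_n=vol,
        leaching_n=leach,
        by_source=est.by_source,
    )


def measured_vs_estimate_ratio(measured: float, estimate: float) -> tuple[float, str]:
    """Symmetric measured-vs-Tier-1 ratio: (max/min, which side is larger)."""
    if measured <= 0 or estimate <= 0:
        raise DomainError("measured and estimated values must both be > 0")
    if measured >= estimate:
        return measured / estimate, "measured_higher"
    return estimate / measured, "estimate_higher"
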