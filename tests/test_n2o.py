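"""Tier 1 N2O: ledger assembly, linearity, indirect pathways, ratios."""

import numpy as np
import pytest

import cropgate as cg
from cropgate.n2o import (
    N2ON_TO_N2O,
    NInputLedger,
    build_n_ledger,
    direct_n2o,
    indirect_n2o,
    measured_vs_estimate_ratio,
)


def random_ledger(rng):
    return NInputLedger(*rng.uniform(0.0, 200.0, 5))


class TestLedger:
    def test_total_is_exact_sum(self):
        led = NInputLedger(10.0, 5.0, 3.0, 2.0, 1.0)
        assert led.total == pytest.approx(21.0)
        assert led.organic_n == pytest.approx(11.0)

    def test_residue_scaled_by_incorporated_share_only(self, factors, coeffs):
        season = cg.builtin_fixture("R-F-R").season("boro")
        season.residue_yield_dm = 4.0
        season.residue_fate_shares = {"incorporated": 0.15, "harvested": 0.85}
        season.fertilizer_inputs = []
        comp = cg.season_npp(season, coeffs, factors)
        comp.n["residue_ag"] = 4.0 * 0.008 * 1000.0  # 0.8% N content
        led = build_n_ledger(comp, season)
        assert led.residue_ag_n == pytest.approx(4.8)

    def test_zero_input_season_gives_zero_ledger(self, factors, coeffs):
        season = cg.builtin_fixture("R-F-R").season("boro")
        season.fertilizer_inputs = []
        season.product_yield_fresh = 0.0
        season.residue_yield_dm = 0.0
        comp = cg.season_npp(season, coeffs, factors)
        assert build_n_ledger(comp, season).total == 0.0

    def test_mungbean_som_is_largest_ledger_entry(self, fixture_reports):
        led = next(s for s in fixture_reports["W-Mu-R"].seasons if s.name == "mungbean").n_ledger
        entries = {
            "synthetic": led.synthetic_n,
            "residue_ag": led.residue_ag_n,
            "residue_bg": led.residue_bg_n,
            "weed": led.weed_n,
            "som": led.som_mineralized_n,
        }
        assert max(entries, key=entries.get) == "som"
        assert led.som_mineralized_n / led.total > 0.4


class TestDirectN2o:
    def test_zero_ledger_gives_zero(self, factors):
        assert direct_n2o(NInputLedger(), cg.CropClass.DRYLAND, factors).direct_n == 0.0

    def test_synthetic_ef_arithmetic(self, factors):
        factors.ef1["synthetic_wet"] = 0.016
        led = NInputLedger(synthetic_n=100.0)
        assert direct_n2o(led, cg.CropClass.DRYLAND, factors).direct_n == pytest.approx(1.6)

    def test_flooded_rice_uses_lower_ef_for_all_sources(self, factors):
        led = NInputLedger(100.0, 10.0, 10.0, 5.0, 5.0)
        rice = direct_n2o(led, cg.CropClass.FLOODED_RICE, factors).direct_n
        dry = direct_n2o(led, cg.CropClass.DRYLAND, factors).direct_n
        assert rice == pytest.approx(led.total * factors.ef1["flooded_rice"])
        assert rice < dry

    def test_shipped_defaults_keep_rice_ef_below_synthetic_wet(self, factors):
        assert factors.ef1["flooded_rice"] < factors.ef1["synthetic_wet"]

    def test_superposition_against_brute_force(self, factors):
        # strict linearity: f(a + b) = f(a) + f(b), and direct == sum N x EF
        rng = np.random.default_rng(11)
        for crop_class in (cg.CropClass.DRYLAND, cg.CropClass.FLOODED_RICE):
            for _ in range(500):
                a, b = random_ledger(rng), random_ledger(rng)
                fa = direct_n2o(a, crop_class, factors).direct_n
                fb = direct_n2o(b, crop_class, factors).direct_n
                ab = NInputLedger(
                    a.synthetic_n + b.synthetic_n,
                    a.residue_ag_n + b.residue_ag_n,
                    a.residue_bg_n + b.residue_bg_n,
                    a.weed_n + b.weed_n,
                    a.som_mineralized_n + b.som_mineralized_n,
                )
                assert direct_n2o(ab, crop_class, factors).direct_n == pytest.approx(fa + fb, rel=1e-9)
                if crop_class is cg.CropClass.DRYLAND:
                    oracle = a.synthetic_n * factors.ef1["synthetic_wet"] + a.organic_n * factors.ef1["other_wet"]
                    assert fa == pytest.approx(oracle, rel=1e-12)

    def test_halving_ledger_halves_output(self, factors):
        led = NInputLedger(120.0, 30.0, 20.0, 10.0, 5.0)
        half = NInputLedger(60.0, 15.0, 10.0, 5.0, 2.5)
        full = direct_n2o(led, cg.CropClass.DRYLAND, factors).direct_n
        assert direct_n2o(half, cg.CropClass.DRYLAND, factors).direct_n == pytest.approx(full / 2)


class TestIndirectN2o:
    def test_zero_ledger_gives_zero(self, factors):
        assert indirect_n2o(NInputLedger(), cg.CropClass.DRYLAND, factors) == (0.0, 0.0)

    def test_volatilization_arithmetic(self, factors):
        factors = cg.load_factors()
        factors.frac_gasf = 0.15
        factors.ef4 = 0.010
        vol, _ = indirect_n2o(NInputLedger(synthetic_n=100.0), cg.CropClass.DRYLAND, factors)
        assert vol == pytest.approx(100.0 * 0.15 * 0.010)  # 0.15 kg N2O-N

    def test_leaching_suppressed_when_marked_absent(self, factors):
        led = NInputLedger(100.0, 10.0, 10.0, 0.0, 0.0)
        _, leach_on = indirect_n2o(led, cg.CropClass.DRYLAND, factors, leaching_occurs=True)
        _, leach_off = indirect_n2o(led, cg.CropClass.DRYLAND, factors, leaching_occurs=False)
        assert leach_on > 0 and leach_off == 0.0

    def test_volatilization_exceeds_leaching_on_all_fixtures(self, fixture_reports):
        for report in fixture_reports.values():
            for s in report.seasons:
                assert s.n2o.volatilization_n >= s.n2o.leaching_n

    def test_totals_decompose(self, fixture_reports):
        for report in fixture_reports.values():
            for s in report.seasons:
                assert s.n2o.total_n == pytest.approx(
                    s.n2o.direct_n + s.n2o.volatilization_n + s.n2o.leaching_n
                )


class TestUnitConversions:
    def test_n2o_n_mass_conversion_round_trips(self):
        assert N2ON_TO_N2O == 44.0 / 28.0
        x = 1.94
        assert x * N2ON_TO_N2O / N2ON_TO_N2O == pytest.approx(x, rel=1e-15)


class TestMeasuredRatio:
    @pytest.mark.parametrize(
        "measured, estimate, ratio, direction",
        [
            (1.08, 0.73, 1.47, "measured_higher"),
            (2.62, 2.3, 1.13, "measured_higher"),
            (0.31, 0.65, 2.09, "estimate_higher"),
        ],
    )
    def test_reported_season_pairs(self, measured, estimate, ratio, direction):
        r, d = measured_vs_estimate_ratio(measured, estimate)
        assert r == pytest.approx(ratio, abs=0.01)  # reported pairs truncate at 2 decimals
        assert d == direction

    def test_nonpositive_inputs_raise(self):
        with pytest.raises(cg.DomainError):
            measured_vs_estimate_ratio(0.0, 1.0)
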