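"""Scenario types, validation, YAML round-trip, fixtures and the generator."""

import dataclasses

import pytest
import yaml

import cropgate as cg
from cropgate.scenario import pattern_from_dict, pattern_to_dict


class TestValidation:
    def test_residue_shares_over_one_raise_named_error(self, all_fixture_patterns):
        p = cg.builtin_fixture("R-F-R")
        p.seasons[0].residue_fate_shares = {"harvested": 0.8, "incorporated": 0.4}
        with pytest.raises(cg.ScenarioValidationError) as exc:
            p.validate()
        assert exc.value.field == "residue_fate_shares"

    @pytest.mark.parametrize(
        "mutate, field",
        [
            (lambda s: setattr(s, "duration_days", 0), "duration_days"),
            (lambda s: setattr(s, "product_moisture", 1.0), "product_moisture"),
            (lambda s: setattr(s, "irrigation_mm", -1.0), "irrigation_mm"),
            (
                lambda s: setattr(s, "water_regime_cultivation", cg.WaterRegime.NONE),
                "water_regime_cultivation",
            ),
        ],
    )
    def test_season_invariants(self, mutate, field):
        season = cg.builtin_fixture("R-R-R").seasons[0]  # boro, flooded rice
        mutate(season)
        with pytest.raises(cg.ScenarioValidationError) as exc:
            season.validate()
        assert exc.value.field == field

    def test_climate_needs_twelve_months(self):
        with pytest.raises(cg.ScenarioValidationError):
            cg.ClimateYear(monthly_temperature=[20.0] * 11, monthly_precipitation=[10.0] * 12).validate()

    def test_annual_water_is_precip_plus_irrigation(self):
        c = cg.ClimateYear(
            monthly_temperature=[25.0] * 12,
            monthly_precipitation=[100.0] * 12,
            irrigation_by_season={"boro": 500.0, "aman": 100.0},
        ).validate()
        assert c.annual_water_input == pytest.approx(12 * 100.0 + 600.0)

    def test_missing_factor_for_used_enum_is_configuration_error(self, all_fixture_patterns):
        factors = cg.load_factors()
        del factors.sf_water["continuously_flooded"]
        with pytest.raises(cg.ConfigurationError):
            factors.check_covers(cg.builtin_fixture("R-R-R"))


class TestRoundTrip:
    @pytest.mark.parametrize("label", cg.FIXTURE_LABELS)
    def test_save_load_is_lossless(self, label, tmp_path):
        p = cg.builtin_fixture(label)
        path = tmp_path / "scenario.yaml"
        cg.save_scenario(p, path)
        reloaded, factors = cg.load_scenario(path)
        assert pattern_to_dict(reloaded) == pattern_to_dict(p)
        assert factors.version_tag  # default table loaded alongside

    def test_kg_per_ha_yields_normalized_at_load(self):
        d = pattern_to_dict(cg.builtin_fixture("R-F-R"))
        for s in d["seasons"]:
            s["product_yield_fresh"] *= 1000.0
            s["residue_yield_dm"] *= 1000.0
        d["units"] = {"yield": "kg_per_ha"}
        p = pattern_from_dict(d)
        ref = cg.builtin_fixture("R-F-R")
        assert p.seasons[0].product_yield_fresh == pytest.approx(ref.seasons[0].product_yield_fresh)

    def test_invalid_enum_value_names_field(self, tmp_path):
        d = pattern_to_dict(cg.builtin_fixture("R-F-R"))
        d["seasons"][0]["water_regime_cultivation"] = "sometimes_wet"
        path = tmp_path / "bad.yaml"
        path.write_text(yaml.safe_dump(d))
        with pytest.raises(cg.ScenarioValidationError) as exc:
            cg.load_scenario(path)
        assert exc.value.field == "water_regime_cultivation"


class TestFixtures:
    def test_labels_cover_the_five_rotations(self):
        assert set(cg.FIXTURE_LABELS) == {"R-R-R", "R-F-R", "M-F-R", "W-Mu-R", "P-R-F"}

    def test_unknown_label_raises(self):
        with pytest.raises(cg.UnknownLabelError):
            cg.builtin_fixture("X-Y-Z")

    def test_rfr_has_two_seasons_and_a_twelve_week_fallow(self):
        p = cg.builtin_fixture("R-F-R")
        assert [s.name for s in p.seasons] == ["boro", "aman"]
        assert len(p.intercrops) == 1
        assert p.intercrops[0].duration_weeks == pytest.approx(12, abs=1)

    def test_rrr_is_triple_rice_with_rainfed_aus(self):
        p = cg.builtin_fixture("R-R-R")
        assert [s.crop for s in p.seasons] == ["rice"] * 3
        aus = p.season("aus")
        assert aus.irrigation_mm == 0.0
        assert aus.water_regime_cultivation is cg.WaterRegime.RAINFED

    def test_prf_residue_incorporation_full_for_potato_partial_for_rice(self):
        p = cg.builtin_fixture("P-R-F")
        assert p.season("potato").residue_fate_shares["incorporated"] == pytest.approx(1.0)
        assert p.season("aman").residue_fate_shares["incorporated"] == pytest.approx(0.30)

    @pytest.mark.parametrize("label", cg.FIXTURE_LABELS)
    def test_fixture_calendars_fit_the_year(self, label):
        p = cg.builtin_fixture(label)
        covered = sum(s.duration_days for s in p.seasons) + sum(ic.duration_days for ic in p.intercrops)
        assert covered <= 366
        p.validate()

    @pytest.mark.parametrize("label", cg.FIXTURE_LABELS)
    def test_fixture_climate_is_monsoon_envelope(self, label):
        c = cg.builtin_fixture(label).climate
        assert 1800 <= c.annual_precipitation <= 2200
        assert 24 <= sum(c.monthly_temperature) / 12 <= 28


class TestSynthScenario:
    def test_same_seed_gives_identical_pattern(self):
        a = cg.synth_scenario(seed=42, n_seasons=3)
        b = cg.synth_scenario(seed=42, n_seasons=3)
        assert pattern_to_dict(a) == pattern_to_dict(b)

    def test_different_seed_differs(self):
        assert pattern_to_dict(cg.synth_scenario(1)) != pattern_to_dict(cg.synth_scenario(2))

    def test_zero_flooded_fraction_yields_no_rice(self):
        for seed in range(20):
            p = cg.synth_scenario(seed=seed, n_seasons=3, flooded_fraction=0.0)
            assert all(s.crop_class is not cg.CropClass.FLOODED_RICE for s in p.seasons)

    def test_generated_patterns_always_validate(self):
        # property sweep: the validator is the oracle
        for seed in range(300):
            p = cg.synth_scenario(seed=seed, n_seasons=1 + seed % 4, flooded_fraction=(seed % 5) / 4)
            p.validate()
            assert 1800 <= p.climate.annual_precipitation <= 2200

    def test_generator_rejects_zero_seasons(self):
        with pytest.raises(ValueError):
            cg.synth_scenario(seed=1, n_seasons=0)
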