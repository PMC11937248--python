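{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "cropgate scenario file",
  "description": "Annual cropping pattern: ordered crop seasons, intercrop (fallow) periods, monthly climate and soil. YAML files with this structure are the canonical scenario format; validation is enforced by the loader, which raises errors naming the field and rule. All masses are Mg ha-1 unless a units block says otherwise; water in mm; calendar positions as day-of-year on a 365-day year.",
  "type": "object",
  "required": ["label", "seasons"],
  "properties": {
    "label": {"type": "string"},
    "country": {"type": "string", "description": "code into the electricity-grid factor table", "default": "BGD"},
    "units": {
      "type": "object",
      "properties": {"yield": {"enum": ["Mg_per_ha", "kg_per_ha"]}}
    },
    "seasons": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "required": ["name", "crop", "crop_class", "start_doy", "duration_days", "product_yield_fresh", "product_moisture"],
        "properties": {
          "name": {"type": "string"},
          "crop": {"type": "string", "description": "coefficient-table key, e.g. rice, maize"},
          "crop_class": {"enum": ["flooded_rice", "waterlogged_nonrice", "dryland"]},
          "start_doy": {"type": "integer"},
          "duration_days": {"type": "integer", "exclusiveMinimum": 0},
          "product_yield_fresh": {"type": "number", "minimum": 0},
          "product_moisture": {"type": "number", "minimum": 0, "exclusiveMaximum": 1},
          "residue_yield_dm": {"type": ["number", "null"], "minimum": 0},
          "residue_fate_shares": {
            "type": "object",
            "description": "each share in [0,1]; the sum must not exceed 1",
            "properties": {
              "harvested": {"type": "number", "minimum": 0, "maximum": 1},
              "incorporated": {"type": "number", "minimum": 0, "maximum": 1},
              "burned": {"type": "number", "minimum": 0, "maximum": 1},
              "grazed": {"type": "number", "minimum": 0, "maximum": 1}
            },
            "additionalProperties": false
          },
          "root_to_shoot": {"type": ["number", "null"], "minimum": 0},
          "fertilizer_inputs": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["product"],
              "properties": {
                "product": {"type": "string"},
                "n": {"type": "number", "minimum": 0},
                "p": {"type": "number", "minimum": 0},
                "k": {"type": "number", "minimum": 0},
                "s": {"type": "number", "minimum": 0}
              }
            }
          },
          "organic_amendments": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["type", "rate"],
              "properties": {
                "type": {"type": "string", "description": "CFOA table key, e.g. straw_short"},
                "rate": {"type": "number", "minimum": 0},
                "cfoa": {"type": ["number", "null"], "minimum": 0}
              }
            }
          },
          "water_regime_cultivation": {
            "enum": ["continuously_flooded", "intermittent_single", "intermittent_multiple", "rainfed", "none"],
            "description": "must not be 'none' for flooded_rice"
          },
          "preseason_regime": {"enum": ["nonflooded_lt30", "nonflooded_30_180", "nonflooded_gt180", "flooded"]},
          "irrigation_mm": {"type": "number", "minimum": 0},
          "machinery_passes": {"type": "object", "additionalProperties": {"type": "integer", "minimum": 0}},
          "pesticide_applications": {"type": "number", "minimum": 0},
          "electricity_kwh": {"type": ["number", "null"], "minimum": 0},
          "seed_rate": {"type": "number", "minimum": 0},
          "price_product": {"type": "number", "minimum": 0},
          "price_residue": {"type": "number", "minimum": 0},
          "leaching_occurs": {"type": "boolean", "default": true}
        }
      }
    },
    "intercrops": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["duration_weeks"],
        "properties": {
          "duration_weeks": {"type": "number", "minimum": 0},
          "weed_management": {"enum": ["none", "partial", "complete_control"]},
          "flooded": {"type": "boolean"},
          "start_doy": {"type": "integer"},
          "follows_season": {"type": ["string", "null"], "description": "season the fallow precedes; its weed inputs attribute forward"}
        }
      }
    },
    "climate": {
      "type": "object",
      "required": ["monthly_temperature", "monthly_precipitation"],
      "properties": {
        "monthly_temperature": {"type": "array", "minItems": 12, "maxItems": 12, "items": {"type": "number"}},
        "monthly_precipitation": {"type": "array", "minItems": 12, "maxItems": 12, "items": {"type": "number", "minimum": 0}},
        "irrigation_by_season": {"type": "object", "additionalProperties": {"type": "number", "minimum": 0}}
      }
    },
    "soil": {
      "type": "object",
      "required": ["soc_stock_initial", "clay_fraction"],
      "properties": {
        "soc_stock_initial": {"type": "number", "minimum": 0},
        "clay_fraction": {"type": "number", "minimum": 0, "maximum": 1},
        "ph": {"type": "number"},
        "depth_cm": {"type": "number", "exclusiveMinimum": 0},
        "cn_ratio": {"type": "number", "exclusiveMinimum": 0}
      }
    }
  }
}
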