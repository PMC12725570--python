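{
  "$defs": {
    "DelineateBlock": {
      "properties": {
        "current_fcn_count": {
          "title": "Current Fcn Count",
          "type": "integer"
        },
        "current_mean_length_km": {
          "title": "Current Mean Length Km",
          "type": "number"
        },
        "fcn_count_pct_change": {
          "title": "Fcn Count Pct Change",
          "type": "number"
        },
        "historical_fcn_count": {
          "title": "Historical Fcn Count",
          "type": "integer"
        },
        "historical_mean_length_km": {
          "title": "Historical Mean Length Km",
          "type": "number"
        },
        "mean_length_pct_change": {
          "title": "Mean Length Pct Change",
          "type": "number"
        }
      },
      "required": [
        "historical_fcn_count",
        "current_fcn_count",
        "fcn_count_pct_change",
        "historical_mean_length_km",
        "current_mean_length_km",
        "mean_length_pct_change"
      ],
      "title": "DelineateBlock",
      "type": "object"
    },
    "HabitatBlock": {
      "properties": {
        "mean_richness_current": {
          "title": "Mean Richness Current",
          "type": "number"
        },
        "mean_richness_historical": {
          "title": "Mean Richness Historical",
          "type": "number"
        },
        "n_classes": {
          "title": "N Classes",
          "type": "integer"
        }
      },
      "required": [
        "n_classes",
        "mean_richness_historical",
        "mean_richness_current"
      ],
      "title": "HabitatBlock",
      "type": "object"
    },
    "LinkBlock": {
      "properties": {
        "mean_length_km_pctchg": {
          "title": "Mean Length Km Pctchg",
          "type": "number"
        },
        "n_huc12": {
          "title": "N Huc12",
          "type": "integer"
        }
      },
      "required": [
        "n_huc12",
        "mean_length_km_pctchg"
      ],
      "title": "LinkBlock",
      "type": "object"
    },
    "RfBlock": {
      "properties": {
        "n_sites": {
          "title": "N Sites",
          "type": "integer"
        },
        "oob_r2_mad": {
          "title": "Oob R2 Mad",
          "type": "number"
        },
        "oob_r2_median": {
          "title": "Oob R2 Median",
          "type": "number"
        },
        "predictors_kept": {
          "items": {
            "type": "string"
          },
          "title": "Predictors Kept",
          "type": "array"
        },
        "spatial_predictors_used": {
          "items": {
            "type": "string"
          },
          "title": "Spatial Predictors Used",
          "type": "array"
        },
        "top_predictors": {
          "items": {
            "type": "string"
          },
          "title": "Top Predictors",
          "type": "array"
        }
      },
      "required": [
        "n_sites",
        "predictors_kept",
        "spatial_predictors_used",
        "oob_r2_median",
        "oob_r2_mad",
        "top_predictors"
      ],
      "title": "RfBlock",
      "type": "object"
    },
    "TbiBlock": {
      "properties": {
        "dominance_direction": {
          "title": "Dominance Direction",
          "type": "string"
        },
        "dominance_p": {
          "title": "Dominance P",
          "type": "number"
        },
        "mean_B": {
          "title": "Mean B",
          "type": "number"
        },
        "mean_C": {
          "title": "Mean C",
          "type": "number"
        },
        "mean_D": {
          "title": "Mean D",
          "type": "number"
        },
        "n_significant_sites": {
          "title": "N Significant Sites",
          "type": "integer"
        },
        "n_significant_species": {
          "title": "N Significant Species",
          "type": "integer"
        },
        "n_sites": {
          "title": "N Sites",
          "type": "integer"
        }
      },
      "required": [
        "mean_D",
        "mean_B",
        "mean_C",
        "dominance_direction",
        "dominance_p",
        "n_significant_sites",
        "n_sites",
        "n_significant_species"
      ],
      "title": "TbiBlock",
      "type": "object"
    },
    "ValidateBlock": {
      "properties": {
        "n_reaches": {
          "title": "N Reaches",
          "type": "integer"
        },
        "n_termini": {
          "title": "N Termini",
          "type": "integer"
        },
        "total_length_km": {
          "title": "Total Length Km",
          "type": "number"
        }
      },
      "required": [
        "n_reaches",
        "n_termini",
        "total_length_km"
      ],
      "title": "ValidateBlock",
      "type": "object"
    }
  },
  "additionalProperties": true,
  "properties": {
    "config": {
      "additionalProperties": true,
      "title": "Config",
      "type": "object"
    },
    "delineate": {
      "anyOf": [
        {
          "$ref": "#/$defs/DelineateBlock"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    },
    "habitat": {
      "anyOf": [
        {
          "$ref": "#/$defs/HabitatBlock"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    },
    "link": {
      "anyOf": [
        {
          "$ref": "#/$defs/LinkBlock"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    },
    "rf": {
      "anyOf": [
        {
          "$ref": "#/$defs/RfBlock"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    },
    "tbi": {
      "anyOf": [
        {
          "$ref": "#/$defs/TbiBlock"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    },
    "validate_": {
      "anyOf": [
        {
          "$ref": "#/$defs/ValidateBlock"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    }
  },
  "required": [
    "config"
  ],
  "title": "RunReport",
  "type": "object"
}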