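{
  "$defs": {
    "AnalysisFlags": {
      "additionalProperties": false,
      "properties": {
        "sr_form": {
          "default": "deficit",
          "enum": [
            "deficit",
            "ratio"
          ],
          "title": "Sr Form",
          "type": "string"
        },
        "baseline_mode": {
          "default": "subject",
          "enum": [
            "subject",
            "group"
          ],
          "title": "Baseline Mode",
          "type": "string"
        },
        "scoring": {
          "default": "position_free",
          "enum": [
            "position_free",
            "strict"
          ],
          "title": "Scoring",
          "type": "string"
        },
        "bf_method": {
          "default": "bic",
          "enum": [
            "bic",
            "prior-integration"
          ],
          "title": "Bf Method",
          "type": "string"
        },
        "alpha": {
          "default": 0.05,
          "exclusiveMaximum": 1,
          "exclusiveMinimum": 0,
          "title": "Alpha",
          "type": "number"
        },
        "holm": {
          "default": false,
          "title": "Holm",
          "type": "boolean"
        }
      },
      "title": "AnalysisFlags",
      "type": "object"
    },
    "CurveSpec": {
      "additionalProperties": false,
      "description": "Gamma blink-curve parameters of one generative accuracy curve.",
      "properties": {
        "shape": {
          "exclusiveMinimum": 0,
          "title": "Shape",
          "type": "number"
        },
        "scale": {
          "exclusiveMinimum": 0,
          "title": "Scale",
          "type": "number"
        },
        "baseline": {
          "maximum": 1,
          "minimum": 0,
          "title": "Baseline",
          "type": "number"
        },
        "depth": {
          "minimum": 0,
          "title": "Depth",
          "type": "number"
        },
        "noise_halfwidth": {
          "default": 0.4,
          "minimum": 0,
          "title": "Noise Halfwidth",
          "type": "number"
        }
      },
      "required": [
        "shape",
        "scale",
        "baseline",
        "depth"
      ],
      "title": "CurveSpec",
      "type": "object"
    },
    "GroupSpec": {
      "additionalProperties": false,
      "properties": {
        "t1_curve": {
          "$ref": "#/$defs/CurveSpec"
        },
        "t2_curve": {
          "$ref": "#/$defs/CurveSpec"
        },
        "swap": {
          "$ref": "#/$defs/SwapSpec"
        }
      },
      "required": [
        "t1_curve",
        "t2_curve",
        "swap"
      ],
      "title": "GroupSpec",
      "type": "object"
    },
    "ProtocolSpec": {
      "additionalProperties": false,
      "description": "Presentation protocol shared by every subject of a study.",
      "properties": {
        "toas_ms": {
          "items": {
            "type": "integer"
          },
          "minItems": 1,
          "title": "Toas Ms",
          "type": "array"
        },
        "soa_by_group": {
          "additionalProperties": {
            "type": "integer"
          },
          "title": "Soa By Group",
          "type": "object"
        },
        "dual_target_fraction": {
          "default": 0.75,
          "exclusiveMinimum": 0.0,
          "maximum": 1.0,
          "title": "Dual Target Fraction",
          "type": "number"
        },
        "trials_per_toa": {
          "default": 40,
          "minimum": 1,
          "title": "Trials Per Toa",
          "type": "integer"
        },
        "target_pool": {
          "items": {
            "type": "string"
          },
          "title": "Target Pool",
          "type": "array"
        },
        "distractor_pool": {
          "items": {
            "type": "string"
          },
          "title": "Distractor Pool",
          "type": "array"
        }
      },
      "required": [
        "toas_ms",
        "soa_by_group"
      ],
      "title": "ProtocolSpec",
      "type": "object"
    },
    "SwapSpec": {
      "additionalProperties": false,
      "description": "Decay-law parameters of the generative swap-probability curve.",
      "properties": {
        "kind": {
          "enum": [
            "ldf",
            "edf"
          ],
          "title": "Kind",
          "type": "string"
        },
        "decay_rate": {
          "exclusiveMinimum": 0,
          "title": "Decay Rate",
          "type": "number"
        },
        "baseline": {
          "exclusiveMaximum": 1,
          "minimum": 0,
          "title": "Baseline",
          "type": "number"
        },
        "noise_halfwidth": {
          "default": 0.02,
          "minimum": 0,
          "title": "Noise Halfwidth",
          "type": "number"
        }
      },
      "required": [
        "kind",
        "decay_rate",
        "baseline"
      ],
      "title": "SwapSpec",
      "type": "object"
    }
  },
  "additionalProperties": false,
  "properties": {
    "preset": {
      "anyOf": [
        {
          "enum": [
            "exp1",
            "exp2"
          ],
          "type": "string"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Preset"
    },
    "protocol": {
      "anyOf": [
        {
          "$ref": "#/$defs/ProtocolSpec"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    },
    "groups": {
      "anyOf": [
        {
          "additionalProperties": {
            "$ref": "#/$defs/GroupSpec"
          },
          "type": "object"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Groups"
    },
    "n_per_group": {
      "anyOf": [
        {
          "minimum": 1,
          "type": "integer"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "N Per Group"
    },
    "analysis": {
      "$ref": "#/$defs/AnalysisFlags"
    },
    "seed": {
      "anyOf": [
        {
          "type": "integer"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Seed"
    }
  },
  "title": "StudyConfig",
  "type": "object"
}
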