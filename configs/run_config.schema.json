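{
  "$defs": {
    "SamplerSettings": {
      "additionalProperties": false,
      "properties": {
        "chains": {
          "default": 4,
          "title": "Chains",
          "type": "integer"
        },
        "iters": {
          "default": 2500,
          "title": "Iters",
          "type": "integer"
        },
        "warmup": {
          "default": 1000,
          "title": "Warmup",
          "type": "integer"
        }
      },
      "title": "SamplerSettings",
      "type": "object"
    },
    "SelectionSettings": {
      "additionalProperties": false,
      "properties": {
        "enabled": {
          "default": true,
          "title": "Enabled",
          "type": "boolean"
        },
        "candidates": {
          "anyOf": [
            {
              "items": {
                "maxItems": 2,
                "minItems": 2,
                "prefixItems": [
                  {
                    "type": "string"
                  },
                  {
                    "type": "string"
                  }
                ],
                "type": "array"
              },
              "type": "array"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Candidates"
        },
        "chains": {
          "default": 2,
          "title": "Chains",
          "type": "integer"
        },
        "iters": {
          "default": 1200,
          "title": "Iters",
          "type": "integer"
        },
        "warmup": {
          "default": 400,
          "title": "Warmup",
          "type": "integer"
        },
        "check_convergence": {
          "default": true,
          "title": "Check Convergence",
          "type": "boolean"
        }
      },
      "title": "SelectionSettings",
      "type": "object"
    },
    "SimulationConfig": {
      "additionalProperties": false,
      "description": "Full specification of a synthetic cohort (validated).",
      "properties": {
        "n_per_regimen": {
          "additionalProperties": {
            "type": "integer"
          },
          "title": "N Per Regimen",
          "type": "object"
        },
        "prob_female": {
          "default": 0.599,
          "title": "Prob Female",
          "type": "number"
        },
        "age_group_probs": {
          "additionalProperties": {
            "maxItems": 4,
            "minItems": 4,
            "prefixItems": [
              {
                "type": "number"
              },
              {
                "type": "number"
              },
              {
                "type": "number"
              },
              {
                "type": "number"
              }
            ],
            "type": "array"
          },
          "title": "Age Group Probs",
          "type": "object"
        },
        "cd4_group_probs": {
          "additionalProperties": {
            "maxItems": 3,
            "minItems": 3,
            "prefixItems": [
              {
                "type": "number"
              },
              {
                "type": "number"
              },
              {
                "type": "number"
              }
            ],
            "type": "array"
          },
          "title": "Cd4 Group Probs",
          "type": "object"
        },
        "true_beta": {
          "additionalProperties": {
            "type": "number"
          },
          "title": "True Beta",
          "type": "object"
        },
        "sigma_u": {
          "default": 1.0,
          "title": "Sigma U",
          "type": "number"
        },
        "attendance_prob": {
          "additionalProperties": {
            "additionalProperties": {
              "type": "number"
            },
            "type": "object"
          },
          "title": "Attendance Prob",
          "type": "object"
        },
        "jitter_sd": {
          "default": 7.0,
          "title": "Jitter Sd",
          "type": "number"
        },
        "out_of_window_prob": {
          "default": 0.05,
          "title": "Out Of Window Prob",
          "type": "number"
        },
        "suppressed_vl_range": {
          "default": [
            0,
            49
          ],
          "maxItems": 2,
          "minItems": 2,
          "prefixItems": [
            {
              "type": "number"
            },
            {
              "type": "number"
            }
          ],
          "title": "Suppressed Vl Range",
          "type": "array"
        },
        "unsuppressed_vl_range": {
          "default": [
            200,
            100000
          ],
          "maxItems": 2,
          "minItems": 2,
          "prefixItems": [
            {
              "type": "number"
            },
            {
              "type": "number"
            }
          ],
          "title": "Unsuppressed Vl Range",
          "type": "array"
        },
        "censor_week": {
          "additionalProperties": {
            "type": "integer"
          },
          "title": "Censor Week",
          "type": "object"
        },
        "ltfu_prob": {
          "default": 0.0,
          "title": "Ltfu Prob",
          "type": "number"
        },
        "death_prob": {
          "default": 0.0,
          "title": "Death Prob",
          "type": "number"
        },
        "seed": {
          "default": 0,
          "title": "Seed",
          "type": "integer"
        }
      },
      "title": "SimulationConfig",
      "type": "object"
    }
  },
  "additionalProperties": false,
  "description": "Schema-validated pipeline configuration (unknown keys rejected).",
  "properties": {
    "simulation": {
      "anyOf": [
        {
          "$ref": "#/$defs/SimulationConfig"
        },
        {
          "type": "null"
        }
      ]
    },
    "persons_csv": {
      "anyOf": [
        {
          "type": "string"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Persons Csv"
    },
    "viral_loads_csv": {
      "anyOf": [
        {
          "type": "string"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Viral Loads Csv"
    },
    "weeks": {
      "default": [
        12,
        24,
        48,
        72,
        96
      ],
      "items": {
        "type": "integer"
      },
      "title": "Weeks",
      "type": "array"
    },
    "half_width_days": {
      "default": 28,
      "title": "Half Width Days",
      "type": "integer"
    },
    "coef_prior_scale": {
      "default": 2.5,
      "title": "Coef Prior Scale",
      "type": "number"
    },
    "re_sd_prior": {
      "default": 1.0,
      "title": "Re Sd Prior",
      "type": "number"
    },
    "sampler": {
      "$ref": "#/$defs/SamplerSettings"
    },
    "selection": {
      "$ref": "#/$defs/SelectionSettings"
    },
    "complete_case": {
      "default": false,
      "title": "Complete Case",
      "type": "boolean"
    },
    "figures": {
      "default": true,
      "title": "Figures",
      "type": "boolean"
    },
    "out_dir": {
      "default": "vlsupp_run",
      "title": "Out Dir",
      "type": "string"
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
  "title": "RunConfig",
  "type": "object"
}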