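{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://w3id.org/fedqi/schema/generator-config",
  "title": "Synthetic cohort generator configuration",
  "type": "object",
  "required": ["center_id", "n_patients", "seed"],
  "additionalProperties": false,
  "properties": {
    "center_id": {"type": "string"},
    "n_patients": {"type": "integer", "minimum": 0},
    "seed": {"type": "integer"},
    "rectum_fraction": {"$ref": "#/$defs/probability"},
    "referred_fraction": {"$ref": "#/$defs/probability"},
    "neoadjuvant_fraction": {"$ref": "#/$defs/probability"},
    "complication_prob": {"$ref": "#/$defs/probability"},
    "short_wait_fraction": {
      "oneOf": [{"$ref": "#/$defs/probability"}, {"type": "null"}]
    },
    "waiting_time_days": {"$ref": "#/$defs/distribution"},
    "quota_counts": {
      "description": "Exact-marginal mode: localization -> [denominator, numerator]. Colon numerator = short-wait count, rectum numerator = complication count. Denominator sums must not exceed n_patients; surplus records are generated as referred.",
      "oneOf": [
        {
          "type": "object",
          "additionalProperties": false,
          "properties": {
            "colon": {"$ref": "#/$defs/quota_pair"},
            "rectum": {"$ref": "#/$defs/quota_pair"}
          }
        },
        {"type": "null"}
      ]
    },
    "age": {"$ref": "#/$defs/distribution"},
    "bmi": {"$ref": "#/$defs/distribution"},
    "charlson": {"$ref": "#/$defs/distribution"},
    "asa": {"$ref": "#/$defs/distribution"},
    "preop_complication": {"$ref": "#/$defs/distribution"}
  },
  "$defs": {
    "probability": {"type": "number", "minimum": 0, "maximum": 1},
    "quota_pair": {
      "type": "array",
      "prefixItems": [
        {"type": "integer", "minimum": 0},
        {"type": "integer", "minimum": 0}
      ],
      "minItems": 2,
      "maxItems": 2
    },
    "distribution": {
      "type": "object",
      "required": ["name"],
      "properties": {
        "name": {
          "enum": ["normal", "lognormal", "poisson", "uniform_int", "categorical", "bernoulli", "constant"]
        }
      }
    }
  }
}
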