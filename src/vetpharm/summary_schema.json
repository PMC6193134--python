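{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "vetpharm pipeline summary",
  "type": "object",
  "required": ["dataset", "mapping", "rates", "diversity", "network", "stats"],
  "properties": {
    "dataset": {"type": "object"},
    "mapping": {
      "type": "object",
      "required": [
        "n_unique_descriptions",
        "n_excluded",
        "n_matched",
        "n_unmatched",
        "n_rules_used"
      ]
    },
    "rates": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "required": ["prescription_frequency", "ci_low", "ci_high"],
        "properties": {
          "prescription_frequency": {"type": "number", "minimum": 0, "maximum": 1},
          "ci_low": {"type": "number"},
          "ci_high": {"type": "number"},
          "cluster_level": {"type": "string"},
          "authorisation": {"type": "object"},
          "rate_per_10k": {
            "type": "object",
            "additionalProperties": {"type": "number", "minimum": 0, "maximum": 10000}
          }
        }
      }
    },
    "diversity": {"type": "object"},
    "network": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "required": ["coprescription_rate", "n_nodes", "n_edges", "n_groups", "groups"]
      }
    },
    "stats": {
      "type": "object",
      "required": ["wilcoxon", "kendall"]
    }
  }
}
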