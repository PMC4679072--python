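{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "batchaudit diagnose report",
  "type": "object",
  "required": ["version", "results"],
  "properties": {
    "version": {"type": "string"},
    "seed": {"type": ["integer", "null"]},
    "results": {
      "type": "object",
      "required": ["batches", "groups", "counts", "n", "pairs", "proportional", "connected"],
      "properties": {
        "batches": {"type": "array", "items": {"type": "string"}},
        "groups": {"type": "array", "items": {"type": "string"}},
        "counts": {
          "type": "array",
          "items": {"type": "array", "items": {"type": "integer", "minimum": 0}}
        },
        "n": {"type": "integer", "minimum": 1},
        "proportional": {"type": "boolean"},
        "connected": {"type": "boolean"},
        "max_ratio": {"type": ["number", "string"]},
        "pairs": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["group_a", "group_b", "nu_per_batch", "nu", "nu0", "ratio"],
            "properties": {
              "group_a": {"type": "string"},
              "group_b": {"type": "string"},
              "nu_per_batch": {"type": "array", "items": {"type": "number"}},
              "nu": {"type": "number", "minimum": 0},
              "nu0": {"type": "number", "minimum": 0},
              "ratio": {"type": ["number", "string"]},
              "n_a": {"type": "integer"},
              "n_b": {"type": "integer"}
            }
          }
        },
        "null_f": {
          "type": "object",
          "required": ["lambdas", "q_tilde", "sigma_tilde_sq", "df_denom", "df_correction", "inflation"],
          "properties": {
            "lambdas": {"type": "array", "items": {"type": "number", "minimum": 0}},
            "q_tilde": {"type": "number", "exclusiveMinimum": 0},
            "sigma_tilde_sq": {"type": "number", "exclusiveMinimum": 0},
            "df_denom": {"type": "integer", "minimum": 1},
            "df_correction": {"type": "number", "minimum": 1},
            "inflation": {"type": "number", "minimum": 1}
          }
        }
      }
    }
  }
}
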