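{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "sgrecover run manifest",
  "type": "object",
  "required": [
    "version", "seed", "config", "checksums", "peak_cascade",
    "methylation", "pools", "recovery", "lengths", "abundance", "pars"
  ],
  "properties": {
    "version": {"type": "string"},
    "seed": {"type": "integer"},
    "config": {"type": "object"},
    "checksums": {
      "type": "object",
      "additionalProperties": {"type": "string", "pattern": "^[0-9a-f]{64}$"}
    },
    "peak_cascade": {
      "type": "object",
      "required": [
        "transcripts", "windows_scored", "windows_retained",
        "windows_after_shared", "windows_drach"
      ],
      "additionalProperties": {"type": "integer", "minimum": 0},
      "description": "windows_scored >= windows_retained >= windows_after_shared >= windows_drach"
    },
    "methylation": {
      "type": "object",
      "required": ["n_methylated", "n_non_methylated", "sensitivity", "specificity"]
    },
    "pools": {"type": "object", "additionalProperties": {"type": "integer"}},
    "recovery": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["group", "condition", "n_sg", "n_recovered", "fraction", "pct_rounded"]
      }
    },
    "lengths": {"type": "object"},
    "abundance": {
      "type": "object",
      "required": ["p_value", "median_rpkm_methylated", "median_rpkm_non_methylated"]
    },
    "pars": {
      "type": "object",
      "required": [
        "n_meth_sites", "n_ctrl_sites", "mean_meth_offset0",
        "mean_ctrl_offset0", "n_significant_offsets"
      ]
    }
  }
}
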