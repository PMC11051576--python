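{
  "title": "AgreementReport",
  "type": "object",
  "required": [
    "n",
    "icc",
    "icc_ci95",
    "icc_form",
    "r2",
    "bland_altman",
    "difference_convention"
  ],
  "properties": {
    "n": {"type": "integer"},
    "icc": {"type": "number"},
    "icc_ci95": {"type": "array", "minItems": 2},
    "icc_pvalue": {"type": "number"},
    "icc_form": {"type": "string"},
    "r2": {"type": "number"},
    "difference_convention": {"type": "string"},
    "bland_altman": {
      "type": "object",
      "required": [
        "mean_difference",
        "sd_difference",
        "loa_low",
        "loa_high",
        "proportional_bias_slope",
        "proportional_bias_p"
      ],
      "properties": {
        "mean_difference": {"type": "number"},
        "sd_difference": {"type": "number"},
        "loa_low": {"type": "number"},
        "loa_high": {"type": "number"},
        "proportional_bias_slope": {"type": "number"},
        "proportional_bias_p": {"type": "number"}
      }
    },
    "model": {"type": "object"}
  }
}
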