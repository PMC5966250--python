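{
  "abundance_median": 0.3,
  "abundance_sigma": 1.4,
  "dropout": {"kind": "exponential", "p0": 0.8, "tau": 9.0},
  "lt_depth_factor": 1.4,
  "target_fractions": {"pt_only": 0.196, "lt_only": 0.296, "shared": 0.508}
}
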