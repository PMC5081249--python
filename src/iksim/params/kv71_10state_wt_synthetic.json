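{
  "schema_version": 1,
  "scheme": "kv71_10state",
  "description": "Synthetic calibrated wild-type parameter set for the 10-state allosteric KV7.1 scheme. Not a transcription of any published rate table: rates were fitted to reproduce the published wild-type behavior (F(V) and G(V) close in voltage dependence with midpoints near -25 mV, activation complete within a 3 s test pulse) and the documented curve responses to S4-movement and opening-transition voltage shifts.",
  "rates": {
    "s4_forward": {"k0": 0.02995, "z": 0.85},
    "s4_backward": {"k0": 0.004, "z": -0.75},
    "opening": {"k0": 5.93e-08, "z": 0.65},
    "closing": {"k0": 0.002, "z": -0.65}
  },
  "allosteric_factor": 30.0,
  "allosteric_split": 1.0,
  "f1": 1.0,
  "f2": 2.2,
  "temperature_K": 295.0,
  "gmax_uS": 20.0,
  "e_rev_mV": -95.0
}
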