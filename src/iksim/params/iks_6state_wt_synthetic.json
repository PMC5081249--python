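{
  "schema_version": 1,
  "scheme": "iks_6state",
  "description": "Synthetic calibrated wild-type parameter set for the 6-state KV7.1+KCNE1 scheme. Not a transcription of any published rate table: rates were fitted to reproduce the published wild-type behavior (main F(V) component near -100 mV well separated from a G(V) near +25 mV with slope factor ~15-20 mV, slow sigmoidal activation at +40 mV, ~1 s deactivation at -20 mV) and the documented curve responses to S4-movement and opening-transition voltage shifts.",
  "rates": {
    "s4_forward": {"k0": 0.14, "z": 0.3},
    "s4_backward": {"k0": 0.02, "z": -0.25},
    "opening": {"k0": 0.000274, "z": 0.6},
    "closing": {"k0": 0.000646, "z": -0.6}
  },
  "f1": 1.0,
  "f2": 1.6,
  "temperature_K": 295.0,
  "gmax_uS": 40.0,
  "e_rev_mV": -95.0
}
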