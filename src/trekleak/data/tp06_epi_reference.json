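{
  "base_model_id": "tp06-epi",
  "pacing": {
    "cycle_length_ms": 1000.0,
    "n_beats": 50,
    "stim_amplitude": -52.0,
    "stim_duration_ms": 1.0
  },
  "dt_ms": 0.01,
  "record_dt_ms": 0.01,
  "biomarkers": {
    "rmp_mV": -85.5938000843791,
    "dvdt_max_mV_per_ms": 394.2091761551982,
    "apd50_ms": 279.373449213907,
    "apd90_ms": 308.2315145770462
  }
}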