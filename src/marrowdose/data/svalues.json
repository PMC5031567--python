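{
  "provenance": "synthetic-plausible defaults for 177Lu constructed from beta/photon energy-per-decay magnitudes; NOT a dosimetric reference table. Replace with an authoritative (e.g. RADAR-derived) table for clinical use.",
  "units": "mGy per MBq*h",
  "s_bm_bm": 0.0726,
  "reference_marrow_mass_kg": 1.17,
  "organs_to_marrow": {
    "liver":   {"s": 1.5e-4, "mass_kg": 1.8},
    "spleen":  {"s": 1.3e-4, "mass_kg": 0.15},
    "kidneys": {"s": 2.0e-4, "mass_kg": 0.31}
  },
  "low_sources_to_marrow": {
    "muscle": 1.0e-4,
    "bone":   1.4e-4
  }
}
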