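{
 "description": "synthetic 12-mode bundle with one planted type-I Fermi resonance and one planted 1-1 Darling-Dennison resonance",
 "generator": {
  "n_modes": 12,
  "seed": 2024
 },
 "planted_features": [
  {
   "kind": "FERMI_I",
   "modes": [
    12,
    9,
    9
   ],
   "delta_cm-1": 2.6,
   "coupling_cm-1": 38.0
  },
  {
   "kind": "DD11",
   "modes": [
    5,
    6
   ],
   "delta_cm-1": 4.0,
   "coupling_cm-1": 25.0
  }
 ]
}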