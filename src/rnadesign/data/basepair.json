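{
 "model": "basepair",
 "params": {
  "AU": -2.0,
  "CG": -3.0,
  "GC": -3.0,
  "GU": -1.0,
  "UA": -2.0,
  "UG": -1.0
 }
}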