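{
 "model": "stacking",
 "params": {
  "AAUU": -0.5,
  "ACGU": -1.25,
  "AGCU": -1.25,
  "AGUU": -0.3,
  "AUAU": -0.5,
  "AUGU": -0.3,
  "CAUG": -1.25,
  "CCGG": -2.0,
  "CGCG": -2.0,
  "CGUG": -1.05,
  "CUAG": -1.25,
  "CUGG": -1.05,
  "GAUC": -1.25,
  "GAUU": -0.3,
  "GCGC": -2.0,
  "GCGU": -1.05,
  "GGCC": -2.0,
  "GGCU": -1.05,
  "GGUC": -1.05,
  "GGUU": -0.1,
  "GUAC": -1.25,
  "GUAU": -0.3,
  "GUGC": -1.05,
  "GUGU": -0.1,
  "UAUA": -0.5,
  "UAUG": -0.3,
  "UCGA": -1.25,
  "UCGG": -1.05,
  "UGCA": -1.25,
  "UGCG": -1.05,
  "UGUA": -0.3,
  "UGUG": -0.1,
  "UUAA": -0.5,
  "UUAG": -0.3,
  "UUGA": -0.3,
  "UUGG": -0.1
 }
}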