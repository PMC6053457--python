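{
  "comment": "Printed screening statistics accompanying the 12-run design; the published analysis used unrounded activities, so values recomputed from the 3-decimal responses differ in the 3rd-4th decimal.",
  "v_eff": 0.001494,
  "se": 0.038652,
  "effect": {
    "yeast_extract": 0.6368, "malt_extract": 0.0393, "dextrose": 0.1918,
    "calcium_carbonate": -0.0377, "starch": -0.1411,
    "ammonium_carbonate": 0.0539, "sodium_carbonate": -0.0248
  },
  "t": {
    "yeast_extract": 16.4770, "malt_extract": 1.0185, "dextrose": 4.9631,
    "calcium_carbonate": -0.9762, "starch": -3.6513,
    "ammonium_carbonate": 1.3954, "sodium_carbonate": -0.6416
  },
  "p": {
    "yeast_extract": 0.00001, "malt_extract": 0.166247, "dextrose": 0.000284,
    "calcium_carbonate": 0.17599, "starch": 0.00222,
    "ammonium_carbonate": 0.09655, "sodium_carbonate": 0.26777
  }
}
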