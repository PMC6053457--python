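{
  "comment": "Published regression coefficients of the quadratic response-surface model, natural units (g/100 ml -> U/ml). The companion equation prints intercept +0.1801 and x4^2 -302.3011; the coefficient table's -0.1801 and -302.3017 are used because they reproduce the published center-point prediction 1.698545.",
  "names": ["yeast_extract", "dextrose", "starch", "ammonium_carbonate"],
  "units": "natural",
  "coef": [-0.1801,
           2.8746, 0.4696, 1.35105, -32.5579,
           0.4879, -0.112, 0.01418, -302.3017,
           -0.0125, -1.95938, 48.37499, -1.175, 65.4999, 16.0625],
  "se": [0.26183,
         0.50285, 0.43527, 0.21073, 8.95763,
         0.24010, 0.17871, 0.04532, 74.69575,
         0.53368, 0.18269, 10.43085, 0.19853, 11.06510, 3.96512]
}
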