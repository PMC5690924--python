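{
  "description": "RTOG 0915 spillage compliance bands for peripheral lung SBRT. The band (lower, upper) is the minor-deviation interval: value <= lower is per protocol, lower < value <= upper is a minor deviation, value > upper is a major deviation. R50% and D2cm bands depend on PTV volume; anchors are monotone piecewise-linear bound functions through the published per-patient (PTV volume, band) pairs, with duplicate volumes merged by averaging. Values outside the anchor range clamp to the end anchors.",
  "r100_band": [1.2, 1.5],
  "v20_band_pct": [10.0, 15.0],
  "r50_anchors": [
    [11.1, 5.0, 5.9],
    [12.9, 4.7, 5.8],
    [15.0, 4.7, 5.7],
    [20.1, 4.6, 5.7],
    [21.0, 4.5, 5.5],
    [26.3, 4.4, 5.4],
    [27.1, 4.5, 5.4],
    [31.2, 4.3, 5.3],
    [36.2, 4.3, 5.3],
    [37.1, 4.2, 5.2],
    [39.7, 4.2, 5.2],
    [39.8, 4.2, 5.2],
    [50.9, 4.0, 5.0],
    [53.4, 3.9, 5.0],
    [56.5, 3.8, 4.9],
    [61.5, 3.7, 4.9],
    [68.1, 3.6, 4.8],
    [132.0, 3.1, 3.9],
    [163.0, 2.9, 3.7]
  ],
  "d2cm_anchors": [
    [11.1, 50.0, 58.0],
    [12.9, 50.0, 58.0],
    [15.0, 50.9, 59.1],
    [20.1, 53.05, 61.9],
    [21.0, 53.6, 62.4],
    [26.3, 55.3, 64.7],
    [27.1, 55.7, 65.0],
    [31.2, 57.0, 66.8],
    [36.2, 58.5, 69.1],
    [37.1, 58.8, 69.7],
    [39.7, 59.3, 70.8],
    [39.8, 59.3, 70.8],
    [50.9, 62.2, 77.5],
    [53.4, 62.6, 78.4],
    [56.5, 63.4, 80.2],
    [61.5, 64.4, 82.4],
    [68.1, 65.6, 85.1],
    [132.0, 73.7, 91.5],
    [163.0, 77.0, 94.0]
  ],
  "oar_limits_gy": {
    "cord_d035cc_gy": 20.8,
    "esophagus_d5cc_gy": 18.8,
    "heart_d15cc_gy": 28.0,
    "lung_d1000cc_gy": 12.8
  }
}
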