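{
  "n": 12,
  "measures": {
    "r2c_r2_ratio": {"mean": 0.815, "sd": 0.093, "delta_mean": 0.170, "delta_sd": 0.107},
    "r2_area": {"mean": 4707.1, "sd": 2864.3, "delta_mean": 546.8, "delta_sd": 616.7},
    "r1_amp": {"mean": 165.1, "sd": 79.1, "delta_mean": 31.8, "delta_sd": 29.7},
    "sbr_area": {"mean": 1716.0, "sd": 1061.1, "delta_mean": 424.8, "delta_sd": 410.5},
    "brer_index": {"mean": 92.4, "sd": 33.7, "delta_mean": 13.2, "delta_sd": 7.2},
    "brip": {"mean": 94.1, "sd": 4.7, "delta_mean": 3.4, "delta_sd": 3.0}
  },
  "brer_anchors": {
    "recovery_300ms": {"mean": 4.4, "sd": 5.8},
    "recovery_600ms": {"mean": 48.1, "sd": 20.1}
  }
}
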