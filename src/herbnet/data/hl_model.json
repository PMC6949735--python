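{
  "intercept": 13.310,
  "coef": {
    "nArCO": 13.376,
    "H7m": 7.092,
    "DDr09": 0.053,
    "N070": 19.377,
    "C032": -7.598,
    "JGI6": -347.423,
    "nRCeqN": 32.752,
    "Mor02e": -0.100
  },
  "metadata": {
    "r2": 0.65,
    "q2": 0.62,
    "f_stat": 27.272,
    "see": 8.127,
    "n_training": 126,
    "n_test": 43
  }
}
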