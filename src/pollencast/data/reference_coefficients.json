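{
  "alnus": {
    "beta0": -3.588,
    "beta_day": 0.066,
    "beta_t": 0.185,
    "statistic": "max",
    "source": "reference fit, Krakow 1991-2010 monitoring series"
  },
  "corylus": {
    "beta0": -4.155,
    "beta_day": 0.074,
    "beta_t": 0.215,
    "statistic": "max",
    "source": "reference fit, Krakow 1991-2010 monitoring series"
  },
  "betula": {
    "beta0": -25.413,
    "beta_day": 0.274,
    "beta_t": 0.352,
    "statistic": "mean",
    "source": "reference fit, Krakow 1991-2010 monitoring series"
  }
}
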