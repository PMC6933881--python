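{
  "note": "Published four-predictor path decomposition of maize breakage rate. X1 = grain specific surface area, X2 = subcutaneous cavity volume, X3 = sphericity, X4 = density. IPC[i][j] is the indirect effect of Xi routed through Xj.",
  "predictors": ["X1", "X2", "X3", "X4"],
  "labels": {
    "X1": "grain specific surface area",
    "X2": "subcutaneous cavity volume",
    "X3": "sphericity",
    "X4": "density"
  },
  "direct": {"X1": -0.0765, "X2": 0.3016, "X3": 0.1275, "X4": -1.0135},
  "indirect": {
    "X1": {"X2": -0.0651, "X3": -0.1051, "X4": 0.6775},
    "X2": {"X1": 0.0165, "X3": -0.0075, "X4": 0.278},
    "X3": {"X1": 0.063, "X2": -0.0178, "X4": -0.8866},
    "X4": {"X1": 0.0511, "X2": -0.0827, "X3": 0.1115}
  }
}
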