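{
  "comment": "Default L1 regularization schedule r(feature class, n presences): piecewise-linear in the presence count, clamped at the ends. These are the published MaxEnt defaults for linear/quadratic/product features.",
  "linear": {"n_presences": [0, 10, 30, 100], "r": [1.0, 1.0, 0.2, 0.05]},
  "quadratic": {"n_presences": [0, 10, 17, 30, 100], "r": [1.3, 0.8, 0.5, 0.25, 0.05]},
  "product": {"n_presences": [0, 10, 17, 30, 100], "r": [2.6, 1.6, 1.1, 0.55, 0.05]}
}
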