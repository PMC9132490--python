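{
  "B": 1.0, "alpha": 0.2, "m": 0.3, "beta": 0.6, "epsilon": 0.2,
  "gamma1": 0.5, "gamma2": 0.7, "mu": 0.3, "lam": 0.4
}
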