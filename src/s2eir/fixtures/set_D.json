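{
  "B": 5.0, "alpha": 0.8, "m": 0.1, "beta": 0.06, "epsilon": 0.2,
  "gamma1": 0.5, "gamma2": 0.7, "mu": 0.2, "lam": 0.2,
  "m_as_control": true
}
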