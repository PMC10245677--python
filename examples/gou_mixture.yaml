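# Gamma-OU driver in the mixture-like regime (x = 1/18, y = 5/7).
family: gou
params:
  kappa: 0.1
  a: 0.4
  theta: 1.0
  beta: 0.8
  gamma: 0.9
grid: [50, 51]
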