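# Transient bursty model observed through a plug-flow reactor snapshot.
transient:
  b: [2.0, 5.0, 1.0]      # stage burst means
  tau: [1.0, 3.0]         # stage-change times
  alpha: 0.8              # burst frequency (1/time)
  beta: 1.2               # splicing rate (1/time)
  gamma: 3.14             # degradation rate (1/time)
  reactor: dirac_pfr
  T: 5.0                  # mean residence time
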