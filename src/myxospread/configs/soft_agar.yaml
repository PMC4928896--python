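# Soft-agar (0.5%) parameter set: EPS-gated expansion with diffusing nutrients.
units:
  rate: per_hour
  length: um
parameters:
  D0: 2.0
  Dp: 220.0
  DN: 10000.0
  m: 4.0
  e0: 1.0
  alpha: 19.0
  beta: 16.0
  gmax: 0.173
  N0: 0.1
  Nin: 3.0
  c0: 0.003
  rho_edge: 1.0
  r0: 1700.0
  rb: 31700.0
  vg: 7.0
  f: 0.1
solver:
  dx: 30.0
  dt: 0.05
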