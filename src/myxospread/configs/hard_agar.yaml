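# Hard-agar (1.5%) parameter set for A-S+ strains: slower growth, low Dp,
# high EPS production.
units:
  rate: per_hour
  length: um
parameters:
  D0: 2.0
  Dp: 16.0
  DN: 10000.0
  m: 4.0
  e0: 1.0
  alpha: 150.0
  beta: 16.0
  gmax: 0.154
  N0: 0.1
  Nin: 3.0
  c0: 0.003
  rho_edge: 1.0
  r0: 1700.0
  rb: 31700.0
solver:
  dx: 30.0
  dt: 0.05
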