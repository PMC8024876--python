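# stochastic live/dead time-lapse counts
kind: population
population:
  kb: 0.05
  kd: 0.02
  delta: 0.10
  X0: 100
  Y0: 5
  t_end: 90.0
  dt: 1.0
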