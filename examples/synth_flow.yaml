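# synthetic two-channel flow-cytometry time course
kind: flow
flow:
  lambda_: 0.02          # activation rate (1/h)
  sample_times: [10.0, 30.0, 50.0, 70.0, 90.0]
  n_per_time: 2000
  start_fraction2: 0.0
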