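# blocking-TF dose response
tf_params:
  N_B: 2
  mechanism: blocking
tf_grid: [0.0, 0.25, 0.5, 1.0, 2.0, 4.0]
n_runs: 100
t_max: 3000.0
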