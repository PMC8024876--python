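# in-silico demethylase inhibition on the MC model
model: mc
kind: dose
target: alpha
multipliers: [0.5, 1.0, 2.0]
n_runs: 150
t_max: 8000.0
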