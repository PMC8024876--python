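# methylation-compaction switch at the documented defaults
model: mc
n_runs: 200
t_max: 4000.0
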