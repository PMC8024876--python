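# mixture-deconvolve a flow CSV and fit the first-order activation rate
events_csv: data/flow_events.csv
bin_width_h: 20.0
early_window_h: 20.0
plateau: fixed_1
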