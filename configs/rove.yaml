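# Roving-masker-level paradigm: 200 ms masker, 2 ms ramps, at 70 dB SPL fixed
# or drawn per interval from a Gaussian (SD 6 dB, truncated at +/-3 SD);
# 10 ms probe, 5 ms ramps, at 4 kHz; masker at 4 kHz (on-frequency) or
# 2.4 kHz (off-frequency); delays 0 and 30 ms; fixed psychophysical window
# 150-300 ms; 70.7% criterion.
experiment:
  name: rove
  masker_duration: 0.200
  masker_ramp: 0.002
  probe_duration: 0.010
  probe_ramp: 0.005
  delays: [0.0, 0.03]
  masker_frequencies: [4000.0, 2400.0]
  probe_frequency: 4000.0
  masker_mean_level: 70.0
  rove_sd: 6.0
  rove_truncation_sd: 3.0
  criterion: 0.707
  window: psychophysical
  n_trials: 100
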