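# Growth-of-masking paradigm (stimulus parameters per the GOM column of the
# stimulus table): 100 ms masker, 2 ms ramps; 25 ms probe, 2 ms ramps;
# masker-probe delay 2.83 ms; masker and probe at 4 kHz; masker level stepped
# in dB re the model's masker-in-quiet threshold; 61% criterion.
experiment:
  name: gom
  masker_duration: 0.100
  masker_ramp: 0.002
  probe_duration: 0.025
  probe_ramp: 0.002
  delay: 0.00283
  masker_frequency: 4000.0
  probe_frequency: 4000.0
  masker_sls: [10, 20, 30, 40, 50, 60, 70, 80]
  criterion: 0.61
  window: physiological
  n_trials: 100
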