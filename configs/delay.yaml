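# Masker-probe delay paradigm: 200 ms masker, 10 ms ramps; 20 ms probe,
# 10 ms ramps; delays 0-150 ms; masker at 40 dB re the model neuron's unmasked
# threshold; 4 kHz; 70.7% criterion; physiological decision window.
experiment:
  name: delay
  masker_duration: 0.200
  masker_ramp: 0.010
  probe_duration: 0.020
  probe_ramp: 0.010
  delays: [0.0, 0.01, 0.025, 0.05, 0.075, 0.1, 0.15]
  masker_frequency: 4000.0
  probe_frequency: 4000.0
  masker_sl: 40.0
  criterion: 0.707
  window: physiological
  n_trials: 100
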