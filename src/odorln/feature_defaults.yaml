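# Default feature-derivation parameters per signal stage.
# delta_*: forward-difference intervals (seconds);
# cutoff_*: zero-phase low-pass -3 dB frequencies (Hz).
odor:
  delta_roc: 0.050
  delta_acc: 0.100
  cutoff_amp: 20.0
  cutoff_roc: 10.0
osn:
  delta_roc: 0.100
  delta_acc: 0.100
  cutoff_amp: 4.0
  cutoff_roc: 4.0
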