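kappa_mean: 0.05312034667723746
g1_loss_rate: 0.01
ts: 20
tg2_mean: 3
tm: 1
death_s: 0.001
death_g2: 0.001
death_m: 0.001
kappa_mod_amp: 0.3561118000830435
kappa_mod_phase: 6.704627959017571
g2_mod_amp: 0.05
g2_mod_phase: 21
label: tumor_slow
_meta:
  calibration:
    target:
      frac_min: 0.42
      frac_max: 0.47
      peak_time: 17.0
    achieved:
      min: 0.42
      max: 0.47
      peak_time: 17.00001
    procedure: bounded Nelder-Mead on (kappa_mean, kappa_mod_amp, kappa_mod_phase)
      vs untreated daily S-fraction stats; see docs/methods.md
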