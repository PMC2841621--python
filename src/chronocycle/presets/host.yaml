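kappa_mean: 0.04605090788702249
g1_loss_rate: 0.01
ts: 9
tg2_mean: 3
tm: 1
death_s: 0.001
death_g2: 0.001
death_m: 0.001
kappa_mod_amp: 0.2431065814703759
kappa_mod_phase: 9.260458998499923
g2_mod_amp: 0.1
g2_mod_phase: 21
label: host
_meta:
  calibration:
    target:
      frac_min: 0.2
      frac_max: 0.3
      peak_time: 12.0
    achieved:
      min: 0.2
      max: 0.3
      peak_time: 11.9999
    procedure: bounded Nelder-Mead on (kappa_mean, kappa_mod_amp, kappa_mod_phase)
      vs untreated daily S-fraction stats; see docs/methods.md
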