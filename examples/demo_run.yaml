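# Two-condition synthetic demo: unassisted walking (c) vs. motorized
# walker with a medium speed cue (mm), parameters set to the published
# condition means.
seed: 11
alpha: 0.05
out_dir: demo_out
comparisons:
  - [c, mm]
scenarios:
  c:
    n_cycles_per_side: 10
    gct_left: 1.29
    gct_right: 1.204   # ~6.7% bilateral cycle-time asymmetry
    swing_fraction_left: 0.2724
    swing_fraction_right: 0.2724
    ids_fraction: 0.1875
    tds_fraction: 0.1688
    step_height_left: 21.2
    step_height_right: 21.2
    step_length_left: 93.0
    step_length_right: 93.0
    noise_sd: 0.1
  mm:
    n_cycles_per_side: 10
    gct_left: 1.40
    gct_right: 1.40
    swing_fraction_left: 0.269
    swing_fraction_right: 0.269
    ids_fraction: 0.1566
    tds_fraction: 0.1509
    step_height_left: 19.0
    step_height_right: 19.0
    step_length_left: 68.6
    step_length_right: 68.6
    noise_sd: 0.1
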