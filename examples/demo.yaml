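# Demo study: MGE-progenitor cycle kinetics under vehicle (DMSO) vs
# TGFbeta-receptor inhibition (LY), a pulse-chase exit contrast, and a
# two-condition reporter flow timecourse.  Identical to
# cyclekin.pipeline.demo_config().
seed: 20210020
output_dir: cyclekin_demo_out

cycle_study:
  times_h: [2, 4, 8, 16, 24]
  n_cells_per_field: 200
  n_fields: 6
  n_replicates: 2
  fit_policy: plateau_exclude
  conditions:
    dmso:
      populations:
        - {label: nkx2.1_pos, tc: 39.98, ts: 16.51, gf: 0.9, proportion: 0.65}
        - {label: nkx2.1_neg, tc: 38.80, ts: 16.60, gf: 0.8, proportion: 0.35}
    ly:
      populations:
        - {label: nkx2.1_pos, tc: 45.65, ts: 21.76, gf: 0.9, proportion: 0.65}
        - {label: nkx2.1_neg, tc: 40.26, ts: 16.11, gf: 0.8, proportion: 0.35}
  compare:
    - [dmso, ly, nkx2.1_pos]
    - [dmso, ly, nkx2.1_neg]

pulse_chase:
  pulse_h: 2
  chase_h: 48
  n_cells_per_field: 300
  n_fields: 6
  n_replicates: 2
  marker_positive: nkx2.1_pos
  conditions:
    control: {label: nkx2.1_pos, tc: 39.98, ts: 16.51, gf: 0.9, quit_prob: 0.25}
    tgfb3: {label: nkx2.1_pos, tc: 39.98, ts: 16.51, gf: 0.9, quit_prob: 0.45}

flow_study:
  days: [25, 30, 35, 40, 45, 50, 55, 60]
  n_events: 5000
  n_replicates: 3
  percentile: 99.9
  viability_multiple: 4.0
  simulate_controls: true
  conditions:
    control: {hazard: 0.079, onset_delay: 20.0, hazard_scale: 1.0}
    ly: {hazard: 0.079, onset_delay: 20.0, hazard_scale: 0.45}
  summary_day: 45
  summary_reference: control
  summary_treated: ly

stats:
  alpha: 0.05
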