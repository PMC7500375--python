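# Full pipeline configuration. Values mirror the experiment's constants:
# two groups, 10 repetitions per order-pair x condition cell, 1 kHz
# sampling with 15 Hz filtering (fixed in the extraction stage), and small
# measurement noise.  Scale n_per_group / n_reps_per_cell down for quick runs.
seed: 1
n_per_group: 4
n_reps_per_cell: 3
keep_traces: false
run_relations: true
dvs: [z_estimate, peak_LFR, peak_GFR, gf_static]
sim_params:
  fs: 1000.0
  memory_weight: 0.9
  lfr_gain: 8.0
  gf_lf_ratio: 1.4
  safety_margin: 1.0
  noise_sd_force: 0.05
  noise_sd_report: 0.15
  percept_prev_bias: 0.035
  tms_effects:
    d_pGFR_dynamic: 5.0
    d_pLFR_dynamic_LO_heavy: 5.0
    d_percept_static_heavy: -0.2
  artifact_probs:
    p_drop: 0.004
    p_multilift: 0.004
    p_tms_fail: 0.004
outdir: null
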