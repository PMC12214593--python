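# Example study configuration for `bretpharm simulate`.
bret:
  receptors: [b2AR, b2V2, V2b2, V2R]
  sensors: [F4, F5, F10]
  concentrations_uM: [0.001, 0.00316, 0.01, 0.0316, 0.1, 0.316, 1.0, 3.16, 10.0, 31.6]
  timepoints_min: [-3, -2, -1, 0, 1, 2, 2.5, 3, 3.5, 4, 5]
  noise: {sd_ratio: 0.002, replicate_count: 3}
  truths:
    # N-domain position F4: driven by the receptor C-terminus
    - {receptor: b2AR, sensor: F4, top: 0.05, log_ec50: -1.3, hill: 1.0, responder: true}
    - {receptor: b2V2, sensor: F4, top: 0.18, log_ec50: -1.0, hill: 1.1, responder: true}
    - {receptor: V2b2, sensor: F4, top: 0.05, log_ec50: -1.3, hill: 1.0, responder: true}
    - {receptor: V2R,  sensor: F4, top: 0.18, log_ec50: -1.0, hill: 1.1, responder: true}
    # N-domain position F5: responds for all variants
    - {receptor: b2AR, sensor: F5, top: 0.08, log_ec50: -1.3, hill: 1.0, responder: true}
    - {receptor: b2V2, sensor: F5, top: 0.15, log_ec50: -1.1, hill: 1.0, responder: true}
    - {receptor: V2b2, sensor: F5, top: 0.07, log_ec50: -1.2, hill: 0.9, responder: true}
    - {receptor: V2R,  sensor: F5, top: 0.20, log_ec50: -1.0, hill: 1.1, responder: true}
    # C-domain position F10: driven by the helix-bundle; flat for b2-bundle receptors
    - {receptor: b2AR, sensor: F10, top: 0.0, responder: false}
    - {receptor: b2V2, sensor: F10, top: 0.0, responder: false}
    - {receptor: V2b2, sensor: F10, top: 0.12, log_ec50: -1.1, hill: 1.0, responder: true}
    - {receptor: V2R,  sensor: F10, top: 0.12, log_ec50: -1.1, hill: 1.0, responder: true}
coloc:
  sd: 0.1
  replicate_count: 3
  samples:
    - {pair: arrestin-Rab5, receptor: b2AR, condition: Control, stim_state: stimulated, fold: 1.0}
    - {pair: arrestin-Rab5, receptor: b2V2, condition: Control, stim_state: stimulated, fold: 2.0}
    - {pair: arrestin-Rab5, receptor: V2b2, condition: Control, stim_state: stimulated, fold: 1.0}
    - {pair: arrestin-Rab5, receptor: V2R,  condition: Control, stim_state: stimulated, fold: 2.0}
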