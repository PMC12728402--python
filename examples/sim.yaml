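# labqc simulate --config sim.yaml --outdir data/
# Synthetic 5-lab network; seed is mandatory.
seed: 7
n_labs: 5
days: 90
points_per_day: 2
n_peer_groups: 2
lab_biases: [0.0, 0.5, -0.5, 0.0, 1.0]     # percent
lab_imprecision: [1.0, 1.0, 1.2, 1.0, 1.0] # SD multipliers
analytes:
  - name: potassium
    true_means: [4.0, 6.5]   # one per control level, mmol/L
    true_cv: 2.0             # percent
    cv_requirement: 3.0
    tea: 10.0
    unit: mmol/L
injections:
  - {lab: 2, analyte: potassium, level: 1, mode: shift, magnitude: 2.0, start_day: 45}
eqa:
  n_events: 6
  samples_per_event: 5
  assigned_from: consensus
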