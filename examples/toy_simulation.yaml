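# Simulation spec for `isrsa simulate` — a toy cohort that runs in seconds.
n_subjects: 30
n_nodes: 20
n_timepoints: 300
seed: 7
nodes:
  - {model: annak, coupling: 0.8, count: 5}
  - {model: nn, coupling: 0.8, count: 5}
  - {model: "null", count: 10}
age_range: [6, 22]
age_motion_corr: -0.35
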