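# Run config for `isrsa run` on the output of `isrsa simulate`.
# Paths are relative to where you invoke the CLI; adjust as needed.
timecourses: toy_data/timecourses
behavior: toy_data/behavior.tsv
output_dir: toy_results
models: [annak, nn]
alpha: 0.05
n_perm: 1000
seed: 1
qc:
  mean_fd: 0.15        # strict <, subjects at the threshold are excluded
  max_displacement: null  # only applied when a max_displacement column exists
split_half: true
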