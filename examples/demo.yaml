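# Small demonstration run: 12 subjects, two conditions, a 4-edge star
# effect on the medial-prefrontal hub, full NBS with threshold sweep.
seed: 42
out_dir: nbsfc_demo
n_subjects: 12
conditions: [self, stranger]
n_trials_per_condition: 16
tr: 2.0
isi_range: [2.0, 6.0]
n_runs: 1
baseline_corr: 0.1
# star: DMN.MPFC (node 0) to bilateral anterior insula (10, 11) and
# bilateral lateral prefrontal cortex (21, 22)
effect_edges: [[0, 10], [0, 11], [0, 21], [0, 22]]
condition_deltas: {self: 0.28}
between_subject_sd: 0.05
contrasts:
  - name: self_gt_stranger
    weights: {self: 1, stranger: -1}
height_p: 0.001
n_perms: 500
sweep_grid: [0.05, 0.01, 0.005, 0.001]
statistic_kind: intensity_abs
estimator: plus_one
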