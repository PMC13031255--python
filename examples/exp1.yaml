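# Speeded-listening cohort: 3 simulated participants, 125 trials each.
experiment: exp1
participants: 3
seed: 7
fs: 250.0
out_dir: runs/exp1
write_logs: true
crop: false
k_folds: 5
# the multiple-choice exclusion threshold must be stated explicitly
mc_accuracy_threshold: 0.5
movement_sd: 3.5
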