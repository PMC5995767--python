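{
 "seed": 1,
 "n_participants": 20,
 "phantom_shape": [12, 12, 12],
 "scan_end_s": 5400.0,
 "cohort_dir": "scratch/cohort",
 "results_dir": "results/analysis"
}
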