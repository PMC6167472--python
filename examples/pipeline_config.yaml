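# End-to-end demo: 80 synthetic patients, 15-minute window, models 2 and 5
n_patients: 80
nd_prevalence: 0.3
window_s: 900.0
models: [2, 5]
cv_folds: 10
cv_repeats: 10
seed: 20
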