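# Three simulated subjects, default phantom (14 parcels, selectivity ratio 3),
# default noise (AR(1) 0.3, block-level CNR ~ 1), odd-even cross-validation.
seed: 7
n_subjects: 3
parcels: default
split: odd-even
include_standard: true
out_dir: emfl_out
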