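n_train: 200
n_test: 200
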