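# cell-to-cell ribosome variability, small demonstration run
# (the full-scale screen uses n_samples: 10000)
circuit:
  type: repressilator
parameter: ribosomes
distribution: {kind: lognormal_cv, median: 5000.0, cv: 0.4}
n_samples: 20
seed: 1
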