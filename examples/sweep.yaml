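# repressilator amplitude/period across ribosome availability
circuit:
  type: repressilator
axis_A: [5.8e+6]
axis_R: [1000, 2000, 5000]
metrics: [amplitude, period]
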