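# A + B <-> C <-> 2 D, the worked compilation example
species:
- {name: A, K: 1.0, x0: 1.0, kind: dynamic}
- {name: B, K: 2.0, x0: 1.0, kind: dynamic}
- {name: C, K: 3.0, x0: 0.0, kind: dynamic}
- {name: D, K: 4.0, x0: 0.0, kind: dynamic}
reactions:
- name: r1
  rate_param: 1.5
  forward_stoich: {A: 1, B: 1}
  reverse_stoich: {C: 1}
  law: mass_action
- name: r2
  rate_param: 0.7
  forward_stoich: {C: 1}
  reverse_stoich: {D: 2}
  law: mass_action
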