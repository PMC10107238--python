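name: baseline-economy
economy:
  a2: 2.0
  a3: 0.03
  gamma: 0.7
  s: 20.0
  death_rate: 0.4
cost:
  c0: 20.0
  c1: 3.0
  c2: 0.1
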