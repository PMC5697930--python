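name: C3
thermal_energy: 0.593
domains:
- {name: F, stability: 0.0, is_functional: true}
- {name: DBD, stability: 0.0, is_binding: true}
couplings:
- pair: [F, DBD]
  delta_g: 0.4110362780720475
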