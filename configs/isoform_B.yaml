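name: B
thermal_energy: 0.593
domains:
- {name: R, stability: 0.4110362780720475}
- {name: F, stability: 0.0, is_functional: true}
- {name: DBD, stability: 0.0, is_binding: true}
couplings:
- pair: [R, F]
  delta_g: -2.0551813903602376
- pair: [R, DBD]
  delta_g: 0.822072556144095
- pair: [F, DBD]
  delta_g: 0.4110362780720475
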