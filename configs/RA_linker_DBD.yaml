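name: R_A-linker-DBD
thermal_energy: 0.593
domains:
- {name: R, stability: 0.822072556144095}
- {name: DBD, stability: 0.0, is_binding: true}
couplings:
- pair: [R, DBD]
  delta_g: 0.822072556144095
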