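name: linker-DBD
thermal_energy: 0.593
domains:
- {name: DBD, stability: 0.0, is_binding: true}
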