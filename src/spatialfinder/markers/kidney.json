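{
  "podocyte": ["NPHS1"],
  "proximal_tubule": ["LRP2"],
  "loop_of_henle": ["UMOD"]
}
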